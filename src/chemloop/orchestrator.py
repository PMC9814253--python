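"""Closed-loop campaign orchestration.

Runs the plan → execute → measure → learn cycle: each loop, a batch of
eight parameter points sharing the block temperature is planned, executed
(against the built-in reaction emulator, or exported as a robot-exchange CSV
for external execution), measured responses are appended as observations
with their *executed* parameters, merits are recomputed, and the next loop
is planned.  Standard (test-reaction) wells are simulated at a fixed
reference condition and logged separately from the optimization accounting.

Also houses the HPLC assay-yield arithmetic (peak-area ratio to an internal
standard with predetermined response factors) and the campaign makespan
model (staggered dispensing at 15-min intervals, 120-min reaction age).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import chimera
from .batch_planner import BatchPlan, lambda_schedule, plan_batch
from .chimera import ObjectiveHierarchy, default_hierarchy
from .kde_optimizer import Observation, SurrogateConfig
from .parameter_space import (
    ContinuousParameter,
    ParameterPoint,
    ParameterSpace,
    default_space,
)
from .virtual_lab import Emulator, EmulatorConfig, build_emulator, simulate_reaction

__all__ = [
    "CampaignConfig",
    "HPLCRecord",
    "CampaignLog",
    "assay_yield",
    "schedule_makespan",
    "run_campaign",
]


@dataclass(frozen=True)
class CampaignConfig:
    space: ParameterSpace
    hierarchy: ObjectiveHierarchy
    surrogate: SurrogateConfig = field(default_factory=SurrogateConfig)
    batch_size: int = 8
    n_loops: int = 24
    standard_wells_per_block: int = 16  # two sets of eight per 96-well block
    stagger_min: float = 15.0
    age_min: float = 120.0
    seed: int = 0
    mode: str = "emulator"  # "emulator" | "csv-exchange"

    def __post_init__(self) -> None:
        if self.mode not in ("emulator", "csv-exchange"):
            raise ValueError("mode must be 'emulator' or 'csv-exchange'")
        if self.batch_size < 1 or self.n_loops < 1:
            raise ValueError("batch_size and n_loops must be positive")

    @property
    def total_iterations(self) -> int:
        return self.n_loops * self.batch_size


@dataclass(frozen=True)
class HPLCRecord:
    """Peak areas for one injection plus per-species response factors."""

    experiment_id: int
    peak_areas: Mapping[str, float]
    internal_standard_area: float
    response_factors: Mapping[str, float]

    def __post_init__(self) -> None:
        object.__setattr__(self, "peak_areas", dict(self.peak_areas))
        object.__setattr__(self, "response_factors", dict(self.response_factors))
        if any(a < 0 for a in self.peak_areas.values()):
            raise ValueError("peak areas must be nonnegative")


def assay_yield(record: HPLCRecord, n_internal_standard: float,
                n_limiting: float) -> dict[str, float]:
    """Assay yield (mol%) per species from HPLC peak-area ratios.

        yield% = (A_species / A_IS) · (1 / RF_species) · (n_IS / n_limiting) · 100

    with RF the predetermined response factor (area ratio per mole ratio)
    and n in consistent amount units (µmol).
    """
    if record.internal_standard_area <= 0:
        raise ValueError("internal-standard area must be positive")
    out: dict[str, float] = {}
    for species, area in record.peak_areas.items():
        if species not in record.response_factors:
            raise KeyError(f"missing response factor for {species!r}")
        rf = record.response_factors[species]
        out[species] = (area / record.internal_standard_area) / rf \
            * (n_internal_standard / n_limiting) * 100.0
    return out


def schedule_makespan(n_reactions: int, batch_size: int = 8,
                      stagger_min: float = 15.0, age_min: float = 120.0,
                      mode: str = "parallel_loops") -> float:
    """Campaign wall-clock duration in hours.

    ``sequential``: one reaction after another, each taking ``age_min``.
    ``parallel_loops``: loops of ``batch_size`` staggered dispenses followed
    by the reaction age; cycle time = batch_size·stagger + age.
    """
    if n_reactions < 1:
        raise ValueError("n_reactions must be >= 1")
    if mode == "sequential":
        return n_reactions * age_min / 60.0
    if mode == "parallel_loops":
        n_loops = math.ceil(n_reactions / batch_size)
        return n_loops * (batch_size * stagger_min + age_min) / 60.0
    raise ValueError("mode must be 'sequential' or 'parallel_loops'")


@dataclass
class CampaignLog:
    """Append-only record of a campaign: observations, plans, config snapshot."""

    config: CampaignConfig
    observations: list[Observation] = field(default_factory=list)
    standard_observations: list[Observation] = field(default_factory=list)
    plans: list[BatchPlan] = field(default_factory=list)

    def to_dataframe(self, include_standard: bool = False) -> pd.DataFrame:
        rows = []
        obs = self.observations + (self.standard_observations if include_standard else [])
        for o in sorted(obs, key=lambda o: (o.loop_id, o.experiment_id)):
            row = {"experiment_id": o.experiment_id, "loop_id": o.loop_id,
                   "lambda": o.lambda_user, "is_standard": o.is_standard,
                   "merit": o.merit}
            row.update({f"param_{k}": v for k, v in o.point.values.items()})
            row.update(o.responses)
            rows.append(row)
        return pd.DataFrame(rows)

    def write_csv(self, path: str | Path) -> None:
        self.to_dataframe(include_standard=True).to_csv(path, index=False)


def plan_to_robot_csv(plan: BatchPlan, path: str | Path,
                      first_experiment_id: int = 0) -> None:
    """Serialize a batch plan to the robot-exchange CSV.

    Columns: experiment_id, well, loop_id, lambda, one ``vol_<name>_uL``
    column per dispense volume (integer µL for a 1 µL quantum) and one raw
    column per executed parameter.  Wells are assigned in row-major order.
    """
    rows = []
    for i, slot in enumerate(plan.slots):
        well = f"{chr(ord('A') + i // 12)}{i % 12 + 1}"
        row: dict[str, object] = {
            "experiment_id": first_experiment_id + i,
            "well": well,
            "loop_id": plan.loop_id,
            "lambda": slot.lambda_user,
        }
        for name, vt in slot.volumes.items():
            row[f"vol_{name}_uL"] = vt["volume"]
        for name, v in slot.executed.values.items():
            row[name] = v
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_results_csv(path: str | Path) -> dict[int, dict[str, float]]:
    """Parse a results CSV (experiment_id, species, peak_area → long form,
    or experiment_id + one column per response → wide form)."""
    df = pd.read_csv(path)
    if "experiment_id" not in df.columns:
        raise ValueError("results CSV missing experiment_id column")
    out: dict[int, dict[str, float]] = {}
    if {"species", "peak_area"} <= set(df.columns):
        for (eid,), grp in df.groupby(["experiment_id"]):
            out[int(eid)] = dict(zip(grp["species"], grp["peak_area"].astype(float)))
    else:
        for _, row in df.iterrows():
            eid = int(row["experiment_id"])
            out[eid] = {c: float(row[c]) for c in df.columns if c != "experiment_id"}
    return out


#: fixed reference condition for standard (test) reactions: the mid-activity
#: reference ligand at the replicate-study condition
STANDARD_CONDITION = {"p_pd_ratio": 1.52, "pd_mol_pct": 2.5, "temperature": 20.0}


def _standard_point(space: ParameterSpace, ligand: str) -> ParameterPoint:
    values: dict[str, float | str] = {}
    for p in space:
        if isinstance(p, ContinuousParameter):
            values[p.name] = STANDARD_CONDITION.get(p.name, (p.low + p.high) / 2.0)
        else:
            values[p.name] = ligand
    return ParameterPoint(values=values, provenance="executed")


def run_campaign(config: CampaignConfig,
                 emulator: Emulator | None = None,
                 exchange_dir: str | Path | None = None) -> CampaignLog:
    """Run a closed-loop campaign and return its log.

    In emulator mode each planned slot is measured by the built-in reaction
    emulator (executed parameters, per-slot derived noise seed); in
    csv-exchange mode each loop's plan is written to
    ``exchange_dir/loop_<id>_plan.csv`` and results are awaited at
    ``exchange_dir/loop_<id>_results.csv`` (wide form, E_yield/Z_yield
    columns) before the next loop is planned.

    Standard wells (``standard_wells_per_block`` per 96-well block, i.e. per
    ~11 optimization loops) are simulated at the fixed reference condition
    and logged separately; they never enter the optimizer's observations.
    """
    cfg = config
    log = CampaignLog(config=cfg)
    experiment_id = 0
    std_ligand = cfg.space.categorical[0].options[1] if cfg.space.categorical else None

    for loop_id in range(cfg.n_loops):
        plan = plan_batch(log.observations, cfg.space, cfg.hierarchy,
                          cfg.surrogate, loop_id, batch_size=cfg.batch_size,
                          campaign_seed=cfg.seed)
        log.plans.append(plan)

        if cfg.mode == "csv-exchange":
            if exchange_dir is None:
                raise ValueError("csv-exchange mode requires exchange_dir")
            exchange_dir = Path(exchange_dir)
            plan_to_robot_csv(plan, exchange_dir / f"loop_{loop_id}_plan.csv",
                              first_experiment_id=experiment_id)
            results_path = exchange_dir / f"loop_{loop_id}_results.csv"
            if not results_path.exists():
                raise FileNotFoundError(
                    f"awaiting results for loop {loop_id}: {results_path}")
            results = read_results_csv(results_path)
        else:
            if emulator is None:
                raise ValueError("emulator mode requires an emulator")
            results = {}
            for i, slot in enumerate(plan.slots):
                rs = np.random.SeedSequence(
                    [cfg.seed, loop_id, i, 7919]).generate_state(1)[0] % (2**31)
                rr = simulate_reaction(emulator, slot.executed, seed=int(rs))
                results[experiment_id + i] = rr.as_responses()

        for i, slot in enumerate(plan.slots):
            eid = experiment_id + i
            if eid not in results:
                raise ValueError(f"results missing experiment_id {eid}")
            missing = [r for r in cfg.hierarchy.response_names
                       if r not in results[eid] and r not in slot.executed.values]
            if missing:
                raise ValueError(
                    f"experiment {eid}: results missing responses {missing}")
            responses = dict(results[eid])
            # objectives that are themselves parameters (e.g. Pd loading)
            for r in cfg.hierarchy.response_names:
                if r not in responses:
                    responses[r] = float(slot.executed.values[r])
            log.observations.append(Observation(
                point=slot.executed, responses=responses, merit=float("nan"),
                loop_id=loop_id, experiment_id=eid,
                lambda_user=slot.lambda_user, is_standard=False))
        experiment_id += len(plan.slots)

        # standard wells: one set of replicates per completed 96-well block
        if (cfg.mode == "emulator" and cfg.standard_wells_per_block > 0
                and std_ligand is not None):
            block_loops = max(1, (96 - cfg.standard_wells_per_block) // cfg.batch_size)
            if (loop_id + 1) % block_loops == 0:
                pt = _standard_point(cfg.space, std_ligand)
                for j in range(cfg.standard_wells_per_block):
                    rs = np.random.SeedSequence(
                        [cfg.seed, loop_id, j, 104729]).generate_state(1)[0] % (2**31)
                    rr = simulate_reaction(emulator, pt, seed=int(rs))
                    responses = dict(rr.as_responses())
                    for r in cfg.hierarchy.response_names:
                        if r not in responses:
                            responses[r] = float(pt.values[r])
                    log.standard_observations.append(Observation(
                        point=pt, responses=responses, merit=float("nan"),
                        loop_id=loop_id, experiment_id=-(len(log.standard_observations) + 1),
                        lambda_user=float("nan"), is_standard=True))

    # final merit pass so the log carries up-to-date merits
    if log.observations:
        mv = chimera.merits_for(cfg.hierarchy,
                                [o.responses for o in log.observations])
        log.observations = [
            dataclasses.replace(o, merit=float(m))
            for o, m in zip(log.observations, mv.merit)
        ]
    return log


def default_campaign_config(n_ligands: int = 23, n_loops: int = 24,
                            seed: int = 0, include_arba: bool = False,
                            candidate_budget: int = 2000) -> CampaignConfig:
    """Campaign-2-style configuration: 23 ligands, 24 loops of 8."""
    return CampaignConfig(
        space=default_space(n_ligands=n_ligands, include_arba=include_arba),
        hierarchy=default_hierarchy(include_arba=include_arba),
        surrogate=SurrogateConfig(candidate_budget=candidate_budget, rng_seed=seed),
        n_loops=n_loops,
        seed=seed,
    )
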
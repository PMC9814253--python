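"""Process-constrained batch planning (pc-BO, basic variant).

A reactor block runs eight reactions in parallel and must hold one shared
temperature, so each loop of proposals fixes the process-constrained
parameter across all slots.  Slots sweep an evenly spaced array of sample
biases from most exploitative (+λ_max) to most explorative (−λ_max).

The shared value is anchored by one slot proposed without the constraint.
Because the exploitative acquisition has its minimum at the incumbent and
tends to the repellent limit away from data, an always-exploitative anchor
can freeze the shared temperature at whatever the first loop happened to
find; the anchor therefore cycles — exploitative for three loops, then the
most explorative slot every fourth — so the shared parameter is both
refined where the surrogate predicts good merit and periodically probed
elsewhere.  Within a batch, proposals that land within a small normalized
radius of an already-planned slot with the same categorical values are
re-proposed with a shifted sub-seed, spreading exploitative slots into a
local cloud around the incumbent instead of eight near-replicates.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from . import chimera
from .chimera import ObjectiveHierarchy
from .kde_optimizer import (
    LAMBDA_MAX,
    Observation,
    SurrogateConfig,
    propose_point,
)
from .parameter_space import (
    ParameterPoint,
    ParameterSpace,
    normalize_point,
    snap_to_executable,
)

__all__ = ["BatchSlot", "BatchPlan", "lambda_schedule", "plan_batch", "slot_seed"]

#: anchor-slot indices per loop, cycled: three exploitative, one explorative
ANCHOR_CYCLE = (0, 0, 0, -1)

#: minimum normalized Chebyshev distance between same-ligand slots in a batch
IN_BATCH_RADIUS = 0.05


@dataclass(frozen=True)
class BatchSlot:
    lambda_user: float
    suggested: ParameterPoint
    executed: ParameterPoint
    volumes: dict[str, dict[str, float]]


@dataclass(frozen=True)
class BatchPlan:
    loop_id: int
    slots: tuple[BatchSlot, ...]
    shared_values: dict[str, float]

    def __post_init__(self) -> None:
        for name, v in self.shared_values.items():
            for s in self.slots:
                if s.suggested.values[name] != v:
                    raise ValueError(
                        f"slot violates shared constraint {name}={v}")


def lambda_schedule(batch_size: int, lambda_max: float = LAMBDA_MAX) -> list[float]:
    """Evenly spaced sample biases, exploitative-first.

    ``batch_size`` values from +λ_max down to −λ_max inclusive; a batch of
    one gets the neutral bias 0.
    """
    if lambda_max <= 0:
        raise ValueError("lambda_max must be positive")
    if batch_size < 1:
        raise ValueError("batch_size must be >= 1")
    if batch_size == 1:
        return [0.0]
    return list(np.linspace(lambda_max, -lambda_max, batch_size))


def slot_seed(campaign_seed: int, loop_id: int, slot: int) -> int:
    """Deterministic per-slot seed derived from (campaign seed, loop, slot)."""
    ss = np.random.SeedSequence([campaign_seed, loop_id, slot])
    return int(ss.generate_state(1)[0] % (2**31))


def plan_batch(observations: Sequence[Observation], space: ParameterSpace,
               hierarchy: ObjectiveHierarchy, config: SurrogateConfig,
               loop_id: int, batch_size: int = 8,
               campaign_seed: int = 0) -> BatchPlan:
    """Plan one loop of proposals sharing the process-constrained parameter.

    Merits are recomputed from scratch over all observations to date; the
    loop's anchor slot (see :data:`ANCHOR_CYCLE`) is proposed without the
    constraint and its value of the constrained parameter becomes the loop's
    shared value; the remaining slots are proposed with it fixed; every
    suggestion is snapped to executable dispense volumes, and the executed
    point is stored alongside the suggested one.
    """
    observations = list(observations)
    if observations:
        mv = chimera.merits_for(hierarchy, [o.responses for o in observations])
        observations = [dataclasses.replace(o, merit=float(m))
                        for o, m in zip(observations, mv.merit)]

    lambdas = lambda_schedule(batch_size)
    constrained = space.constrained_parameter
    anchor = ANCHOR_CYCLE[loop_id % len(ANCHOR_CYCLE)] % batch_size
    order = [anchor] + [i for i in range(batch_size) if i != anchor]

    cont_names = [p.name for p in space.continuous]
    cat_names = [p.name for p in space.categorical]
    placed: list[tuple[tuple, np.ndarray]] = []

    def encode(pt: ParameterPoint) -> tuple[tuple, np.ndarray]:
        nn = normalize_point(space, pt)
        return (tuple(nn[c] for c in cat_names),
                np.array([nn[c] for c in cont_names], dtype=float))

    def crowds(pt: ParameterPoint) -> bool:
        cats, x = encode(pt)
        for pc, px in placed:
            if cats != pc:
                continue
            if x.size == 0 or np.abs(x - px).max() < IN_BATCH_RADIUS:
                return True
        return False

    shared: dict[str, float] = {}
    slots_by_idx: dict[int, BatchSlot] = {}
    for i in order:
        lam = lambdas[i]
        fixed = dict(shared) if (constrained is not None and shared) else None
        suggestion = propose_point(observations, lam, space, fixed=fixed,
                                   config=config,
                                   seed=slot_seed(campaign_seed, loop_id, i))
        attempt = 0
        while crowds(suggestion) and attempt < 6:
            attempt += 1
            suggestion = propose_point(
                observations, lam, space, fixed=fixed, config=config,
                seed=slot_seed(campaign_seed, loop_id, i + 1000 * attempt))
        placed.append(encode(suggestion))
        if i == anchor and constrained is not None:
            shared[constrained.name] = float(suggestion.values[constrained.name])
        executed, volumes = snap_to_executable(space, suggestion)
        slots_by_idx[i] = BatchSlot(lambda_user=lam, suggested=suggestion,
                                    executed=executed, volumes=volumes)
    return BatchPlan(loop_id=loop_id,
                     slots=tuple(slots_by_idx[i] for i in range(batch_size)),
                     shared_values=shared)
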
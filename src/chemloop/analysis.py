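"""Post-campaign summaries: replicate statistics, bias–response averages,
best-so-far traces, chemical-space response maps, and experiment-count
arithmetic for comparing against factorial designs."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .kde_optimizer import Observation
from .ligand_space import ClusterModel

__all__ = [
    "ReplicateSummary",
    "replicate_stats",
    "bias_response_summary",
    "best_so_far",
    "factorial_count",
    "space_response_map",
    "selectivity_ratio",
]


@dataclass(frozen=True)
class ReplicateSummary:
    mean: float
    sd: float
    rsd: float | None  # percent; None when the mean is 0
    n: int


def replicate_stats(values: Sequence[float]) -> ReplicateSummary:
    """Mean, sample sd (n−1 denominator) and relative sd of replicates."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 replicates")
    mean = float(v.mean())
    sd = float(v.std(ddof=1))
    rsd = 100.0 * sd / mean if mean != 0 else None
    return ReplicateSummary(mean=mean, sd=sd, rsd=rsd, n=int(v.size))


def bias_response_summary(observations: Sequence[Observation],
                          response: str = "E_yield") -> pd.DataFrame:
    """Mean response per sample-bias value, ordered explorative → exploitative.

    Reproduces the bias-vs-yield bar chart: grouping the log by the λ each
    slot was proposed with, exploitative (positive) biases should on average
    outperform explorative (negative) ones once the optimizer has learned
    the surface.
    """
    obs = [o for o in observations if not o.is_standard]
    if not obs:
        raise ValueError("empty observation log")
    df = pd.DataFrame({
        "lambda": [o.lambda_user for o in obs],
        response: [o.responses[response] for o in obs],
    })
    out = df.groupby("lambda", sort=True)[response].agg(["mean", "count"])
    out = out.reset_index().rename(columns={"mean": f"mean_{response}",
                                            "count": "n"})
    return out  # ascending lambda = explorative first


def best_so_far(observations: Sequence[Observation], response: str = "E_yield",
                direction: str = "maximize") -> pd.DataFrame:
    """Running best of a response over experiment order.

    Returns a frame (experiment_id, value, best, incumbent_id); the trace is
    monotone and ends at the global extremum of the log.
    """
    obs = sorted((o for o in observations if not o.is_standard),
                 key=lambda o: o.experiment_id)
    if not obs:
        raise ValueError("empty observation log")
    sign = 1.0 if direction == "maximize" else -1.0
    rows = []
    best_val = -np.inf
    incumbent = None
    for o in obs:
        v = float(o.responses[response])
        if sign * v > best_val:
            best_val = sign * v
            incumbent = o.experiment_id
        rows.append({"experiment_id": o.experiment_id, "value": v,
                     "best": sign * best_val, "incumbent_id": incumbent})
    return pd.DataFrame(rows)


def factorial_count(levels_per_factor: int, n_factors: int,
                    n_categories: int) -> int:
    """Experiments a full factorial design would need:
    levels^factors × categories (e.g. 3³ × 23 = 621)."""
    if min(levels_per_factor, n_factors, n_categories) < 1:
        raise ValueError("arguments must be positive integers")
    return levels_per_factor**n_factors * n_categories


def space_response_map(model: ClusterModel, ligand_ids: Sequence[str],
                       per_ligand_max: Mapping[str, float]) -> pd.DataFrame:
    """Map per-ligand best responses onto the 2-D PC chemical space.

    One row per ligand in the model: (ligand_id, pc1, pc2, cluster,
    max_response, evaluated).  Ligands never run in a campaign carry
    ``evaluated=False`` and a missing response.  A response for a ligand the
    model does not know is an error.
    """
    known = set(ligand_ids)
    unknown = set(per_ligand_max) - known
    if unknown:
        raise KeyError(f"responses for unknown ligands: {sorted(unknown)}")
    rows = []
    for i, lig in enumerate(ligand_ids):
        evaluated = lig in per_ligand_max
        rows.append({
            "ligand_id": lig,
            "pc1": float(model.pc_scores[i, 0]),
            "pc2": float(model.pc_scores[i, 1]),
            "cluster": model.labels[lig],
            "max_response": float(per_ligand_max[lig]) if evaluated else np.nan,
            "evaluated": evaluated,
        })
    return pd.DataFrame(rows)


def per_ligand_max(observations: Sequence[Observation], ligand_param: str = "ligand",
                   response: str = "E_yield") -> dict[str, float]:
    """Best observed response for each ligand appearing in the log."""
    out: dict[str, float] = {}
    for o in observations:
        if o.is_standard:
            continue
        lig = str(o.point.values[ligand_param])
        v = float(o.responses[response])
        if lig not in out or v > out[lig]:
            out[lig] = v
    return out


def selectivity_ratio(observations: Sequence[Observation],
                      e_response: str = "E_yield", z_response: str = "Z_yield",
                      ) -> float:
    """E/Z selectivity at the incumbent (best-E) condition, one decimal."""
    obs = [o for o in observations if not o.is_standard]
    if not obs:
        raise ValueError("empty observation log")
    best = max(obs, key=lambda o: o.responses[e_response])
    z = float(best.responses[z_response])
    if z <= 0:
        return float("inf")
    return round(float(best.responses[e_response]) / z, 1)
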
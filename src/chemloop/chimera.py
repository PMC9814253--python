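"""Hierarchical multi-objective scalarization ("Chimera"-style merit).

An ordered hierarchy of objectives -- here: maximize E-product yield, then
minimize Z-product yield, then minimize palladium loading, then minimize
arylboronic-acid equivalents -- is collapsed into a single scalar merit per
observation.  Each level carries a relative tolerance (default 10%): a
threshold is placed at ``min + tolerance × span`` of that level's values over
the region of observations that satisfied all higher-priority thresholds,
and only observations within the threshold are considered at the next level.

The merit used here is an *operational reconstruction* of the soft-stacking
Chimera scalarizer: an observation failing its first threshold at level ``d``
receives an integer offset ``J + 1 − d`` (J = number of levels) plus the
min–max-normalized value of the failed (or last) level.  This preserves the
hierarchy semantics -- any observation satisfying more levels strictly
outranks one satisfying fewer -- while remaining exactly testable.  Lower
merit is better.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "ObjectiveSpec",
    "ObjectiveHierarchy",
    "MeritVector",
    "orient",
    "compute_thresholds",
    "scalarize",
    "default_hierarchy",
]


@dataclass(frozen=True)
class ObjectiveSpec:
    """One level of the objective hierarchy.

    ``relative_tolerance`` is the fraction of the observed span of this
    objective (within the surviving region) that still counts as "achieved".
    """

    response_name: str
    direction: str  # "maximize" | "minimize"
    relative_tolerance: float = 0.10

    def __post_init__(self) -> None:
        if self.direction not in ("maximize", "minimize"):
            raise ValueError(f"direction must be maximize/minimize, got {self.direction!r}")
        if not 0.0 <= self.relative_tolerance < 1.0:
            raise ValueError("relative_tolerance must be in [0, 1)")


@dataclass(frozen=True)
class ObjectiveHierarchy:
    objectives: tuple[ObjectiveSpec, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "objectives", tuple(self.objectives))
        if len(self.objectives) < 1:
            raise ValueError("need at least one objective")
        names = [o.response_name for o in self.objectives]
        if len(set(names)) != len(names):
            raise ValueError("response names must be unique")

    def __len__(self) -> int:
        return len(self.objectives)

    def __iter__(self):
        return iter(self.objectives)

    @property
    def response_names(self) -> tuple[str, ...]:
        return tuple(o.response_name for o in self.objectives)


@dataclass(frozen=True)
class MeritVector:
    """Scalar merit per observation (lower = better) plus the first violated level.

    ``violation_level[i]`` is the 1-based index of the first hierarchy level
    whose threshold observation ``i`` fails, or ``J + 1`` if it satisfies all.
    """

    merit: np.ndarray
    violation_level: np.ndarray
    thresholds: np.ndarray

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.merit)):
            raise ValueError("merit must be finite")


def orient(hierarchy: ObjectiveHierarchy,
           responses: Sequence[Mapping[str, float]]) -> np.ndarray:
    """Stack responses into an (n_obs, n_levels) matrix in minimization form.

    Maximize-objectives are negated so that, at every level, smaller is
    better.  Raises if any observation lacks a response the hierarchy needs.
    """
    n = len(responses)
    J = len(hierarchy)
    out = np.empty((n, J), dtype=float)
    for j, obj in enumerate(hierarchy):
        for i, r in enumerate(responses):
            if obj.response_name not in r:
                raise KeyError(
                    f"observation {i} missing response {obj.response_name!r}")
            v = float(r[obj.response_name])
            out[i, j] = -v if obj.direction == "maximize" else v
    return out


def compute_thresholds(oriented: np.ndarray,
                       hierarchy: ObjectiveHierarchy) -> np.ndarray:
    """Per-level thresholds over nested surviving regions.

    With R₁ = all observations, level j's threshold is
    ``min_{R_j} f_j + t_j · (max_{R_j} f_j − min_{R_j} f_j)`` and
    ``R_{j+1} = {i ∈ R_j : f_j(i) ≤ threshold_j}``.  If R_{j+1} would be
    empty (cannot happen with t_j ≥ 0, but guarded for robustness) it falls
    back to the argmin set of f_j on R_j.
    """
    oriented = np.asarray(oriented, dtype=float)
    if oriented.ndim != 2 or oriented.shape[0] < 1:
        raise ValueError("need at least one observation")
    J = len(hierarchy)
    thresholds = np.empty(J, dtype=float)
    region = np.ones(oriented.shape[0], dtype=bool)
    for j, obj in enumerate(hierarchy):
        vals = oriented[region, j]
        lo, hi = vals.min(), vals.max()
        thresholds[j] = lo + obj.relative_tolerance * (hi - lo)
        nxt = region & (oriented[:, j] <= thresholds[j])
        if not nxt.any():
            nxt = region & (oriented[:, j] == lo)
        region = nxt
    return thresholds


def scalarize(oriented: np.ndarray, hierarchy: ObjectiveHierarchy,
              thresholds: np.ndarray | None = None) -> MeritVector:
    """Merit per observation from the hierarchy and its thresholds.

    For observation i let d(i) be the first level whose threshold it fails
    (J+1 if none) and c = min(d(i), J).  Then

        merit(i) = (J + 1 − d(i)) + f̂_c(i)

    with f̂_c the min–max normalization of level c over *all* observations
    (zero-span levels normalize to 0).  The integer offset guarantees the
    dominance property: satisfying strictly more levels always wins.
    """
    oriented = np.asarray(oriented, dtype=float)
    J = len(hierarchy)
    if thresholds is None:
        thresholds = compute_thresholds(oriented, hierarchy)
    n = oriented.shape[0]
    fails = oriented > thresholds[None, :]  # (n, J)
    d = np.full(n, J + 1, dtype=int)
    any_fail = fails.any(axis=1)
    d[any_fail] = fails[any_fail].argmax(axis=1) + 1
    c = np.minimum(d, J) - 1  # 0-based column of the deciding level

    # min-max normalize each level over all observations
    lo = oriented.min(axis=0)
    span = oriented.max(axis=0) - lo
    safe = np.where(span > 0, span, 1.0)
    normed = (oriented - lo[None, :]) / safe[None, :]
    normed[:, span == 0] = 0.0

    merit = (J + 1 - d).astype(float) + normed[np.arange(n), c]
    return MeritVector(merit=merit, violation_level=d, thresholds=np.asarray(thresholds))


def merits_for(hierarchy: ObjectiveHierarchy,
               responses: Sequence[Mapping[str, float]]) -> MeritVector:
    """Convenience: orient, threshold and scalarize in one call."""
    oriented = orient(hierarchy, responses)
    return scalarize(oriented, hierarchy)


def default_hierarchy(include_arba: bool = False,
                      tolerance: float = 0.10) -> ObjectiveHierarchy:
    """The campaign's objective ordering.

    Maximize E-product assay yield, then minimize Z-product assay yield, then
    minimize Pd loading, then (optionally) minimize arylboronic-acid
    equivalents; every level at the given relative tolerance.
    """
    objectives = [
        ObjectiveSpec("E_yield", "maximize", tolerance),
        ObjectiveSpec("Z_yield", "minimize", tolerance),
        ObjectiveSpec("pd_mol_pct", "minimize", tolerance),
    ]
    if include_arba:
        objectives.append(ObjectiveSpec("arba_equiv", "minimize", tolerance))
    return ObjectiveHierarchy(tuple(objectives))
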
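"""Kernel-density surrogate with explicit explore/exploit sample bias.

The surrogate follows the Phoenics/Gryffin idea: a kernel density estimate
over the *evaluated* parameter points reweights observed merits into an
acquisition function

    α_λ(x) = ( Σ_n m̂_n k_n(x) + λ_int · w₀ · p₀ ) / ( Σ_n k_n(x) + w₀ · p₀ )

where m̂_n are min–max-normalized merits (lower = better), k_n the kernel
weight of observation n at query x, p₀ the uniform density over the
normalized space, w₀ a prior weight, and λ_int ∈ [−1, 1] the *sample bias*:
far from all data the acquisition tends to λ_int, so negative λ makes
unexplored regions attractive (explorative) and positive λ makes them
repellent (exploitative).  Batches probe a spread of λ values at once.

Kernels are fixed (no learned parameters): Gaussian on normalized continuous
axes with a Scott-like bandwidth scaled by the observed per-dimension spread,
a smoothed indicator on categorical axes, or a Gaussian on standardized
descriptor vectors when a categorical parameter carries molecular
descriptors (descriptor mode).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .parameter_space import (
    CategoricalParameter,
    ContinuousParameter,
    ParameterPoint,
    ParameterSpace,
    denormalize_point,
    normalize_point,
    validate_point,
)

__all__ = [
    "Observation",
    "SurrogateConfig",
    "LAMBDA_MAX",
    "kernel_weight",
    "acquisition",
    "propose_point",
]

#: magnitude of the most exploitative / explorative sample bias exposed to users
LAMBDA_MAX = 0.000104


@dataclass(frozen=True)
class Observation:
    """An executed experiment: parameter point, measured responses, merit."""

    point: ParameterPoint
    responses: Mapping[str, float]
    merit: float = float("nan")
    loop_id: int = -1
    experiment_id: int = -1
    lambda_user: float = float("nan")
    is_standard: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "responses", dict(self.responses))


@dataclass(frozen=True)
class SurrogateConfig:
    """Tunables of the KDE surrogate.

    ``categorical_smoothing`` s gives a differing option the weight
    ``s/(K−1)`` (same option: ``1−s``); ``prior_weight`` w₀ sets how much
    evidence is needed before the data overrides the uniform prior;
    ``candidate_budget`` is the random-search size of the acquisition
    optimizer.
    """

    bandwidth_rule: str = "scott"
    categorical_smoothing: float = 0.1
    descriptor_mode: bool = False
    prior_weight: float = 1.0
    candidate_budget: int = 2000
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.categorical_smoothing < 1.0:
            raise ValueError("categorical_smoothing must be in [0, 1)")
        if self.prior_weight <= 0:
            raise ValueError("prior_weight must be positive")


def continuous_bandwidth(n_obs: int, n_continuous: int) -> float:
    """Scott-like bandwidth factor n^(−1/(d+4)) on normalized axes,
    floored at 0.05."""
    if n_obs < 1:
        return 1.0
    return max(0.05, float(n_obs) ** (-1.0 / (n_continuous + 4)))


def _standardized_descriptors(param: CategoricalParameter) -> dict[str, np.ndarray]:
    """Z-score descriptor vectors across options (zero-variance dims → 0)."""
    mat = np.stack([param.descriptors[o] for o in param.options])
    mu = mat.mean(axis=0)
    sd = mat.std(axis=0, ddof=0)
    sd = np.where(sd > 0, sd, 1.0)
    z = (mat - mu) / sd
    return {o: z[i] for i, o in enumerate(param.options)}


class _SpaceView:
    """Precomputed numeric view of a space for fast kernel evaluation."""

    def __init__(self, space: ParameterSpace, config: SurrogateConfig):
        self.space = space
        self.config = config
        self.cont = space.continuous
        self.cat = space.categorical
        self.desc: dict[str, dict[str, np.ndarray]] = {}
        if config.descriptor_mode:
            for p in self.cat:
                if p.descriptors is None:
                    raise ValueError(
                        f"descriptor mode requires descriptors on {p.name!r}")
                self.desc[p.name] = _standardized_descriptors(p)

    def encode(self, normalized: Mapping[str, float | int]) -> tuple[np.ndarray, np.ndarray]:
        x = np.array([normalized[p.name] for p in self.cont], dtype=float)
        c = np.array([int(normalized[p.name]) for p in self.cat], dtype=int)
        return x, c

    def encode_points(self, points: Sequence[ParameterPoint]) -> tuple[np.ndarray, np.ndarray]:
        xs = np.empty((len(points), len(self.cont)))
        cs = np.empty((len(points), len(self.cat)), dtype=int)
        for i, pt in enumerate(points):
            nn = normalize_point(self.space, pt)
            xs[i] = [nn[p.name] for p in self.cont]
            cs[i] = [int(nn[p.name]) for p in self.cat]
        return xs, cs

    @property
    def prior_density(self) -> float:
        # uniform density: 1 over the unit cube × 1/K per categorical axis
        p0 = 1.0
        for p in self.cat:
            p0 /= len(p.options)
        return p0


class _Surrogate:
    """Encoded observations + bandwidths, built once per proposal round."""

    def __init__(self, view: _SpaceView, observations: Sequence[Observation]):
        self.view = view
        self.n = len(observations)
        d = max(len(view.cont), 1)
        if self.n:
            self.obs_x, self.obs_c = view.encode_points([o.point for o in observations])
            merits = np.array([o.merit for o in observations], dtype=float)
            lo, hi = merits.min(), merits.max()
            self.m_hat = (merits - lo) / (hi - lo) if hi > lo else np.zeros_like(merits)
            # Scott-like bandwidth scaled by the observed per-dimension spread
            factor = float(self.n) ** (-1.0 / (d + 4))
            sd = self.obs_x.std(axis=0, ddof=0) if self.obs_x.size else np.array([])
            self.sigma = np.maximum(0.05, np.maximum(sd, 0.05) * factor)
        else:
            self.obs_x = np.empty((0, len(view.cont)))
            self.obs_c = np.empty((0, len(view.cat)), dtype=int)
            self.m_hat = np.empty(0)
            self.sigma = np.full(len(view.cont), continuous_bandwidth(0, d))

    def kernel(self, q_x: np.ndarray, q_c: np.ndarray) -> np.ndarray:
        """(n_obs, n_query) kernel weights."""
        view = self.view
        w = np.ones((self.n, q_x.shape[0]))
        if self.obs_x.shape[1]:
            d2 = ((self.obs_x[:, None, :] - q_x[None, :, :])
                  / self.sigma[None, None, :]) ** 2
            w *= np.exp(-0.5 * d2.sum(axis=2))
        s = view.config.categorical_smoothing
        for j, p in enumerate(view.cat):
            K = len(p.options)
            if view.config.descriptor_mode:
                z = np.stack([view.desc[p.name][o] for o in p.options])
                sigma_c = float(self.sigma.mean() if self.sigma.size else 0.5) \
                    * np.sqrt(z.shape[1])
                d2 = ((z[self.obs_c[:, j]][:, None, :]
                       - z[q_c[:, j]][None, :, :]) ** 2).sum(axis=2)
                w *= np.exp(-d2 / (2.0 * sigma_c**2))
            else:
                same = self.obs_c[:, j][:, None] == q_c[:, j][None, :]
                w *= np.where(same, 1.0 - s, s / (K - 1))
        return w

    def alpha(self, q_x: np.ndarray, q_c: np.ndarray, lambda_int: float) -> np.ndarray:
        prior = self.view.config.prior_weight * self.view.prior_density
        if self.n == 0:
            return np.full(q_x.shape[0], lambda_int, dtype=float)
        k = self.kernel(q_x, q_c)
        num = self.m_hat @ k + lambda_int * prior
        den = k.sum(axis=0) + prior
        return num / den


def kernel_weight(space: ParameterSpace, obs_point: Mapping[str, float | int],
                  query_point: Mapping[str, float | int],
                  config: SurrogateConfig, n_obs: int = 1) -> float:
    """Kernel weight of one normalized observation at one normalized query.

    Product over dimensions: Gaussian ``exp(−(Δ/σ)²/2)`` on continuous axes,
    smoothed indicator ``1−s`` / ``s/(K−1)`` on categorical axes (plain
    mode), Gaussian on standardized descriptor distance (descriptor mode).
    With a single reference observation the bandwidth falls back to the
    spread-free Scott factor.
    """
    view = _SpaceView(space, config)
    sigma = continuous_bandwidth(n_obs, max(len(view.cont), 1))
    ox, oc = view.encode(obs_point)
    qx, qc = view.encode(query_point)
    w = 1.0
    if ox.size:
        w *= float(np.exp(-0.5 * (((ox - qx) / sigma) ** 2).sum()))
    s = config.categorical_smoothing
    for j, p in enumerate(view.cat):
        K = len(p.options)
        if config.descriptor_mode:
            z = view.desc[p.name]
            zo, zq = z[p.options[oc[j]]], z[p.options[qc[j]]]
            sigma_c = sigma * np.sqrt(zo.shape[0])
            w *= float(np.exp(-((zo - zq) ** 2).sum() / (2.0 * sigma_c**2)))
        else:
            w *= (1.0 - s) if oc[j] == qc[j] else s / (K - 1)
    return w


def acquisition(observations: Sequence[Observation], query: ParameterPoint,
                lambda_user: float, space: ParameterSpace,
                config: SurrogateConfig) -> float:
    """Acquisition value (to minimize) at a single query point.

    ``lambda_user`` lives on the user-facing ``[−LAMBDA_MAX, +LAMBDA_MAX]``
    scale and is mapped internally to ``λ_int = λ_user / LAMBDA_MAX``.
    """
    view = _SpaceView(space, config)
    sur = _Surrogate(view, list(observations))
    lam = float(np.clip(lambda_user / LAMBDA_MAX, -1.0, 1.0))
    qn = normalize_point(space, query)
    q_x, q_c = view.encode(qn)
    return float(sur.alpha(q_x[None, :], q_c[None, :].reshape(1, -1), lam)[0])


def _random_candidates(view: _SpaceView, rng: np.random.Generator, n: int,
                       fixed_norm: Mapping[str, float | int]) -> tuple[np.ndarray, np.ndarray]:
    q_x = rng.random((n, len(view.cont)))
    q_c = np.empty((n, len(view.cat)), dtype=int)
    for j, p in enumerate(view.cat):
        q_c[:, j] = rng.integers(0, len(p.options), size=n)
    for i, p in enumerate(view.cont):
        if p.name in fixed_norm:
            q_x[:, i] = float(fixed_norm[p.name])
    for j, p in enumerate(view.cat):
        if p.name in fixed_norm:
            q_c[:, j] = int(fixed_norm[p.name])
    return q_x, q_c


_INVPHI = (np.sqrt(5.0) - 1.0) / 2.0


def _golden_refine(sur: _Surrogate, lam: float, x: np.ndarray, cats: np.ndarray,
                   dims: Sequence[int], rounds: int = 3, shrinks: int = 8) -> np.ndarray:
    """Coordinate-wise golden-section refinement on free continuous dims."""
    x = x.copy()
    c_row = cats[None, :]

    def f(dim: int, val: float) -> float:
        x2 = x.copy()
        x2[dim] = val
        return float(sur.alpha(x2[None, :], c_row, lam)[0])

    for _ in range(rounds):
        for d in dims:
            a, b = 0.0, 1.0
            c1 = b - _INVPHI * (b - a)
            c2 = a + _INVPHI * (b - a)
            f1, f2 = f(d, c1), f(d, c2)
            for _ in range(shrinks):
                if f1 <= f2:
                    b, c2, f2 = c2, c1, f1
                    c1 = b - _INVPHI * (b - a)
                    f1 = f(d, c1)
                else:
                    a, c1, f1 = c1, c2, f2
                    c2 = a + _INVPHI * (b - a)
                    f2 = f(d, c2)
            x[d] = (a + b) / 2.0
    return x


def propose_point(observations: Sequence[Observation], lambda_user: float,
                  space: ParameterSpace,
                  fixed: Mapping[str, float | str] | None = None,
                  config: SurrogateConfig | None = None,
                  seed: int | None = None) -> ParameterPoint:
    """Propose the next parameter point by minimizing the acquisition.

    Random search over ``candidate_budget`` uniform valid candidates (with
    ``fixed`` parameter values clamped, e.g. the loop temperature), followed
    by coordinate-wise golden-section refinement of the best candidate on
    the free continuous dimensions.  If the winner essentially coincides
    with an existing observation (same categorical values, normalized
    continuous distance < 1e−6) the next-best candidate is taken instead.
    """
    config = config or SurrogateConfig()
    fixed = dict(fixed or {})
    view = _SpaceView(space, config)
    observations = list(observations)
    sur = _Surrogate(view, observations)
    lam = float(np.clip(lambda_user / LAMBDA_MAX, -1.0, 1.0))

    # translate fixed raw values into normalized coordinates, validating them
    fixed_norm: dict[str, float | int] = {}
    for name, v in fixed.items():
        if name not in space:
            raise ValueError(f"fixed parameter {name!r} not in space")
        p = space[name]
        if isinstance(p, ContinuousParameter):
            if not (p.low <= float(v) <= p.high):
                raise ValueError(f"fixed {name}={v} outside [{p.low}, {p.high}]")
            fixed_norm[name] = (float(v) - p.low) / (p.high - p.low)
        else:
            if v not in p.options:
                raise ValueError(f"fixed {name}={v!r} not an option")
            fixed_norm[name] = p.index_of(str(v))

    rng = np.random.default_rng(seed if seed is not None else config.rng_seed)
    q_x, q_c = _random_candidates(view, rng, config.candidate_budget, fixed_norm)
    alpha = sur.alpha(q_x, q_c, lam)
    order = np.argsort(alpha, kind="stable")

    free_dims = [i for i, p in enumerate(view.cont) if p.name not in fixed_norm]

    def duplicates(x_vec: np.ndarray, cats: np.ndarray) -> bool:
        if sur.n == 0:
            return False
        same_cat = (sur.obs_c == cats[None, :]).all(axis=1)
        if not same_cat.any():
            return False
        if sur.obs_x.shape[1] == 0:
            return True
        d = np.abs(sur.obs_x[same_cat] - x_vec[None, :]).max(axis=1)
        return bool((d < 1e-6).any())

    chosen_x: np.ndarray | None = None
    chosen_c: np.ndarray | None = None
    for rank, idx in enumerate(order):
        x0, c0 = q_x[idx].copy(), q_c[idx].copy()
        if rank == 0 and free_dims and sur.n > 0:
            x0 = _golden_refine(sur, lam, x0, c0, free_dims)
        if not duplicates(x0, c0):
            chosen_x, chosen_c = x0, c0
            break
    if chosen_x is None:  # every candidate duplicated an observation
        chosen_x, chosen_c = q_x[order[0]], q_c[order[0]]

    normalized: dict[str, float | int] = {}
    for i, p in enumerate(view.cont):
        normalized[p.name] = float(np.clip(chosen_x[i], 0.0, 1.0))
    for j, p in enumerate(view.cat):
        normalized[p.name] = int(chosen_c[j])
    # re-impose fixed raw values exactly (avoid normalize/denormalize drift)
    point = denormalize_point(space, normalized, provenance="suggested")
    values = dict(point.values)
    for name, v in fixed.items():
        values[name] = float(v) if isinstance(space[name], ContinuousParameter) else str(v)
    point = ParameterPoint(values=values, provenance="suggested")
    report = validate_point(space, point)
    if not report:
        raise ValueError("internal error: proposed invalid point: "
                         + "; ".join(report.violations))
    return point
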
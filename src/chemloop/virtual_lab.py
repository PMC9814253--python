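"""Synthetic Suzuki-coupling emulator for hardware-free closed-loop runs.

The emulator returns (E-yield, Z-yield) in mol% for any valid parameter
point.  Its mean surface is an invented but qualitatively faithful shape for
a ligand-mediated cross-coupling:

  conversion(x) = 100 · logistic((T − T₀)/τ) · Pd/(Pd + Pd½)
                      · exp(−(r − r_L)²/(2w²)) · a_L

with reaction temperature T (conversion improves toward the upper end of the
range), palladium loading Pd (saturating benefit), phosphine-to-palladium
ratio r (each ligand L has a preferred ratio r_L near the center of the
range), and a per-ligand activity a_L.  Stereochemistry splits conversion
into E (retention) and Z (inversion) by a per-ligand selectivity s_L:
E = conversion·s_L, Z = conversion·(1−s_L).  Measurement noise is additive
Gaussian with sd 1.5 mol% by default, matching a replicate reproducibility
of 1–2 mol%.

These functional forms are fixtures for exercising the optimizer, not
claims about reaction mechanism.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .parameter_space import (
    ParameterPoint,
    ParameterSpace,
    validate_point,
)

__all__ = [
    "LigandLatent",
    "EmulatorConfig",
    "ReactionResult",
    "Emulator",
    "build_emulator",
    "simulate_reaction",
    "true_optimum",
]


@dataclass(frozen=True)
class LigandLatent:
    """Hidden per-ligand truth the optimizer must discover."""

    selectivity_base: float   # fraction of conversion going to the E product
    preferred_ratio: float    # P/Pd ratio maximizing conversion for this ligand
    activity: float           # multiplicative activity scale in (0, 1]

    def __post_init__(self) -> None:
        if not 0.0 <= self.selectivity_base <= 1.0:
            raise ValueError("selectivity_base must be in [0, 1]")
        if not 0.0 < self.activity <= 1.0:
            raise ValueError("activity must be in (0, 1]")


@dataclass(frozen=True)
class EmulatorConfig:
    """Shape and noise parameters of the mean response surface."""

    noise_sd: float = 1.5          # mol%, replicate sd between 1 and 2 by default
    temp_midpoint: float = 30.0    # °C, logistic midpoint of the T response
    temp_steepness: float = 5.0    # °C
    pd_halfsat: float = 2.0        # mol% at which the Pd factor reaches 1/2
    ratio_width: float = 0.8       # width w of the P/Pd preference ridge
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")


@dataclass(frozen=True)
class ReactionResult:
    E_yield: float
    Z_yield: float
    conversion: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.E_yield and 0.0 <= self.Z_yield):
            raise ValueError("yields must be nonnegative")
        if self.E_yield + self.Z_yield > self.conversion + 1e-9:
            raise ValueError("E + Z must not exceed conversion")
        if self.conversion > 100.0 + 1e-9:
            raise ValueError("conversion must not exceed 100 mol%")

    def as_responses(self) -> dict[str, float]:
        return {"E_yield": self.E_yield, "Z_yield": self.Z_yield,
                "conversion": self.conversion}


def _logistic(z: np.ndarray | float) -> np.ndarray | float:
    return 1.0 / (1.0 + np.exp(-z))


class Emulator:
    """Deterministic mean surface + seeded Gaussian measurement noise."""

    def __init__(self, latents: Mapping[str, LigandLatent], config: EmulatorConfig,
                 parameter_names: Mapping[str, str] | None = None):
        if not latents:
            raise ValueError("need at least one ligand")
        self.latents = dict(latents)
        self.config = config
        names = parameter_names or {}
        self.ligand_param = names.get("ligand", "ligand")
        self.ratio_param = names.get("ratio", "p_pd_ratio")
        self.pd_param = names.get("pd", "pd_mol_pct")
        self.temp_param = names.get("temperature", "temperature")

    def mean_surface(self, ligand: str, ratio: float, pd: float,
                     temperature: float) -> tuple[float, float, float]:
        """Noiseless (E, Z, conversion) in mol%."""
        if ligand not in self.latents:
            raise KeyError(f"unknown ligand {ligand!r}")
        lat = self.latents[ligand]
        cfg = self.config
        conv = (100.0
                * _logistic((temperature - cfg.temp_midpoint) / cfg.temp_steepness)
                * (pd / (pd + cfg.pd_halfsat))
                * np.exp(-((ratio - lat.preferred_ratio) ** 2)
                         / (2.0 * cfg.ratio_width**2))
                * lat.activity)
        conv = float(min(conv, 100.0))
        return conv * lat.selectivity_base, conv * (1.0 - lat.selectivity_base), conv

    def mean_at(self, point: ParameterPoint) -> tuple[float, float, float]:
        v = point.values
        return self.mean_surface(str(v[self.ligand_param]),
                                 float(v[self.ratio_param]),
                                 float(v[self.pd_param]),
                                 float(v[self.temp_param]))


def build_emulator(ligand_ids: Sequence[str],
                   descriptors: Mapping[str, np.ndarray] | None = None,
                   config: EmulatorConfig | None = None,
                   seed: int | None = None,
                   parameter_names: Mapping[str, str] | None = None) -> Emulator:
    """Draw per-ligand latent truths and assemble an emulator.

    Without descriptors, selectivities are drawn so that a few ligands are
    markedly E-selective while most favor stereoinversion, mirroring a
    campaign where only a minority of ligands give the retention product.
    With descriptors, the selectivity is a logistic-linear function of the
    ligand's (standardized) descriptor vector, so descriptor-aware
    optimization has exploitable signal.
    """
    if len(ligand_ids) < 1:
        raise ValueError("need at least one ligand")
    config = config or EmulatorConfig()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    latents: dict[str, LigandLatent] = {}
    if descriptors is not None:
        mat = np.stack([np.asarray(descriptors[l], dtype=float) for l in ligand_ids])
        mu, sd = mat.mean(axis=0), mat.std(axis=0, ddof=0)
        sd = np.where(sd > 0, sd, 1.0)
        Z = (mat - mu) / sd
        w = rng.normal(0.0, 1.0, size=Z.shape[1])
        w /= max(np.linalg.norm(w), 1e-12)
        logit = 2.5 * (Z @ w) - 0.8
        selectivities = _logistic(logit)
    else:
        # beta(1.2, 2.5): most ligands Z-prone, a thin tail of E-selective ones
        selectivities = rng.beta(1.2, 2.5, size=len(ligand_ids))
    for lig, s in zip(ligand_ids, selectivities):
        latents[lig] = LigandLatent(
            selectivity_base=float(np.clip(s, 0.0, 1.0)),
            preferred_ratio=float(rng.uniform(1.2, 3.2)),
            activity=float(rng.uniform(0.55, 1.0)),
        )
    return Emulator(latents, config, parameter_names)


def simulate_reaction(emulator: Emulator, point: ParameterPoint,
                      seed: int | None = None,
                      space: ParameterSpace | None = None) -> ReactionResult:
    """One noisy measurement at a parameter point.

    Independent Gaussian noise (sd = ``noise_sd``) on E and Z, truncated so
    that yields stay nonnegative and E + Z ≤ conversion ≤ 100.
    """
    if space is not None:
        report = validate_point(space, point)
        if not report:
            raise ValueError("invalid point: " + "; ".join(report.violations))
    mean_E, mean_Z, mean_conv = emulator.mean_at(point)
    rng = np.random.default_rng(seed)
    E = max(0.0, mean_E + rng.normal(0.0, emulator.config.noise_sd))
    Z = max(0.0, mean_Z + rng.normal(0.0, emulator.config.noise_sd))
    total = E + Z
    if total > 100.0:
        E, Z = E * 100.0 / total, Z * 100.0 / total
        total = 100.0
    conv = float(min(100.0, max(total, mean_conv)))
    return ReactionResult(E_yield=float(E), Z_yield=float(Z), conversion=conv)


def true_optimum(emulator: Emulator, space: ParameterSpace,
                 resolution: int = 21) -> tuple[ParameterPoint, float]:
    """Brute-force grid argmax of the noiseless E-yield.

    Exhaustive over every ligand and a ``resolution``-point grid per
    continuous dimension; serves as the oracle optimum for judging campaign
    performance.
    """
    cont = space.continuous
    grids = {p.name: np.linspace(p.low, p.high, resolution) for p in cont}
    cat = space.categorical
    assert len(cat) == 1, "emulator space has exactly one categorical parameter"
    ligands = cat[0].options
    cfg = emulator.config
    R, P, T = np.meshgrid(grids[emulator.ratio_param],
                          grids[emulator.pd_param],
                          grids[emulator.temp_param], indexing="ij")
    base = (100.0
            * _logistic((T - cfg.temp_midpoint) / cfg.temp_steepness)
            * (P / (P + cfg.pd_halfsat)))
    best_val = -np.inf
    best_point: ParameterPoint | None = None
    for lig in ligands:
        if lig not in emulator.latents:
            raise KeyError(f"unknown ligand {lig!r}")
        lat = emulator.latents[lig]
        conv = np.minimum(
            base * np.exp(-((R - lat.preferred_ratio) ** 2)
                          / (2.0 * cfg.ratio_width**2)) * lat.activity,
            100.0)
        E = conv * lat.selectivity_base
        idx = np.unravel_index(int(E.argmax()), E.shape)
        if E[idx] > best_val:
            best_val = float(E[idx])
            best_point = ParameterPoint(values={
                cat[0].name: lig,
                emulator.ratio_param: float(R[idx]),
                emulator.pd_param: float(P[idx]),
                emulator.temp_param: float(T[idx]),
            })
    return best_point, float(best_val)
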
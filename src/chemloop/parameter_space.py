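"""Mixed categorical/continuous parameter spaces for batch reaction optimization.

A :class:`ParameterSpace` describes the search domain of an optimization
campaign: continuous process parameters (ranges with units, e.g. reaction
temperature in degrees Celsius) and categorical parameters (ordered option
lists, e.g. phosphine ligands identified by catalog-style labels such as
``"L30"``).  One continuous parameter may be flagged *process-constrained*,
meaning every reaction in a parallel batch must share its value -- on the
robotic platform this is the reactor-block temperature.

Continuous parameters dispensed as stock solutions carry a
:class:`DispenseRule` describing the stock concentration and the instrument's
volume quantum; :func:`snap_to_executable` rounds suggested amounts to
dispensable volumes and records the *executed* amounts, which is what enters
the optimizer's observation history.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "ContinuousParameter",
    "CategoricalParameter",
    "DispenseRule",
    "ParameterPoint",
    "ParameterSpace",
    "ValidationReport",
    "validate_point",
    "normalize_point",
    "denormalize_point",
    "snap_to_executable",
    "load_space",
]


@dataclass(frozen=True)
class DispenseRule:
    """Quantization of a dispensed amount through a stock solution.

    Parameters
    ----------
    stock_concentration
        Concentration of the stock solution in amount per volume (µmol/µL,
        numerically equal to mol/L), so that amount / concentration is a
        volume in µL.
    volume_quantum
        Smallest volume increment the instrument can dispense (µL).
    min_volume, max_volume
        Dispensable volume range (µL).
    amount_per_unit
        Conversion from the parameter's value to the dispensed amount in
        µmol (e.g. 0.1 µmol per mol% when the limiting reagent is 10 µmol).
        Default 1: the parameter value *is* the amount.
    """

    stock_concentration: float
    volume_quantum: float = 1.0
    min_volume: float = 3.0
    max_volume: float = 100.0
    amount_per_unit: float = 1.0

    def __post_init__(self) -> None:
        if self.volume_quantum <= 0:
            raise ValueError("volume_quantum must be positive")
        if self.min_volume > self.max_volume:
            raise ValueError("min_volume must not exceed max_volume")
        if self.stock_concentration <= 0:
            raise ValueError("stock_concentration must be positive")
        if self.amount_per_unit <= 0:
            raise ValueError("amount_per_unit must be positive")


@dataclass(frozen=True)
class ContinuousParameter:
    name: str
    low: float
    high: float
    units: str = ""
    is_process_constrained: bool = False
    dispense: DispenseRule | None = None

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise ValueError(f"{self.name}: require low < high, got [{self.low}, {self.high}]")


@dataclass(frozen=True)
class CategoricalParameter:
    name: str
    options: tuple[str, ...]
    descriptors: Mapping[str, np.ndarray] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "options", tuple(self.options))
        if len(self.options) < 2:
            raise ValueError(f"{self.name}: need at least 2 options")
        if len(set(self.options)) != len(self.options):
            raise ValueError(f"{self.name}: duplicate options")
        if self.descriptors is not None:
            desc = {k: np.asarray(v, dtype=float) for k, v in self.descriptors.items()}
            lengths = {v.shape for v in desc.values()}
            if len(lengths) > 1:
                raise ValueError(f"{self.name}: descriptor vectors differ in length")
            missing = set(self.options) - set(desc)
            if missing:
                raise ValueError(f"{self.name}: descriptors missing for {sorted(missing)}")
            object.__setattr__(self, "descriptors", desc)

    def index_of(self, option: str) -> int:
        return self.options.index(option)


@dataclass(frozen=True)
class ParameterPoint:
    """An assignment of a value to every parameter of a space."""

    values: Mapping[str, float | str]
    provenance: str = "suggested"  # "suggested" | "executed"

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", dict(self.values))
        if self.provenance not in ("suggested", "executed"):
            raise ValueError(f"provenance must be 'suggested' or 'executed', got {self.provenance!r}")

    def __getitem__(self, name: str) -> float | str:
        return self.values[name]


@dataclass(frozen=True)
class ValidationReport:
    ok: bool
    violations: tuple[str, ...] = ()

    def __bool__(self) -> bool:
        return self.ok


class ParameterSpace:
    """Ordered collection of continuous and categorical parameters."""

    def __init__(self, parameters: Sequence[ContinuousParameter | CategoricalParameter]):
        names = [p.name for p in parameters]
        if len(set(names)) != len(names):
            raise ValueError("duplicate parameter names")
        constrained = [p for p in parameters if isinstance(p, ContinuousParameter) and p.is_process_constrained]
        if len(constrained) > 1:
            raise ValueError("at most one process-constrained parameter allowed")
        self.parameters: tuple[ContinuousParameter | CategoricalParameter, ...] = tuple(parameters)
        self._by_name = {p.name: p for p in parameters}

    def __getitem__(self, name: str) -> ContinuousParameter | CategoricalParameter:
        return self._by_name[name]

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def __iter__(self):
        return iter(self.parameters)

    @property
    def continuous(self) -> tuple[ContinuousParameter, ...]:
        return tuple(p for p in self.parameters if isinstance(p, ContinuousParameter))

    @property
    def categorical(self) -> tuple[CategoricalParameter, ...]:
        return tuple(p for p in self.parameters if isinstance(p, CategoricalParameter))

    @property
    def constrained_parameter(self) -> ContinuousParameter | None:
        for p in self.continuous:
            if p.is_process_constrained:
                return p
        return None

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(p.name for p in self.parameters)


def validate_point(space: ParameterSpace, point: ParameterPoint) -> ValidationReport:
    """Check a point against a space; never clamps, always reports.

    Returns a :class:`ValidationReport` listing every violation: missing or
    unknown parameters, continuous values outside ``[low, high]``, categorical
    values not in the option list.
    """
    violations: list[str] = []
    for name in point.values:
        if name not in space:
            violations.append(f"unknown parameter {name!r}")
    for p in space:
        if p.name not in point.values:
            violations.append(f"missing parameter {p.name!r}")
            continue
        v = point.values[p.name]
        if isinstance(p, ContinuousParameter):
            if not isinstance(v, (int, float, np.floating, np.integer)):
                violations.append(f"{p.name}: expected a number, got {type(v).__name__}")
            elif not (p.low <= float(v) <= p.high):
                violations.append(f"{p.name}: value {v} out of range [{p.low}, {p.high}]")
        else:
            if v not in p.options:
                violations.append(f"{p.name}: unknown option {v!r}")
    return ValidationReport(ok=not violations, violations=tuple(violations))


def normalize_point(space: ParameterSpace, point: ParameterPoint) -> dict[str, float | int]:
    """Map a valid point to the unit cube; categorical values become option indices."""
    report = validate_point(space, point)
    if not report:
        raise ValueError("cannot normalize invalid point: " + "; ".join(report.violations))
    out: dict[str, float | int] = {}
    for p in space:
        v = point.values[p.name]
        if isinstance(p, ContinuousParameter):
            out[p.name] = (float(v) - p.low) / (p.high - p.low)
        else:
            out[p.name] = p.index_of(str(v))
    return out


def denormalize_point(space: ParameterSpace, normalized: Mapping[str, float | int],
                      provenance: str = "suggested") -> ParameterPoint:
    """Inverse of :func:`normalize_point`."""
    values: dict[str, float | str] = {}
    for p in space:
        v = normalized[p.name]
        if isinstance(p, ContinuousParameter):
            values[p.name] = p.low + float(v) * (p.high - p.low)
        else:
            values[p.name] = p.options[int(v)]
    return ParameterPoint(values=values, provenance=provenance)


def _round_half_away(x: float) -> float:
    """Round to nearest integer, ties away from zero (numpy rounds ties to even)."""
    return float(np.sign(x) * np.floor(np.abs(x) + 0.5))


def snap_to_executable(space: ParameterSpace, point: ParameterPoint,
                       ) -> tuple[ParameterPoint, dict[str, dict[str, float]]]:
    """Round dispensed amounts to instrument-executable volumes.

    For every continuous parameter carrying a :class:`DispenseRule`, the
    dispensed amount (parameter value × ``amount_per_unit``) is converted to
    a stock-solution volume, rounded to the nearest multiple of the volume
    quantum (ties away from zero), and the executed amount -- hence the
    executed parameter value -- is recomputed from the rounded volume.  The
    returned point has ``provenance="executed"`` and is what belongs in the
    observation log.

    Returns
    -------
    executed_point, volume_table
        ``volume_table[name]`` has keys ``suggested_amount``, ``volume``,
        ``executed_amount``.

    Raises
    ------
    ValueError
        If a rounded volume falls outside ``[min_volume, max_volume]``,
        naming the parameter and the violated bound; no clamping.
    """
    report = validate_point(space, point)
    if not report:
        raise ValueError("cannot snap invalid point: " + "; ".join(report.violations))
    values = dict(point.values)
    table: dict[str, dict[str, float]] = {}
    for p in space.continuous:
        if p.dispense is None:
            continue
        rule = p.dispense
        amount = float(values[p.name]) * rule.amount_per_unit
        volume = amount / rule.stock_concentration
        snapped = _round_half_away(volume / rule.volume_quantum) * rule.volume_quantum
        if snapped < rule.min_volume:
            raise ValueError(f"{p.name}: rounded volume {snapped} µL below min_volume {rule.min_volume} µL")
        if snapped > rule.max_volume:
            raise ValueError(f"{p.name}: rounded volume {snapped} µL above max_volume {rule.max_volume} µL")
        executed_amount = snapped * rule.stock_concentration
        values[p.name] = executed_amount / rule.amount_per_unit
        table[p.name] = {
            "suggested_amount": amount,
            "volume": snapped,
            "executed_amount": executed_amount,
        }
    executed = ParameterPoint(values=values, provenance="executed")
    post = validate_point(space, executed)
    if not post:
        raise ValueError("executed point invalid after rounding: " + "; ".join(post.violations))
    return executed, table


# ---------------------------------------------------------------------------
# config I/O

def _parse_parameter(block: Mapping) -> ContinuousParameter | CategoricalParameter:
    kind = block["type"]
    if kind == "continuous":
        dispense = None
        if "dispense" in block and block["dispense"] is not None:
            d = block["dispense"]
            dispense = DispenseRule(
                stock_concentration=float(d["stock_concentration"]),
                volume_quantum=float(d.get("volume_quantum", 1.0)),
                min_volume=float(d.get("min_volume", 3.0)),
                max_volume=float(d.get("max_volume", 100.0)),
                amount_per_unit=float(d.get("amount_per_unit", 1.0)),
            )
        return ContinuousParameter(
            name=block["name"],
            low=float(block["low"]),
            high=float(block["high"]),
            units=block.get("units", ""),
            is_process_constrained=bool(block.get("process_constrained", False)),
            dispense=dispense,
        )
    if kind == "categorical":
        descriptors = None
        if "descriptor_csv" in block and block["descriptor_csv"]:
            import pandas as pd

            df = pd.read_csv(block["descriptor_csv"], index_col=0)
            descriptors = {str(i): row.to_numpy(dtype=float) for i, row in df.iterrows()}
        return CategoricalParameter(
            name=block["name"],
            options=tuple(str(o) for o in block["options"]),
            descriptors=descriptors,
        )
    raise ValueError(f"unknown parameter type {kind!r}")


def load_space(path: str | Path) -> ParameterSpace:
    """Load a parameter space from a YAML or JSON config file.

    The file holds a list (or a ``parameters:`` list) of per-parameter blocks
    with ``type`` (continuous/categorical), range or options, units, an
    optional ``dispense`` rule and an optional ``descriptor_csv`` path.
    """
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    blocks = data["parameters"] if isinstance(data, Mapping) else data
    return ParameterSpace([_parse_parameter(b) for b in blocks])


def default_space(n_ligands: int = 23, ligand_prefix: str = "L",
                  include_arba: bool = False,
                  descriptors: Mapping[str, np.ndarray] | None = None) -> ParameterSpace:
    """The campaign search space: ligand choice plus continuous process knobs.

    Ranges: P/Pd ratio 0.5-4.0, Pd loading 1.0-5.0 mol%, reaction temperature
    10-40 °C (process-constrained), optionally arylboronic-acid equivalents
    1.0-2.0.  Ligand options are labelled ``L1..Ln`` by default.
    """
    params: list[ContinuousParameter | CategoricalParameter] = [
        CategoricalParameter(
            name="ligand",
            options=tuple(f"{ligand_prefix}{i}" for i in range(1, n_ligands + 1)),
            descriptors=descriptors,
        ),
        # ligand dispensed from 0.02 M stock; amount per unit ratio referenced
        # to a 0.2 µmol nominal Pd charge, so range endpoints land on whole µL
        ContinuousParameter(name="p_pd_ratio", low=0.5, high=4.0, units="ratio",
                            dispense=DispenseRule(stock_concentration=0.02,
                                                  volume_quantum=1.0,
                                                  min_volume=3.0, max_volume=100.0,
                                                  amount_per_unit=0.2)),
        # Pd dispensed from 0.01 M stock; 0.1 µmol per mol% (10 µmol limiting)
        ContinuousParameter(name="pd_mol_pct", low=1.0, high=5.0, units="mol%",
                            dispense=DispenseRule(stock_concentration=0.01,
                                                  volume_quantum=1.0,
                                                  min_volume=3.0, max_volume=100.0,
                                                  amount_per_unit=0.1)),
        ContinuousParameter(name="temperature", low=10.0, high=40.0, units="°C",
                            is_process_constrained=True),
    ]
    if include_arba:
        params.append(ContinuousParameter(name="arba_equiv", low=1.0, high=2.0, units="equiv"))
    return ParameterSpace(params)
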
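"""Domain types and Stern-Volmer model mathematics.

The Stern-Volmer relation for dynamic quenching of a phosphor is

    I0 / I = 1 + K_SV * [Q]

where ``I0`` is the unquenched emission intensity, ``I`` the intensity in the
presence of quencher at concentration ``[Q]``, and ``K_SV`` the Stern-Volmer
constant.  For pure chemicals ``[Q]`` is molar and ``K_SV`` has units of M^-1;
for culture supernatants ``[Q]`` is a relative concentration in
(fold dilutions)^-1 (neat supernatant = 1) and the slope is an *effective*
constant in (fold dilutions)^-1.  The two unit systems are never mixed: every
concentration-bearing quantity carries an explicit :class:`ConcentrationUnit`
tag and operations refuse to combine mismatched tags.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Union

import numpy as np

from .errors import DomainError, UnitMismatchError

__all__ = [
    "ConcentrationUnit",
    "SensorKind",
    "WellRole",
    "SensorSpec",
    "QuencherSpec",
    "DilutionSeries",
    "WellRecord",
    "PlateTable",
    "QuenchRatioPoint",
    "SVFitResult",
    "sv_ratio",
    "sv_inverse_ratio",
]

ArrayLike = Union[float, np.ndarray]


class ConcentrationUnit(str, Enum):
    """Unit system for quencher concentrations (and hence fitted slopes)."""

    MOLAR = "molar"
    FOLD_DILUTION = "fold_dilution"

    @property
    def slope_label(self) -> str:
        """Label for a Stern-Volmer slope in this unit system."""
        return "per_" + self.value


class SensorKind(str, Enum):
    SOLUBLE = "soluble"
    ENCAPSULATED = "encapsulated"


class WellRole(str, Enum):
    SAMPLE = "sample"
    BLANK = "blank"
    SENSOR_ONLY_CONTROL = "sensor_only_control"


class Classification(str, Enum):
    QUENCHER = "quencher"
    NON_QUENCHER = "non_quencher"


def _check_unit_match(*units: ConcentrationUnit) -> None:
    if len(set(units)) > 1:
        raise UnitMismatchError(
            f"mixed concentration units in one computation: {sorted({u.value for u in units})}"
        )


@dataclass(frozen=True)
class SensorSpec:
    """A phosphorescent O2-sensing dye or nanoparticle.

    ``reference_emission_nm`` is only meaningful for encapsulated dual-dye
    sensors that carry a quencher-insensitive reference dye alongside the
    sensing dye.
    """

    name: str
    kind: SensorKind = SensorKind.SOLUBLE
    excitation_nm: float = 450.0
    sensing_emission_nm: float = 625.0
    reference_emission_nm: Optional[float] = None

    def __post_init__(self):
        wavelengths = [self.excitation_nm, self.sensing_emission_nm]
        if self.reference_emission_nm is not None:
            wavelengths.append(self.reference_emission_nm)
        if any(not (w > 0) for w in wavelengths):
            raise DomainError(f"wavelengths must be strictly positive: {wavelengths}")
        if self.reference_emission_nm is not None and self.kind is not SensorKind.ENCAPSULATED:
            raise DomainError("reference emission channel only applies to encapsulated sensors")


@dataclass(frozen=True)
class QuencherSpec:
    """A candidate quencher: a pure chemical or a culture supernatant.

    ``intrinsically_fluorescent`` may be ``None``, meaning "unknown"; the
    fitting stage then auto-detects intrinsic fluorescence from the
    pre-addition readings.  An explicit True/False always wins.
    """

    name: str
    concentration_unit: ConcentrationUnit = ConcentrationUnit.FOLD_DILUTION
    intrinsically_fluorescent: Optional[bool] = None
    stock_concentration: float = 1.0

    def __post_init__(self):
        if not (self.stock_concentration > 0):
            raise DomainError("stock_concentration must be > 0")
        if (
            self.concentration_unit is ConcentrationUnit.FOLD_DILUTION
            and not (0 < self.stock_concentration <= 1)
        ):
            raise DomainError("fold-dilution concentrations lie in (0, 1]; neat supernatant = 1")


@dataclass(frozen=True)
class DilutionSeries:
    """A serial dilution design: pre-addition concentrations, descending.

    ``n_steps`` counts dilution steps, so a series "2-fold diluted 5 times"
    holds ``n_steps + 1 = 6`` concentrations (neat plus five dilutions).
    """

    concentrations: tuple
    fold_factor: float
    n_steps: int

    def __post_init__(self):
        conc = np.asarray(self.concentrations, dtype=float)
        if conc.size < 1 or np.any(conc <= 0):
            raise DomainError("concentrations must be strictly positive")
        if np.any(np.diff(conc) >= 0):
            raise DomainError("concentrations must be strictly decreasing")
        if not self.fold_factor > 1:
            raise DomainError("fold_factor must exceed 1")
        if self.n_steps != conc.size - 1:
            raise DomainError("n_steps must equal len(concentrations) - 1")
        ratios = conc[:-1] / conc[1:]
        if not np.allclose(ratios, self.fold_factor, rtol=1e-9):
            raise DomainError("successive concentration ratios must equal fold_factor")

    @classmethod
    def from_design(cls, start: float, fold_factor: float = 2.0, n_steps: int = 5) -> "DilutionSeries":
        conc = tuple(start / fold_factor**i for i in range(n_steps + 1))
        return cls(concentrations=conc, fold_factor=fold_factor, n_steps=n_steps)


@dataclass(frozen=True)
class WellRecord:
    """One well's paired pre/post-sensor-addition intensity readings."""

    well_id: str
    role: WellRole
    concentration_pre: Optional[float]
    bio_replicate: str
    tech_replicate: str
    pre_intensity: float
    post_intensity: float

    def __post_init__(self):
        if self.role is WellRole.SAMPLE:
            if self.concentration_pre is None:
                raise DomainError(f"sample well {self.well_id} requires concentration_pre")
        elif self.concentration_pre is not None:
            raise DomainError(f"{self.role.value} well {self.well_id} must not carry a concentration")
        for label, v in (("pre", self.pre_intensity), ("post", self.post_intensity)):
            if not math.isfinite(v):
                raise DomainError(f"non-finite {label}_intensity in well {self.well_id}")


@dataclass(frozen=True)
class PlateTable:
    """A full plate: sample dilution series plus blanks and sensor-only controls."""

    wells: tuple
    sensor: SensorSpec
    quencher: QuencherSpec
    dilution_volume_initial: float = 100.0
    dilution_volume_added: float = 11.0
    metadata: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        object.__setattr__(self, "wells", tuple(self.wells))
        if not self.dilution_volume_initial > 0 or self.dilution_volume_added < 0:
            raise DomainError("well volume must be positive and added volume nonnegative")
        if len(self.blank_wells()) < 2:
            raise DomainError("plate requires at least 2 blank wells")
        if len(self.control_wells()) < 2:
            raise DomainError("plate requires at least 2 sensor-only control wells")
        if len({w.concentration_pre for w in self.sample_wells()}) < 3:
            raise DomainError("plate requires at least 3 distinct sample concentrations")

    def sample_wells(self) -> list:
        return [w for w in self.wells if w.role is WellRole.SAMPLE]

    def blank_wells(self) -> list:
        return [w for w in self.wells if w.role is WellRole.BLANK]

    def control_wells(self) -> list:
        return [w for w in self.wells if w.role is WellRole.SENSOR_ONLY_CONTROL]


@dataclass(frozen=True)
class QuenchRatioPoint:
    """One datum of the Stern-Volmer fit: (rescaled [Q], I0/I, variance, weight).

    ``var_y`` is the full delta-method variance of I0/I (replicate noise plus
    the I0 uncertainty).  ``weight`` is the reciprocal of the replicate-noise
    component only: the I0 part is shared by every point on the plate and is
    accounted for at the slope level, not per point.
    """

    q: float
    intensity_I: float
    var_I: float
    ratio_y: float
    var_y: float
    weight: float
    unit: ConcentrationUnit
    excluded: bool = False
    reason: Optional[str] = None
    well_id: Optional[str] = None

    def __post_init__(self):
        if not self.excluded:
            if not (math.isfinite(self.weight) and self.weight > 0):
                raise DomainError(f"included point requires a positive finite weight (well {self.well_id})")
            if not self.ratio_y > 0:
                raise DomainError(f"included point requires ratio_y > 0 (well {self.well_id})")


@dataclass(frozen=True)
class SVFitResult:
    """A fitted Stern-Volmer slope with its uncertainty and classification.

    ``k_sv`` is the slope of I0/I against [Q]; its unit is the reciprocal of
    the concentration unit.  ``ci95`` is symmetric about ``k_sv``.  The
    classification may be ``None`` when it has not been (or cannot be)
    assigned, e.g. a degenerate sensor baseline.
    """

    k_sv: float
    stderr: float
    ci95: tuple
    pearson_r: float
    n_included: int
    n_excluded: int
    unit: ConcentrationUnit
    classification: Optional[Classification] = None
    exclusion_reasons: tuple = ()
    quencher_name: str = ""
    sensor_name: str = ""

    def __post_init__(self):
        lo, hi = self.ci95
        if math.isfinite(lo) and math.isfinite(hi):
            if not (lo <= self.k_sv <= hi):
                raise DomainError("ci95 must bracket k_sv")
            if not math.isclose(self.k_sv - lo, hi - self.k_sv, rel_tol=1e-9, abs_tol=1e-12):
                raise DomainError("ci95 must be symmetric about k_sv")


def sv_ratio(k_sv: ArrayLike, q: ArrayLike) -> ArrayLike:
    """Fractional intensity I/I0 = (1 + K_SV * [Q])^-1.

    At K_SV = 1 (fold dilutions)^-1 a neat supernatant ([Q] = 1) halves the
    signal: sv_ratio(1, 1) == 0.5.
    """
    k_sv = np.asarray(k_sv, dtype=float)
    q = np.asarray(q, dtype=float)
    if np.any(k_sv < 0) or np.any(q < 0):
        raise DomainError("sv_ratio requires k_sv >= 0 and q >= 0")
    out = 1.0 / (1.0 + k_sv * q)
    return float(out) if out.ndim == 0 else out


def sv_inverse_ratio(k_sv: ArrayLike, q: ArrayLike) -> ArrayLike:
    """Inverse fractional intensity I0/I = 1 + K_SV * [Q] (the fitted line)."""
    k_sv = np.asarray(k_sv, dtype=float)
    q = np.asarray(q, dtype=float)
    if np.any(k_sv < 0) or np.any(q < 0):
        raise DomainError("sv_inverse_ratio requires k_sv >= 0 and q >= 0")
    out = 1.0 + k_sv * q
    return float(out) if out.ndim == 0 else out
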
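"""From raw plate readings to Stern-Volmer points.

The measurement design: each well is read once before sensor addition
("pre", capturing media background plus any intrinsic quencher fluorescence)
and once after ("post").  Adding sensor stock and withdrawing an equal volume
dilutes everything already in the well by a factor

    f = v_initial / (v_initial + v_added)

(~0.9 for 11 uL into 100 uL).  The quencher-attributable sensor signal is
therefore

    I = (post - blank_post) - f * (pre - blank_pre)

with both phases blank-corrected so that media autofluorescence cancels
exactly, and the effective quencher concentration entering the Stern-Volmer
plot is the rescaled [Q] = f * [Q_pre].

Uncertainties are propagated to first order (delta method) through blanking
and the I0/I ratio; per-concentration intensity variances come from replicate
spread, with blank variance added on top.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np

from .errors import (
    DomainError,
    EmptySeriesError,
    InsufficientReplicationError,
    InvalidBaselineError,
)
from .model import PlateTable, QuenchRatioPoint, WellRole

__all__ = [
    "BlankStats",
    "SensorBaseline",
    "PreprocessConfig",
    "dilution_factor",
    "corrected_intensity",
    "rescale_concentration",
    "blank_stats",
    "sensor_baseline",
    "ratio_with_variance",
    "build_ratio_series",
    "intrinsic_fluorescence_r",
]

EXCLUSION_NONPOSITIVE = "nonpositive corrected intensity"


@dataclass(frozen=True)
class BlankStats:
    """Mean and unbiased variance of blank (media/buffer only) wells."""

    mean: float
    variance: float
    n: int

    def __post_init__(self):
        if self.variance < 0:
            raise DomainError("variance must be nonnegative")
        if self.n < 2:
            raise InsufficientReplicationError("blank statistics require n >= 2 wells")

    @property
    def variance_of_mean(self) -> float:
        return self.variance / self.n


@dataclass(frozen=True)
class SensorBaseline:
    """Blank-subtracted unquenched sensor intensity I0 and its spread.

    ``variance_I0`` combines the well-to-well spread of the sensor-only
    controls with the uncertainty of the subtracted blank mean; ``cv`` is the
    relative variability of the unquenched sensor used by the non-quencher
    classification rule.  ``variance_of_mean`` is the variance of the I0
    *estimate* itself (spread of the mean, not of a single well); this error
    is shared by every I0/I ratio on the plate and is propagated into the
    slope's standard error as a common-mode term.
    """

    mean_I0: float
    variance_I0: float
    n: int = 2
    variance_of_mean: Optional[float] = None

    def __post_init__(self):
        if not self.mean_I0 > 0:
            raise InvalidBaselineError("sensor baseline must be positive after blank subtraction")
        if self.variance_I0 < 0:
            raise DomainError("variance_I0 must be nonnegative")
        if self.variance_of_mean is None:
            object.__setattr__(self, "variance_of_mean", self.variance_I0 / self.n)

    @property
    def cv(self) -> float:
        return math.sqrt(self.variance_I0) / self.mean_I0


@dataclass(frozen=True)
class PreprocessConfig:
    """Knobs for variance estimation during preprocessing.

    include_blank_variance
        Add the variance of the subtracted blank mean to each per-point
        intensity variance (on by default).
    """

    include_blank_variance: bool = True


def dilution_factor(v_initial: float, v_added: float) -> float:
    """Fraction by which pre-existing well contents are diluted by sensor addition.

    Equals v_initial / (v_initial + v_added): 100/111 ~ 0.9 for the standard
    11 uL addition (with equal-volume withdrawal), 1.0 when nothing is added.
    """
    if not v_initial > 0:
        raise DomainError("v_initial must be > 0")
    if v_added < 0:
        raise DomainError("v_added must be >= 0")
    return v_initial / (v_initial + v_added)


def corrected_intensity(post: float, pre: float, f: float) -> float:
    """Sensor-attributable intensity I = post - f * pre.

    May be <= 0 for strongly fluorescent, strongly quenching samples; callers
    flag such points for exclusion rather than clipping.
    """
    if not (0 < f <= 1):
        raise DomainError("dilution factor f must lie in (0, 1]")
    return post - f * pre


def rescale_concentration(q_pre: float, f: float) -> float:
    """Post-addition concentration [Q] = f * [Q_pre]; unit tag is unchanged."""
    if q_pre < 0:
        raise DomainError("concentration must be >= 0")
    if not (0 < f <= 1):
        raise DomainError("dilution factor f must lie in (0, 1]")
    return f * q_pre


def blank_stats(plate: PlateTable, phase: str) -> BlankStats:
    """Mean and unbiased variance of blank-well intensities for one phase."""
    if phase not in ("pre", "post"):
        raise DomainError(f"phase must be 'pre' or 'post', got {phase!r}")
    blanks = plate.blank_wells()
    if len(blanks) < 2:
        raise InsufficientReplicationError("need >= 2 blank wells")
    vals = np.array(
        [w.pre_intensity if phase == "pre" else w.post_intensity for w in blanks], dtype=float
    )
    return BlankStats(mean=float(vals.mean()), variance=float(vals.var(ddof=1)), n=len(vals))


def _plate_pooled_cv2(plate: PlateTable) -> float:
    """Plate-wide pooled squared coefficient of variation of raw readings.

    Pools the squared relative deviations of every replicated well group
    (each sample concentration per phase, the controls per phase, the blanks
    per phase).  Under multiplicative read noise the relative spread is a
    property of the instrument, so pooling across the whole plate gives the
    steadiest available noise estimate.
    """
    groups: list = []
    by_conc: dict = {}
    for w in plate.sample_wells():
        by_conc.setdefault(w.concentration_pre, []).append(w)
    for ws in by_conc.values():
        groups.append([w.pre_intensity for w in ws])
        groups.append([w.post_intensity for w in ws])
    for ws in (plate.blank_wells(), plate.control_wells()):
        groups.append([w.pre_intensity for w in ws])
        groups.append([w.post_intensity for w in ws])
    ss = 0.0
    df = 0
    for vals in groups:
        v = np.asarray(vals, dtype=float)
        if v.size >= 2:
            m = float(v.mean())
            if m != 0:
                ss += float(np.sum((v - m) ** 2)) / m**2
                df += v.size - 1
    return ss / df if df > 0 else 0.0


def sensor_baseline(plate: PlateTable) -> SensorBaseline:
    """I0 from sensor-only control wells, blank-corrected in the post phase.

    ``variance_I0`` (used by the non-quencher rule's cv) is the control-well
    spread plus the blank-mean uncertainty.  ``variance_of_mean`` — the
    uncertainty of the I0 estimate that the slope stderr must absorb — is
    instead built from the plate-wide pooled relative variance, because the
    handful of control wells alone pin it down too loosely.
    """
    controls = plate.control_wells()
    if len(controls) < 2:
        raise InsufficientReplicationError("need >= 2 sensor-only control wells")
    post = np.array([w.post_intensity for w in controls], dtype=float)
    blank = blank_stats(plate, "post")
    mean_i0 = float(post.mean()) - blank.mean
    ctrl_var = float(post.var(ddof=1))
    var_i0 = ctrl_var + blank.variance_of_mean
    if mean_i0 <= 0:
        raise InvalidBaselineError(
            "sensor-only signal does not exceed the blank; baseline is invalid"
        )
    pooled_ctrl_var = _plate_pooled_cv2(plate) * float(post.mean()) ** 2
    return SensorBaseline(
        mean_I0=mean_i0,
        variance_I0=var_i0,
        n=len(controls),
        variance_of_mean=pooled_ctrl_var / len(controls) + blank.variance_of_mean,
    )


def ratio_with_variance(
    I: float, var_I: float, baseline: SensorBaseline
) -> Tuple[float, float]:
    """I0/I with its first-order (delta-method) variance.

    var(I0/I) = (I0/I)^2 * (var_I0/I0^2 + var_I/I^2), valid for small relative
    errors (checked against Monte-Carlo to within 10% at cv <= 5%).
    """
    if I <= 0:
        raise DomainError("ratio undefined for nonpositive corrected intensity; exclude the point")
    ratio = baseline.mean_I0 / I
    var = ratio**2 * (baseline.variance_I0 / baseline.mean_I0**2 + var_I / I**2)
    return ratio, var


def _pooled_relative_variance(wells_by_conc: dict, intensities: dict) -> float:
    """Pooled squared coefficient of variation of the readings.

    Plate-reader noise is proportional to signal, so the relative replicate
    spread is a constant of the instrument, not of the concentration.  Pooling
    the squared relative deviations over every replicated concentration
    (degrees of freedom sum over the series) gives a far steadier variance
    estimate than the 1-3 degrees of freedom available at any single
    concentration, which keeps the 1/variance weights from chasing the very
    fluctuations being fitted.
    """
    ss = 0.0
    df = 0
    for ws in wells_by_conc.values():
        vals = np.array([intensities[w.well_id] for w in ws], dtype=float)
        if len(vals) >= 2:
            m = float(vals.mean())
            if m != 0:
                ss += float(np.sum((vals - m) ** 2)) / m**2
                df += len(vals) - 1
    return ss / df if df > 0 else 0.0


def _per_concentration_variance(
    wells_by_conc: dict, intensities: dict, blank_var_of_mean: float
) -> dict:
    """Per-concentration reading variance: pooled cv^2 times the local mean
    signal squared, plus the variance of the subtracted blank mean."""
    pooled_rel = _pooled_relative_variance(wells_by_conc, intensities)
    var = {}
    for conc, ws in wells_by_conc.items():
        m = float(np.mean([intensities[w.well_id] for w in ws]))
        var[conc] = pooled_rel * m**2 + blank_var_of_mean
    return var


def build_ratio_series(
    plate: PlateTable, config: Optional[PreprocessConfig] = None
) -> List[QuenchRatioPoint]:
    """Convert a plate into Stern-Volmer points (q, I0/I, variance, weight).

    One point per sample well (replicates are pooled into the fit, not
    averaged).  Wells whose corrected intensity is nonpositive are marked
    excluded with reason "nonpositive corrected intensity".  Weights are the
    inverse replicate-noise variance of each ratio; when every variance is
    exactly zero (noiseless data) all points receive unit weight.
    """
    config = config or PreprocessConfig()
    samples = plate.sample_wells()
    if not samples:
        raise EmptySeriesError("plate has no sample wells")
    f = dilution_factor(plate.dilution_volume_initial, plate.dilution_volume_added)
    blank_pre = blank_stats(plate, "pre")
    blank_post = blank_stats(plate, "post")
    baseline = sensor_baseline(plate)
    blank_pre_vm = blank_pre.variance_of_mean if config.include_blank_variance else 0.0
    blank_post_vm = blank_post.variance_of_mean if config.include_blank_variance else 0.0

    wells_by_conc: dict = {}
    for w in samples:
        wells_by_conc.setdefault(w.concentration_pre, []).append(w)
    pre_vars = _per_concentration_variance(
        wells_by_conc, {w.well_id: w.pre_intensity for w in samples}, blank_pre_vm
    )
    post_vars = _per_concentration_variance(
        wells_by_conc, {w.well_id: w.post_intensity for w in samples}, blank_post_vm
    )

    unit = plate.quencher.concentration_unit
    raw: list = []
    for w in samples:
        I = corrected_intensity(
            w.post_intensity - blank_post.mean, w.pre_intensity - blank_pre.mean, f
        )
        var_I = post_vars[w.concentration_pre] + f**2 * pre_vars[w.concentration_pre]
        q = rescale_concentration(w.concentration_pre, f)
        if I <= 0:
            raw.append((w, q, I, var_I, math.nan, math.nan, math.nan, True, EXCLUSION_NONPOSITIVE))
            continue
        ratio, var_y = ratio_with_variance(I, var_I, baseline)
        # Weighting uses only the point-independent (replicate-noise) part of
        # var_y.  The I0 contribution is identical for every point on the
        # plate: it rescales all ratios in unison, never appears in residuals,
        # and is propagated into the slope stderr as a common-mode term.
        indep_var = ratio**2 * var_I / I**2
        raw.append((w, q, I, var_I, ratio, var_y, indep_var, False, None))

    positive_vars = [r[6] for r in raw if not r[7] and r[6] > 0 and math.isfinite(r[6])]
    fallback_weight = 1.0 / min(positive_vars) if positive_vars else 1.0

    points = []
    for w, q, I, var_I, ratio, var_y, indep_var, excluded, reason in raw:
        if excluded:
            weight = math.nan
        elif indep_var > 0 and math.isfinite(indep_var):
            weight = 1.0 / indep_var
        else:
            weight = fallback_weight
        points.append(
            QuenchRatioPoint(
                q=q,
                intensity_I=I,
                var_I=var_I,
                ratio_y=ratio,
                var_y=var_y,
                weight=weight,
                unit=unit,
                excluded=excluded,
                reason=reason,
                well_id=w.well_id,
            )
        )
    points.sort(key=lambda p: (p.q, p.well_id))
    if all(p.excluded for p in points):
        raise EmptySeriesError("every sample point was excluded")
    return points


def intrinsic_fluorescence_r(plate: PlateTable) -> float:
    """Pearson correlation of pre-addition (blank-corrected) intensity vs [Q_pre].

    A strong correlation marks an intrinsically fluorescent quencher, which is
    both a QC check (dilution worked) and the auto-detection signal for
    inner-filter exclusion.  Returns NaN when either axis has zero variance.
    """
    samples = plate.sample_wells()
    concs = np.array([w.concentration_pre for w in samples], dtype=float)
    if len(set(concs.tolist())) < 3:
        raise DomainError("need >= 3 distinct concentrations for a correlation")
    blank_pre = blank_stats(plate, "pre")
    intens = np.array([w.pre_intensity for w in samples], dtype=float) - blank_pre.mean
    if np.ptp(intens) == 0 or np.ptp(concs) == 0:
        return math.nan
    from scipy import stats

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        r = stats.pearsonr(concs, intens).statistic
    return float(r)
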
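"""Weighted slope-only Stern-Volmer regression and quencher classification.

The fit is a regression through the origin of (I0/I - 1) on the rescaled
quencher concentration [Q]: the Stern-Volmer intercept is theoretically 1 and
is not fitted, only the slope K_SV is.  Points are weighted by 1/var(I0/I).
The weighted least-squares solution is

    k = sum(w_i q_i (y_i - 1)) / sum(w_i q_i^2)

computed here via statsmodels WLS, whose residual-rescaled covariance and
t-quantile (n - 1 degrees of freedom) give the symmetric 95% confidence
interval.

Classification: a sample is a non-quencher when the I0/I-vs-[Q] correlation
is weak (Pearson R below threshold) or when the projected quenching at a
reference concentration (neat supernatant, or 1 M for chemicals) is within
the variability of the unquenched sensor itself.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import List, Optional, Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .errors import (
    DomainError,
    InsufficientPointsError,
    RankDeficiencyError,
)
from .model import (
    Classification,
    ConcentrationUnit,
    PlateTable,
    QuenchRatioPoint,
    QuencherSpec,
    SVFitResult,
    sv_ratio,
)
from .preprocess import (
    PreprocessConfig,
    SensorBaseline,
    build_ratio_series,
    intrinsic_fluorescence_r,
    sensor_baseline,
)

__all__ = ["FitConfig", "exclude_inner_filter", "fit_ksv", "classify", "analyze_plate"]

EXCLUSION_INNER_FILTER = "inner filter"
MIN_POINTS = 3

#: Pre-addition fluorescence-vs-concentration correlation above which a
#: quencher with no explicit fluorescence flag is treated as intrinsically
#: fluorescent (triggering inner-filter exclusion).
AUTO_FLUORESCENCE_R = 0.9


@dataclass(frozen=True)
class FitConfig:
    """Fitting and classification parameters.

    r_threshold
        Minimum Pearson correlation of I0/I vs [Q] for a quencher call (0.4).
    nq_cv_multiplier
        Projected fractional quenching at ``reference_q`` must exceed this
        multiple of the unquenched sensor's coefficient of variation
        (2, a ~95% envelope) to call a quencher.
    inner_filter_drop
        Number of top concentrations removed for intrinsically fluorescent
        quenchers before fitting.
    reference_q
        Concentration at which projected quenching is evaluated: 1 in
        fold-dilution units (neat supernatant) or 1 M for pure chemicals.
        ``None`` selects 1 in the data's own unit.
    ci_level
        Confidence level of the symmetric interval on the slope.
    """

    r_threshold: float = 0.4
    nq_cv_multiplier: float = 2.0
    inner_filter_drop: int = 1
    reference_q: Optional[float] = None
    ci_level: float = 0.95

    def __post_init__(self):
        if not (0 < self.r_threshold < 1):
            raise DomainError("r_threshold must lie in (0, 1)")
        if self.inner_filter_drop < 0:
            raise DomainError("inner_filter_drop must be >= 0")
        if not (0 < self.ci_level < 1):
            raise DomainError("ci_level must lie in (0, 1)")


def exclude_inner_filter(
    points: Sequence[QuenchRatioPoint],
    quencher: QuencherSpec,
    config: Optional[FitConfig] = None,
    intrinsic_r: Optional[float] = None,
) -> List[QuenchRatioPoint]:
    """Drop the top concentration(s) of intrinsically fluorescent quenchers.

    Inner-filter absorption by a fluorescent quencher mimics quenching at high
    concentration, so the ``inner_filter_drop`` highest distinct
    concentrations are excluded before fitting.  A quencher counts as
    fluorescent when its flag is explicitly True, or when the flag is unset
    and the pre-addition fluorescence correlates with concentration at
    Pearson R >= 0.9 (``intrinsic_r``).
    """
    config = config or FitConfig()
    fluorescent = quencher.intrinsically_fluorescent
    if fluorescent is None:
        fluorescent = intrinsic_r is not None and math.isfinite(intrinsic_r) and intrinsic_r >= AUTO_FLUORESCENCE_R
    if not fluorescent or config.inner_filter_drop == 0:
        return list(points)
    top = sorted({p.q for p in points}, reverse=True)[: config.inner_filter_drop]
    out = []
    for p in points:
        if not p.excluded and p.q in top:
            p = replace(p, excluded=True, reason=EXCLUSION_INNER_FILTER, weight=math.nan)
        out.append(p)
    if sum(not p.excluded for p in out) < MIN_POINTS:
        raise InsufficientPointsError(
            "inner-filter exclusion leaves fewer than 3 points for the slope fit"
        )
    return out


def _pearson_r(q: np.ndarray, y: np.ndarray) -> float:
    if np.ptp(q) == 0 or np.ptp(y) == 0:
        return math.nan
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(stats.pearsonr(q, y).statistic)


def fit_ksv(
    points: Sequence[QuenchRatioPoint],
    config: Optional[FitConfig] = None,
    baseline: Optional[SensorBaseline] = None,
) -> SVFitResult:
    """Weighted regression of (I0/I - 1) through the origin; slope = K_SV.

    Uses statsmodels WLS with weights 1/var(I0/I); the standard error is
    residual-rescaled and the confidence interval uses the t distribution at
    n - 1 degrees of freedom.  Pearson R is computed over the included points
    (q vs I0/I).  The returned result has no classification yet.

    When ``baseline`` is supplied, the uncertainty of the I0 estimate — which
    scales every ratio on the plate in unison and therefore never shows up in
    residuals — is propagated into the slope's standard error as a
    common-mode term:  d k / d I0 = (sum w q y / sum w q^2) / I0,  so
    var(k) gains (cv of the I0 mean)^2 * (sum w q y / sum w q^2)^2.
    """
    config = config or FitConfig()
    included = [p for p in points if not p.excluded]
    if len(included) < MIN_POINTS:
        raise InsufficientPointsError(f"need >= {MIN_POINTS} included points, got {len(included)}")
    units = {p.unit for p in included}
    if len(units) > 1:
        from .errors import UnitMismatchError

        raise UnitMismatchError(f"points mix concentration units: {sorted(u.value for u in units)}")
    unit = included[0].unit
    q = np.array([p.q for p in included], dtype=float)
    y = np.array([p.ratio_y for p in included], dtype=float)
    w = np.array([p.weight for p in included], dtype=float)
    if not np.all(np.isfinite(w) & (w > 0)):
        raise DomainError("all included points require positive finite weights")
    if np.ptp(q) == 0:
        raise RankDeficiencyError("all concentrations identical; slope is unidentifiable")

    res = sm.WLS(y - 1.0, q[:, None], weights=w).fit()
    k = float(res.params[0])
    stderr = float(res.bse[0])
    if baseline is not None and baseline.variance_of_mean > 0:
        sensitivity = float(np.sum(w * q * y) / np.sum(w * q**2))
        shared_var = baseline.variance_of_mean / baseline.mean_I0**2 * sensitivity**2
        stderr = math.sqrt(stderr**2 + shared_var)
    tcrit = float(stats.t.ppf(0.5 + config.ci_level / 2.0, df=len(included) - 1))
    half = tcrit * stderr
    ci = (k - half, k + half)

    n_excluded = len(points) - len(included)
    reasons = tuple(sorted({p.reason for p in points if p.excluded and p.reason}))
    return SVFitResult(
        k_sv=k,
        stderr=stderr,
        ci95=ci,
        pearson_r=_pearson_r(q, y),
        n_included=len(included),
        n_excluded=n_excluded,
        unit=unit,
        classification=None,
        exclusion_reasons=reasons,
    )


def classify(
    fit: SVFitResult, baseline: SensorBaseline, config: Optional[FitConfig] = None
) -> SVFitResult:
    """Attach the quencher / non-quencher call to a fit result.

    Non-quencher when either (a) Pearson R of I0/I vs [Q] is below the
    threshold (or not computable), or (b) the projected fractional quenching
    at the reference concentration, 1 - (1 + k * q_ref)^-1, does not exceed
    ``nq_cv_multiplier`` times the unquenched sensor's coefficient of
    variation.  A negative fitted slope always projects zero quenching and is
    therefore a non-quencher.
    """
    config = config or FitConfig()
    cv = baseline.cv
    if not math.isfinite(cv):
        warnings.warn("sensor baseline cv not computable; classification deferred")
        return fit
    q_ref = config.reference_q if config.reference_q is not None else 1.0
    projected = 1.0 - sv_ratio(max(fit.k_sv, 0.0), q_ref)
    weak_correlation = (not math.isfinite(fit.pearson_r)) or fit.pearson_r < config.r_threshold
    weak_quenching = projected <= config.nq_cv_multiplier * cv
    label = Classification.NON_QUENCHER if (weak_correlation or weak_quenching) else Classification.QUENCHER
    return replace(fit, classification=label)


def analyze_plate(
    plate: PlateTable,
    config: Optional[FitConfig] = None,
    preprocess_config: Optional[PreprocessConfig] = None,
) -> SVFitResult:
    """Full pipeline on one plate: ratio series -> exclusions -> fit -> classify."""
    config = config or FitConfig()
    points = build_ratio_series(plate, preprocess_config)
    try:
        intrinsic_r = intrinsic_fluorescence_r(plate)
    except DomainError:
        intrinsic_r = math.nan
    points = exclude_inner_filter(points, plate.quencher, config, intrinsic_r=intrinsic_r)
    baseline = sensor_baseline(plate)
    fit = fit_ksv(points, config, baseline=baseline)
    fit = classify(fit, baseline, config)
    return replace(
        fit, quencher_name=plate.quencher.name, sensor_name=plate.sensor.name
    )
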
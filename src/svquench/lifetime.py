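"""Phosphorescence lifetime fitting and lifetime-based Stern-Volmer analysis.

Dynamic quenching shortens the excited-state lifetime tau in the same
proportion as it dims intensity, giving the lifetime Stern-Volmer relation
tau0/tau = 1 + K_SV [Q].  Decay traces are fit to a mono-exponential with an
additive offset, I(t) = A exp(-t/tau) + B, and a titration series of fitted
lifetimes is fed through the same slope-only weighted regression used for
intensity data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import optimize

from .errors import DomainError, FitConvergenceError, InsufficientPointsError
from .fit import FitConfig, fit_ksv
from .model import ConcentrationUnit, QuenchRatioPoint, SVFitResult

__all__ = [
    "DecayTrace",
    "LifetimeFit",
    "normalize_trace",
    "fit_decay",
    "lifetime_sv",
    "titration_concentrations",
]


@dataclass(frozen=True)
class DecayTrace:
    """A time-resolved emission decay at one quencher concentration (times in us)."""

    times: tuple
    intensities: tuple
    quencher_concentration: float = 0.0

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        i = np.asarray(self.intensities, dtype=float)
        if t.size != i.size:
            raise DomainError("times and intensities must have equal length")
        if t.size < 20:
            raise DomainError("decay trace requires >= 20 samples")
        if np.any(np.diff(t) <= 0):
            raise DomainError("times must be strictly increasing")

    def arrays(self) -> Tuple[np.ndarray, np.ndarray]:
        return np.asarray(self.times, float), np.asarray(self.intensities, float)


@dataclass(frozen=True)
class LifetimeFit:
    """Fitted mono-exponential decay: amplitude A, lifetime tau (us), offset B.

    ``tau_stderr`` (residual-scaled, from the nonlinear fit's covariance) is
    what lets a titration's lifetime Stern-Volmer fit weight its points and
    propagate the shared tau0 uncertainty.
    """

    tau: float
    amplitude: float
    baseline_offset: float
    rss: float
    tau_stderr: float = 0.0

    def __post_init__(self):
        if not self.tau > 0:
            raise DomainError("tau must be > 0")
        if self.rss < 0 or self.tau_stderr < 0:
            raise DomainError("rss and tau_stderr must be >= 0")


def normalize_trace(trace: DecayTrace) -> DecayTrace:
    """Divide intensities by their maximum (I/Imax); idempotent."""
    i = np.asarray(trace.intensities, float)
    peak = float(i.max())
    if peak <= 0:
        raise DomainError("cannot normalize a trace with nonpositive maximum")
    return DecayTrace(
        times=trace.times,
        intensities=tuple((i / peak).tolist()),
        quencher_concentration=trace.quencher_concentration,
    )


def _initial_guess(t: np.ndarray, i: np.ndarray) -> Tuple[float, float, float]:
    """Log-linear initializer on baseline-subtracted early samples."""
    b0 = float(i[-max(3, len(i) // 10):].mean())
    shifted = i - b0
    # Early portion, before the signal sinks into the offset noise.
    head = shifted[: max(5, len(i) // 3)]
    t_head = t[: len(head)]
    mask = head > max(1e-12, 0.01 * float(shifted.max()))
    if mask.sum() < 3:
        mask = head > 0
    if mask.sum() < 2:
        raise FitConvergenceError(
            "cannot initialize decay fit: too few positive baseline-subtracted samples",
            {"offset_guess": b0, "positive_samples": int(mask.sum())},
        )
    slope, intercept = np.polyfit(t_head[mask], np.log(head[mask]), 1)
    tau0 = -1.0 / slope if slope < 0 else float(t[-1] - t[0])
    return float(np.exp(intercept)), float(tau0), b0


def fit_decay(trace: DecayTrace) -> LifetimeFit:
    """Least-squares fit of I(t) = A exp(-t/tau) + B."""
    t, i = trace.arrays()
    a0, tau0, b0 = _initial_guess(t, i)

    def model(tt, a, tau, b):
        return a * np.exp(-tt / tau) + b

    try:
        popt, pcov = optimize.curve_fit(
            model, t, i, p0=[a0, tau0, b0], maxfev=10000,
            bounds=([0.0, 1e-12, -np.inf], [np.inf, np.inf, np.inf]),
        )
    except (RuntimeError, optimize.OptimizeWarning) as exc:
        raise FitConvergenceError(
            f"decay fit did not converge: {exc}",
            {"a0": a0, "tau0": tau0, "b0": b0},
        ) from exc
    a, tau, b = (float(v) for v in popt)
    rss = float(np.sum((model(t, a, tau, b) - i) ** 2))
    tau_se = float(np.sqrt(pcov[1, 1])) if np.isfinite(pcov[1, 1]) else 0.0
    return LifetimeFit(tau=tau, amplitude=a, baseline_offset=b, rss=rss, tau_stderr=tau_se)


def lifetime_sv(
    fits: Sequence[Tuple[float, LifetimeFit]],
    config: Optional[FitConfig] = None,
    unit: ConcentrationUnit = ConcentrationUnit.MOLAR,
) -> SVFitResult:
    """Slope-only weighted fit of tau0/tau - 1 against concentration.

    Requires an unquenched reference (concentration 0) whose lifetime serves
    as tau0.  Reuses the intensity pipeline's regression, so the result
    carries the same stderr/CI/Pearson-R semantics: points are weighted by
    the inverse of their own lifetime variance contribution, and the tau0
    uncertainty — which rescales every ratio in unison — enters the slope
    stderr as a common-mode term.
    """
    if len(fits) < 3:
        raise InsufficientPointsError("lifetime Stern-Volmer requires >= 3 concentrations")
    zero = [f for c, f in fits if c == 0]
    if not zero:
        raise DomainError("missing the unquenched (concentration 0) reference lifetime")
    tau0 = float(np.mean([f.tau for f in zero]))
    var_tau0 = float(np.sum([f.tau_stderr**2 for f in zero])) / len(zero) ** 2

    raw = []
    for conc, f in fits:
        if conc < 0:
            raise DomainError("concentrations must be >= 0")
        y = tau0 / f.tau
        indep = y**2 * (f.tau_stderr / f.tau) ** 2
        var_y = indep + y**2 * var_tau0 / tau0**2
        raw.append((conc, f, y, indep, var_y))
    positive = [r[3] for r in raw if r[3] > 0]
    fallback = 1.0 / min(positive) if positive else 1.0
    points = [
        QuenchRatioPoint(
            q=conc,
            intensity_I=f.tau,
            var_I=f.tau_stderr**2,
            ratio_y=y,
            var_y=var_y,
            weight=1.0 / indep if indep > 0 else fallback,
            unit=unit,
            well_id=f"trace{idx}",
        )
        for idx, (conc, f, y, indep, var_y) in enumerate(raw)
    ]
    baseline = None
    if var_tau0 > 0:
        from .preprocess import SensorBaseline

        baseline = SensorBaseline(
            mean_I0=tau0, variance_I0=var_tau0, n=1, variance_of_mean=var_tau0
        )
    return fit_ksv(points, config, baseline=baseline)


def titration_concentrations(
    added_volumes_uL: Sequence[float], stock_concentration: float, v0_uL: float
) -> List[float]:
    """Cumulative quencher concentrations for sequential stock additions.

    Accounts for volume growth: after additions summing to v_add, the
    concentration is stock * v_add / (v0 + v_add).  The leading value (no
    addition yet) is 0.
    """
    if not v0_uL > 0:
        raise DomainError("initial volume must be > 0")
    concs = [0.0]
    cum = 0.0
    for v in added_volumes_uL:
        if v < 0:
            raise DomainError("added volumes must be >= 0")
        cum += v
        concs.append(stock_concentration * cum / (v0_uL + cum))
    return concs
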
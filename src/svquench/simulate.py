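"""Seeded synthetic plate and decay-trace generator.

Emulates the statistical structure of the serial-dilution assay: a 2-fold
dilution series read before and after sensor addition, biological x technical
replicate wells, media blanks and sensor-only controls, an intrinsically
fluorescent quencher whose baseline signal is linear in concentration, the
~10% dilution caused by sensor addition, and multiplicative Gaussian
measurement error (3% by default).  Every reading is generated as

    pre  = blank + g * q_pre                                  (times 1 + eps)
    post = blank + f * g * q_pre + I0 / (1 + K * f * q_pre)   (times 1 + eps)

with g the intrinsic-fluorescence slope, f the dilution factor, and
eps ~ Normal(0, noise_fraction) independent per reading.  An optional
inner-filter term attenuates the sensor component at high concentration to
exercise the exclusion rule.

The generator is the ground truth for the pipeline's end-to-end tests: with
zero noise, analyze_plate recovers ``true_ksv`` exactly for any
intrinsic-fluorescence slope and any dilution factor.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Optional, Tuple

import numpy as np

from .errors import DomainError
from .model import (
    ConcentrationUnit,
    DilutionSeries,
    PlateTable,
    QuencherSpec,
    SensorKind,
    SensorSpec,
    WellRecord,
    WellRole,
    sv_ratio,
)

__all__ = ["SimConfig", "simulate_plate", "simulate_decay", "fixture_suite"]


@dataclass(frozen=True)
class SimConfig:
    """Generating parameters for one synthetic plate.

    Defaults reproduce the standard assay: a 6-concentration 2-fold series
    (neat down to 1/32 in fold-dilution units), biological and technical
    duplicates, 3% multiplicative Gaussian read noise, and the 11 uL-into-
    100 uL sensor addition (f = 100/111).
    """

    true_ksv: float = 1.0
    unit: ConcentrationUnit = ConcentrationUnit.FOLD_DILUTION
    i0_true: float = 10000.0
    noise_fraction: float = 0.03
    dilution: DilutionSeries = field(
        default_factory=lambda: DilutionSeries.from_design(1.0, 2.0, 5)
    )
    n_bio_replicates: int = 2
    n_tech_replicates: int = 2
    intrinsic_slope: float = 0.0
    blank_mean: float = 100.0
    v_initial: float = 100.0
    v_added: float = 11.0
    n_blank_wells: int = 4
    n_control_wells: int = 4
    inner_filter_strength: float = 0.0
    additive_noise: bool = False
    seed: int = 0
    quencher_name: str = "synthetic quencher"
    sensor_name: str = "synthetic sensor"
    intrinsically_fluorescent: Optional[bool] = None

    def __post_init__(self):
        if self.true_ksv < 0 or self.noise_fraction < 0 or self.intrinsic_slope < 0:
            raise DomainError("true_ksv, noise_fraction and intrinsic_slope must be >= 0")
        if self.n_bio_replicates < 1 or self.n_tech_replicates < 1:
            raise DomainError("replicate counts must be >= 1")
        if not (self.v_initial > 0) or self.v_added < 0:
            raise DomainError("volumes must be positive (added volume nonnegative)")
        if not self.i0_true > 0:
            raise DomainError("i0_true must be > 0")


def _noisy(rng: np.random.Generator, value: float, cfg: SimConfig) -> float:
    eps = rng.normal(0.0, cfg.noise_fraction) if cfg.noise_fraction > 0 else 0.0
    if cfg.additive_noise:
        return value + cfg.i0_true * eps
    return value * (1.0 + eps)


def simulate_plate(cfg: SimConfig) -> PlateTable:
    """Generate one plate, fully reproducible from ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    f = cfg.v_initial / (cfg.v_initial + cfg.v_added)
    wells = []
    for i in range(cfg.n_blank_wells):
        wells.append(
            WellRecord(
                well_id=f"BLK{i + 1}",
                role=WellRole.BLANK,
                concentration_pre=None,
                bio_replicate="-",
                tech_replicate=str(i + 1),
                pre_intensity=_noisy(rng, cfg.blank_mean, cfg),
                post_intensity=_noisy(rng, cfg.blank_mean, cfg),
            )
        )
    for i in range(cfg.n_control_wells):
        wells.append(
            WellRecord(
                well_id=f"CTL{i + 1}",
                role=WellRole.SENSOR_ONLY_CONTROL,
                concentration_pre=None,
                bio_replicate="-",
                tech_replicate=str(i + 1),
                pre_intensity=_noisy(rng, cfg.blank_mean, cfg),
                post_intensity=_noisy(rng, cfg.blank_mean + cfg.i0_true, cfg),
            )
        )
    for ci, q_pre in enumerate(cfg.dilution.concentrations):
        q_post = f * q_pre
        sensor_signal = cfg.i0_true * sv_ratio(cfg.true_ksv, q_post)
        if cfg.inner_filter_strength > 0:
            sensor_signal *= np.exp(-cfg.inner_filter_strength * q_post)
        pre_true = cfg.blank_mean + cfg.intrinsic_slope * q_pre
        post_true = cfg.blank_mean + f * cfg.intrinsic_slope * q_pre + sensor_signal
        for b in range(cfg.n_bio_replicates):
            for t in range(cfg.n_tech_replicates):
                wells.append(
                    WellRecord(
                        well_id=f"S{ci + 1}B{b + 1}T{t + 1}",
                        role=WellRole.SAMPLE,
                        concentration_pre=q_pre,
                        bio_replicate=str(b + 1),
                        tech_replicate=str(t + 1),
                        pre_intensity=_noisy(rng, pre_true, cfg),
                        post_intensity=_noisy(rng, post_true, cfg),
                    )
                )
    quencher = QuencherSpec(
        name=cfg.quencher_name,
        concentration_unit=cfg.unit,
        intrinsically_fluorescent=cfg.intrinsically_fluorescent,
        stock_concentration=max(cfg.dilution.concentrations),
    )
    sensor = SensorSpec(name=cfg.sensor_name, kind=SensorKind.SOLUBLE)
    return PlateTable(
        wells=tuple(wells),
        sensor=sensor,
        quencher=quencher,
        dilution_volume_initial=cfg.v_initial,
        dilution_volume_added=cfg.v_added,
        metadata={"seed": cfg.seed, "true_ksv": cfg.true_ksv},
    )


def simulate_decay(
    tau: float,
    noise_fraction: float = 0.0,
    sampling: Tuple[float, float] = (25.0, 100),
    seed: int = 0,
    quencher_concentration: float = 0.0,
):
    """A mono-exponential phosphorescence decay I(t) = exp(-t/tau) * (1 + eps)."""
    from .lifetime import DecayTrace

    if not tau > 0:
        raise DomainError("tau must be > 0")
    t_max, n_points = sampling
    rng = np.random.default_rng(seed)
    times = np.linspace(0.0, t_max, int(n_points))
    clean = np.exp(-times / tau)
    if noise_fraction > 0:
        clean = clean * (1.0 + rng.normal(0.0, noise_fraction, size=clean.shape))
    return DecayTrace(
        times=tuple(times.tolist()),
        intensities=tuple(clean.tolist()),
        quencher_concentration=quencher_concentration,
    )


def fixture_suite() -> Dict[str, Tuple[SimConfig, PlateTable]]:
    """Canonical named fixtures regenerated deterministically from their configs.

    - "standard_quencher": K = 1 per fold dilution, 3% noise (the reference
      simulation the pipeline is validated against);
    - "non_quencher": K = 0, same noise;
    - "fluorescent_quencher": strong intrinsic fluorescence (pyocyanin-like);
    - "early_protocol": 1 uL sensor addition without withdrawal (f = 100/101).
    """
    configs = {
        "standard_quencher": SimConfig(true_ksv=1.0, seed=11),
        "non_quencher": SimConfig(true_ksv=0.0, seed=12),
        "fluorescent_quencher": SimConfig(
            true_ksv=2.0,
            intrinsic_slope=5000.0,
            intrinsically_fluorescent=True,
            seed=13,
            quencher_name="synthetic fluorescent quencher",
        ),
        "early_protocol": SimConfig(true_ksv=1.0, v_added=1.0, seed=14),
    }
    return {name: (cfg, simulate_plate(cfg)) for name, cfg in configs.items()}
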
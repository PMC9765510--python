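import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from svquench.model import (
    ConcentrationUnit,
    PlateTable,
    QuencherSpec,
    SensorSpec,
    WellRecord,
    WellRole,
)

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


def make_plate(
    sample_rows,
    blanks_pre=(100.0, 100.0),
    blanks_post=(100.0, 100.0),
    controls_post=(10100.0, 10100.0),
    controls_pre=(100.0, 100.0),
    v_initial=90.0,
    v_added=10.0,
    unit=ConcentrationUnit.FOLD_DILUTION,
    fluorescent=None,
):
    """Hand-build a plate from (concentration, pre, post) sample tuples.

    Defaults give an exact dilution factor f = 90/100 = 0.9 and a clean
    sensor baseline I0 = 10000.
    """
    wells = []
    for i, (bp, bq) in enumerate(zip(blanks_pre, blanks_post)):
        wells.append(
            WellRecord(f"BLK{i}", WellRole.BLANK, None, "-", str(i), bp, bq)
        )
    for i, (cp, cq) in enumerate(zip(controls_pre, controls_post)):
        wells.append(
            WellRecord(f"CTL{i}", WellRole.SENSOR_ONLY_CONTROL, None, "-", str(i), cp, cq)
        )
    for i, (conc, pre, post) in enumerate(sample_rows):
        wells.append(
            WellRecord(f"S{i}", WellRole.SAMPLE, conc, "1", str(i), pre, post)
        )
    return PlateTable(
        wells=tuple(wells),
        sensor=SensorSpec(name="test sensor"),
        quencher=QuencherSpec(
            name="test quencher",
            concentration_unit=unit,
            intrinsically_fluorescent=fluorescent,
            stock_concentration=max(c for c, _, _ in sample_rows)
            if unit is ConcentrationUnit.MOLAR
            else 1.0,
        ),
        dilution_volume_initial=v_initial,
        dilution_volume_added=v_added,
    )


@pytest.fixture
def exact_quencher_plate():
    """Noiseless K = 1 plate, f = 0.9, non-fluorescent quencher, I0 = 10000.

    Sample wells follow post = blank + I0 / (1 + K * f * q_pre) with
    pre = blank, so the pipeline must recover y = 1 + 0.9 * q_pre exactly.
    """
    rows = []
    for q in (1.0, 0.5, 0.25, 0.125):
        for _ in range(2):
            rows.append((q, 100.0, 100.0 + 10000.0 / (1.0 + 0.9 * q)))
    return make_plate(rows)


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)
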
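"""Readers and writers for plate tables, decay traces and results.

The canonical plate format is a long ("tidy") CSV with one row per well per
phase:

    well_id,role,phase,intensity,concentration_pre,concentration_unit,bio_replicate,tech_replicate

Plate-level metadata (volumes, sensor and quencher identity) travels in
``# key=value`` comment lines preceding the header, so a plate file is fully
self-describing and round-trips byte-identically.  Concentrations are stored
pre-addition; the pipeline applies the dilution rescaling, never the file.
"""

from __future__ import annotations

import csv
import io as _io
import math
from pathlib import Path
from typing import Dict, List, Sequence, Union

from .errors import SchemaError
from .lifetime import DecayTrace
from .model import (
    ConcentrationUnit,
    PlateTable,
    QuencherSpec,
    SensorKind,
    SensorSpec,
    WellRecord,
    WellRole,
)

__all__ = [
    "read_plate_csv",
    "write_plate_csv",
    "write_results_csv",
    "write_points_csv",
    "read_decay_csv",
    "write_decay_csv",
]

PLATE_COLUMNS = [
    "well_id",
    "role",
    "phase",
    "intensity",
    "concentration_pre",
    "concentration_unit",
    "bio_replicate",
    "tech_replicate",
]

RESULT_COLUMNS = [
    "quencher",
    "sensor",
    "unit",
    "k_sv",
    "stderr",
    "ci_low",
    "ci_high",
    "pearson_r",
    "n_included",
    "n_excluded",
    "classification",
    "exclusion_reasons",
]

PathLike = Union[str, Path]


def _fmt(x: float) -> str:
    """Shortest exact decimal representation (round-trips via float())."""
    return repr(float(x))


def _fmt6(x: float) -> str:
    """Fixed 6-significant-digit formatting for result tables."""
    if isinstance(x, float) and math.isnan(x):
        return "nan"
    return f"{float(x):.6g}"


def read_plate_csv(
    path: PathLike,
    sensor: SensorSpec | None = None,
    quencher: QuencherSpec | None = None,
) -> PlateTable:
    """Parse a long-format plate CSV into a validated :class:`PlateTable`.

    Metadata comment lines (``# key=value``) supply volumes and sensor /
    quencher names; explicit ``sensor`` / ``quencher`` arguments override
    them.  Negative intensities are rejected with the offending row number.
    """
    path = Path(path)
    meta: Dict[str, str] = {}
    with path.open(newline="") as fh:
        lines = fh.read().splitlines()
    data_lines = []
    for ln in lines:
        if ln.startswith("#"):
            body = ln.lstrip("#").strip()
            if "=" in body:
                k, v = body.split("=", 1)
                meta[k.strip()] = v.strip()
        elif ln.strip():
            data_lines.append(ln)
    if not data_lines:
        raise SchemaError(f"{path}: empty plate file")
    reader = csv.DictReader(_io.StringIO("\n".join(data_lines)))
    missing = [c for c in PLATE_COLUMNS if c not in (reader.fieldnames or [])]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")

    rows: Dict[str, dict] = {}
    units = set()
    for lineno, row in enumerate(reader, start=2):
        wid = row["well_id"]
        try:
            role = WellRole(row["role"])
        except ValueError:
            raise SchemaError(f"{path}:{lineno}: unknown role {row['role']!r}") from None
        phase = row["phase"]
        if phase not in ("pre", "post"):
            raise SchemaError(f"{path}:{lineno}: phase must be 'pre' or 'post', got {phase!r}")
        try:
            intensity = float(row["intensity"])
        except ValueError:
            raise SchemaError(f"{path}:{lineno}: non-numeric intensity {row['intensity']!r}") from None
        if intensity < 0:
            raise SchemaError(f"{path}:{lineno}: negative intensity {intensity}")
        conc_raw = (row.get("concentration_pre") or "").strip()
        conc = float(conc_raw) if conc_raw else None
        unit_raw = (row.get("concentration_unit") or "").strip()
        if unit_raw:
            try:
                units.add(ConcentrationUnit(unit_raw))
            except ValueError:
                raise SchemaError(f"{path}:{lineno}: unknown concentration unit {unit_raw!r}") from None
        rec = rows.setdefault(
            wid,
            {
                "role": role,
                "concentration_pre": conc,
                "bio_replicate": row["bio_replicate"],
                "tech_replicate": row["tech_replicate"],
            },
        )
        if rec["role"] is not role:
            raise SchemaError(f"{path}:{lineno}: well {wid} changes role between rows")
        rec[phase] = intensity
    if len(units) > 1:
        raise SchemaError(
            f"{path}: plate mixes concentration units: {sorted(u.value for u in units)}"
        )
    unit = next(iter(units)) if units else ConcentrationUnit.FOLD_DILUTION

    wells = []
    for wid, rec in rows.items():
        if "pre" not in rec or "post" not in rec:
            raise SchemaError(f"{path}: well {wid} lacks a '{'pre' if 'pre' not in rec else 'post'}' row")
        wells.append(
            WellRecord(
                well_id=wid,
                role=rec["role"],
                concentration_pre=rec["concentration_pre"],
                bio_replicate=rec["bio_replicate"],
                tech_replicate=rec["tech_replicate"],
                pre_intensity=rec["pre"],
                post_intensity=rec["post"],
            )
        )

    if sensor is None:
        sensor = SensorSpec(
            name=meta.get("sensor", "unknown sensor"),
            kind=SensorKind(meta.get("sensor_kind", "soluble")),
        )
    if quencher is None:
        concs = [w.concentration_pre for w in wells if w.concentration_pre is not None]
        quencher = QuencherSpec(
            name=meta.get("quencher", "unknown quencher"),
            concentration_unit=unit,
            intrinsically_fluorescent={"true": True, "false": False}.get(
                meta.get("intrinsically_fluorescent", "").lower()
            ),
            stock_concentration=max(concs) if concs else 1.0,
        )
    return PlateTable(
        wells=tuple(wells),
        sensor=sensor,
        quencher=quencher,
        dilution_volume_initial=float(meta.get("v_initial_uL", 100.0)),
        dilution_volume_added=float(meta.get("v_added_uL", 11.0)),
        metadata={k: v for k, v in meta.items()},
    )


def write_plate_csv(plate: PlateTable, path: PathLike) -> None:
    """Write a plate in the canonical long format (deterministic byte layout)."""
    path = Path(path)
    out = []
    out.append(f"# sensor={plate.sensor.name}")
    out.append(f"# sensor_kind={plate.sensor.kind.value}")
    out.append(f"# quencher={plate.quencher.name}")
    if plate.quencher.intrinsically_fluorescent is not None:
        out.append(
            f"# intrinsically_fluorescent={'true' if plate.quencher.intrinsically_fluorescent else 'false'}"
        )
    out.append(f"# v_initial_uL={_fmt(plate.dilution_volume_initial)}")
    out.append(f"# v_added_uL={_fmt(plate.dilution_volume_added)}")
    out.append(",".join(PLATE_COLUMNS))
    unit = plate.quencher.concentration_unit.value
    for w in plate.wells:
        conc = "" if w.concentration_pre is None else _fmt(w.concentration_pre)
        cunit = "" if w.concentration_pre is None else unit
        for phase, intensity in (("pre", w.pre_intensity), ("post", w.post_intensity)):
            out.append(
                f"{w.well_id},{w.role.value},{phase},{_fmt(intensity)},{conc},{cunit},"
                f"{w.bio_replicate},{w.tech_replicate}"
            )
    path.write_text("\n".join(out) + "\n")


def write_results_csv(results: Sequence, path: PathLike) -> None:
    """Write fit results, one row per plate, sorted by (quencher, sensor).

    Non-quenchers keep their fitted slope and CI in the table alongside the
    "non_quencher" label, so weak fits remain inspectable.
    """
    if not results:
        raise ValueError("results must be non-empty")
    path = Path(path)
    rows = []
    for r in sorted(results, key=lambda r: (r.quencher_name, r.sensor_name)):
        rows.append(
            [
                r.quencher_name,
                r.sensor_name,
                r.unit.slope_label,
                _fmt6(r.k_sv),
                _fmt6(r.stderr),
                _fmt6(r.ci95[0]),
                _fmt6(r.ci95[1]),
                _fmt6(r.pearson_r),
                str(r.n_included),
                str(r.n_excluded),
                r.classification.value if r.classification else "unclassified",
                ";".join(r.exclusion_reasons),
            ]
        )
    lines = [",".join(RESULT_COLUMNS)] + [",".join(row) for row in rows]
    path.write_text("\n".join(lines) + "\n")


def write_points_csv(points: Sequence, path: PathLike) -> None:
    """Write the per-plate Stern-Volmer point table (q, I0/I, variance, exclusion)."""
    path = Path(path)
    lines = ["well_id,q,ratio_y,var_y,weight,excluded,reason"]
    for p in points:
        lines.append(
            f"{p.well_id},{_fmt6(p.q)},{_fmt6(p.ratio_y)},{_fmt6(p.var_y)},"
            f"{_fmt6(p.weight)},{'true' if p.excluded else 'false'},{p.reason or ''}"
        )
    path.write_text("\n".join(lines) + "\n")


def read_decay_csv(path: PathLike, quencher_concentration: float = 0.0) -> DecayTrace:
    """Read a two-column (time_us, intensity) decay trace."""
    path = Path(path)
    times: List[float] = []
    intens: List[float] = []
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not {"time_us", "intensity"} <= set(reader.fieldnames):
            raise SchemaError(f"{path}: decay CSV requires columns time_us, intensity")
        for row in reader:
            times.append(float(row["time_us"]))
            intens.append(float(row["intensity"]))
    return DecayTrace(
        times=tuple(times), intensities=tuple(intens), quencher_concentration=quencher_concentration
    )


def write_decay_csv(trace: DecayTrace, path: PathLike) -> None:
    path = Path(path)
    lines = ["time_us,intensity"]
    for t, i in zip(trace.times, trace.intensities):
        lines.append(f"{_fmt(t)},{_fmt(i)}")
    path.write_text("\n".join(lines) + "\n")
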
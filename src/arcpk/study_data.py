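"""Domain data model and CSV I/O for the fluid-therapy renal-function study.

The study design is a two-occasion (baseline M1, re-measurement M2) cohort of
piglets split into a control and a fluid-treated arm.  On each occasion every
animal receives consecutive IV boluses of three renal markers — iohexol (GFR),
para-aminohippuric acid (PAH, effective renal plasma flow) and amikacin (a
renally excreted antibiotic) — followed by a 13-point plasma sampling schedule
and timed urine collection (PAH only).  Hematology, body temperature and
hematocrit accompany each animal.

Four plain CSV tables carry a dataset on disk:

``plasma.csv``
    animal_id, group, occasion, analyte, dose_mg_per_kg, body_weight_kg,
    time_h, conc_ug_per_ml, blq, lloq_ug_per_ml
``urine.csv``
    animal_id, occasion, start_h, end_h, volume_ml, conc_ug_per_ml, leaked
``animals.csv``
    animal_id, group, occasion, body_weight_kg, temp_c, leukocytes_per_ul,
    neutrophils_per_ul, lymphocytes_per_ul, monocytes_per_ul
``hematocrit.csv``
    animal_id, time_since_fluid_start_h, hct_pct

All times are hours since dose (plasma/urine) or since fluid start
(hematocrit); concentrations are µg/mL; body weight kg.  ``read_study_tables``
and ``write_study_tables`` round-trip a dataset exactly at value level.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .exceptions import SchemaError, ValidationError

__all__ = [
    "ANALYTES",
    "OCCASIONS",
    "GROUPS",
    "DoseEvent",
    "ConcentrationRecord",
    "PlasmaProfile",
    "UrineInterval",
    "Hematology",
    "AnimalRecord",
    "StudyDataset",
    "read_study_tables",
    "write_study_tables",
]

#: Registry of the three marker drugs with study doses (mg/kg) and assay
#: lower limits of quantification (µg/mL).  Extensible: unknown analytes are
#: accepted if registered here first.
ANALYTES: dict[str, dict[str, float]] = {
    "iohexol": {"dose_mg_per_kg": 64.7, "lloq_ug_per_ml": 0.25},
    "pah": {"dose_mg_per_kg": 10.0, "lloq_ug_per_ml": 0.25},
    "amikacin": {"dose_mg_per_kg": 7.5, "lloq_ug_per_ml": 0.50},
}

OCCASIONS = ("M1", "M2")
GROUPS = ("control", "treatment")

#: 13-point plasma sampling schedule, hours post-dose (5 min ... 10 h).
SAMPLING_TIMES_H = (
    5 / 60, 10 / 60, 20 / 60, 30 / 60, 45 / 60, 1.0,
    1.5, 2.0, 4.0, 6.0, 8.0, 10.0,
)
# note: schedule above lists 12 post-dose samples; the 13th study sample is
# the pre-dose (t = 0) draw, retained in the data model but never fitted.


@dataclass(frozen=True)
class DoseEvent:
    """A single IV bolus of one marker on one occasion."""

    analyte: str
    dose_per_bw: float  # mg/kg body weight
    occasion: str
    route: str = "IV bolus"

    def __post_init__(self) -> None:
        if self.analyte not in ANALYTES:
            raise ValidationError(f"unknown analyte {self.analyte!r}; register it in ANALYTES")
        if not self.dose_per_bw > 0:
            raise ValidationError(f"dose_per_bw must be > 0, got {self.dose_per_bw}")
        if self.occasion not in OCCASIONS:
            raise ValidationError(f"occasion must be one of {OCCASIONS}, got {self.occasion!r}")


@dataclass(frozen=True)
class ConcentrationRecord:
    """One timed plasma sample; ``blq`` flags a censored (below-LLOQ) value.

    ``concentration`` is None for BLQ records — a censored observation has no
    numeric value, only the information that it fell below ``lloq``.
    """

    time_h: float
    concentration: float | None
    lloq: float
    blq: bool = False

    def __post_init__(self) -> None:
        if self.time_h < 0:
            raise ValidationError(f"time must be >= 0, got {self.time_h}")
        if not self.lloq > 0:
            raise ValidationError(f"lloq must be > 0, got {self.lloq}")
        if self.blq:
            if self.concentration is not None:
                raise ValidationError("BLQ record must not carry a concentration")
        else:
            if self.concentration is None or not self.concentration >= 0:
                raise ValidationError(
                    f"quantifiable record needs concentration >= 0, got {self.concentration}"
                )


@dataclass(frozen=True)
class PlasmaProfile:
    """One animal x analyte x occasion concentration-time series."""

    animal_id: str
    group: str
    occasion: str
    dose: DoseEvent
    body_weight: float  # kg at this occasion
    records: tuple[ConcentrationRecord, ...]

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValidationError(f"group must be one of {GROUPS}, got {self.group!r}")
        if not self.body_weight > 0:
            raise ValidationError(f"body_weight must be > 0, got {self.body_weight}")
        times = [r.time_h for r in self.records]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValidationError(
                f"times must be strictly increasing for {self.animal_id}/{self.dose.analyte}/{self.occasion}"
            )

    @property
    def analyte(self) -> str:
        return self.dose.analyte

    def quantifiable(self) -> tuple[ConcentrationRecord, ...]:
        """Post-dose, non-censored records (the fittable observations)."""
        return tuple(r for r in self.records if not r.blq and r.time_h > 0)


@dataclass(frozen=True)
class UrineInterval:
    """A timed urine collection interval with measured volume and concentration."""

    start_h: float
    end_h: float
    volume_ml: float
    conc_ug_per_ml: float
    leaked: bool = False

    def __post_init__(self) -> None:
        if self.start_h < 0 or self.end_h <= self.start_h:
            raise ValidationError(
                f"need end > start >= 0, got [{self.start_h}, {self.end_h}]"
            )
        if self.volume_ml < 0:
            raise ValidationError(f"volume must be >= 0, got {self.volume_ml}")
        if self.conc_ug_per_ml < 0:
            raise ValidationError(f"concentration must be >= 0, got {self.conc_ug_per_ml}")


@dataclass(frozen=True)
class Hematology:
    leukocytes: float
    neutrophils: float
    lymphocytes: float
    monocytes: float

    def __post_init__(self) -> None:
        for name in ("leukocytes", "neutrophils", "lymphocytes", "monocytes"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} count must be >= 0")


@dataclass
class AnimalRecord:
    """Per-animal physiology: weights, temperature, hematology, hematocrit."""

    animal_id: str
    group: str
    body_weight: dict[str, float] = field(default_factory=dict)      # occasion -> kg
    body_temperature: dict[str, float] = field(default_factory=dict)  # occasion -> degC
    hematology: dict[str, Hematology] = field(default_factory=dict)   # occasion -> panel
    hematocrit: list[tuple[float, float]] = field(default_factory=list)  # (h since fluid start, %)

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValidationError(f"group must be one of {GROUPS}, got {self.group!r}")
        for _, hct in self.hematocrit:
            if not 0 < hct < 100:
                raise ValidationError(f"hematocrit must be in (0, 100), got {hct}")


@dataclass
class StudyDataset:
    """Validated, typed container for one complete study dataset."""

    animals: dict[str, AnimalRecord] = field(default_factory=dict)
    profiles: list[PlasmaProfile] = field(default_factory=list)
    urine: dict[tuple[str, str], list[UrineInterval]] = field(default_factory=dict)

    def profile(self, animal_id: str, analyte: str, occasion: str) -> PlasmaProfile:
        for p in self.profiles:
            if p.animal_id == animal_id and p.analyte == analyte and p.occasion == occasion:
                return p
        raise KeyError((animal_id, analyte, occasion))

    def animal_ids(self, group: str | None = None) -> list[str]:
        ids = sorted(self.animals)
        if group is None:
            return ids
        return [a for a in ids if self.animals[a].group == group]

    def validate(self) -> None:
        """Cross-record checks: urine intervals non-overlapping, groups consistent."""
        for (animal, occ), intervals in self.urine.items():
            ordered = sorted(intervals, key=lambda iv: iv.start_h)
            for a, b in zip(ordered, ordered[1:]):
                if b.start_h < a.end_h - 1e-12:
                    raise ValidationError(
                        f"overlapping urine intervals for {animal}/{occ}: "
                        f"[{a.start_h},{a.end_h}] and [{b.start_h},{b.end_h}]"
                    )
        for p in self.profiles:
            rec = self.animals.get(p.animal_id)
            if rec is not None and rec.group != p.group:
                raise ValidationError(
                    f"group mismatch for {p.animal_id}: profile says {p.group}, "
                    f"animal table says {rec.group}"
                )


# ---------------------------------------------------------------------------
# Tabular I/O
# ---------------------------------------------------------------------------

_PLASMA_COLS = [
    "animal_id", "group", "occasion", "analyte", "dose_mg_per_kg",
    "body_weight_kg", "time_h", "conc_ug_per_ml", "blq", "lloq_ug_per_ml",
]
_URINE_COLS = [
    "animal_id", "occasion", "start_h", "end_h", "volume_ml",
    "conc_ug_per_ml", "leaked",
]
_ANIMAL_COLS = [
    "animal_id", "group", "occasion", "body_weight_kg", "temp_c",
    "leukocytes_per_ul", "neutrophils_per_ul", "lymphocytes_per_ul",
    "monocytes_per_ul",
]
_HCT_COLS = ["animal_id", "time_since_fluid_start_h", "hct_pct"]

FILENAMES = {
    "plasma": "plasma.csv",
    "urine": "urine.csv",
    "animals": "animals.csv",
    "hematocrit": "hematocrit.csv",
}


def _require_columns(df: pd.DataFrame, cols: Iterable[str], table: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{table}: missing required column(s) {missing}")


def _read_csv(path: Path, table: str) -> pd.DataFrame:
    if not path.exists():
        raise SchemaError(f"{table}: file not found: {path}")
    return pd.read_csv(path, float_precision="round_trip")


def read_study_tables(directory: str | Path) -> StudyDataset:
    """Read the four canonical CSV tables from *directory* into a dataset.

    BLQ plasma cells (``blq == 1``) may leave ``conc_ug_per_ml`` empty; the
    record is parsed to a censored observation with no numeric concentration.
    Raises :class:`SchemaError` for missing files/columns and
    :class:`ValidationError` (with row provenance) for invalid values.
    """
    directory = Path(directory)
    plasma = _read_csv(directory / FILENAMES["plasma"], "plasma")
    urine = _read_csv(directory / FILENAMES["urine"], "urine")
    animals = _read_csv(directory / FILENAMES["animals"], "animals")
    hct = _read_csv(directory / FILENAMES["hematocrit"], "hematocrit")

    _require_columns(plasma, _PLASMA_COLS, "plasma")
    _require_columns(urine, _URINE_COLS, "urine")
    _require_columns(animals, _ANIMAL_COLS, "animals")
    _require_columns(hct, _HCT_COLS, "hematocrit")

    ds = StudyDataset()

    # animals.csv: one row per animal x occasion
    for idx, row in animals.iterrows():
        aid = str(row["animal_id"])
        occ = str(row["occasion"])
        if occ not in OCCASIONS:
            raise ValidationError(f"bad occasion {occ!r}", row=int(idx), table="animals")
        rec = ds.animals.setdefault(aid, AnimalRecord(animal_id=aid, group=str(row["group"])))
        try:
            rec.body_weight[occ] = float(row["body_weight_kg"])
            rec.body_temperature[occ] = float(row["temp_c"])
            rec.hematology[occ] = Hematology(
                leukocytes=float(row["leukocytes_per_ul"]),
                neutrophils=float(row["neutrophils_per_ul"]),
                lymphocytes=float(row["lymphocytes_per_ul"]),
                monocytes=float(row["monocytes_per_ul"]),
            )
        except ValidationError as exc:
            raise ValidationError(str(exc), row=int(idx), table="animals") from exc

    for idx, row in hct.iterrows():
        aid = str(row["animal_id"])
        if aid not in ds.animals:
            raise ValidationError(f"unknown animal {aid!r}", row=int(idx), table="hematocrit")
        t, v = float(row["time_since_fluid_start_h"]), float(row["hct_pct"])
        if not 0 < v < 100:
            raise ValidationError(f"hematocrit out of (0,100): {v}", row=int(idx), table="hematocrit")
        ds.animals[aid].hematocrit.append((t, v))

    # plasma.csv: group rows into profiles
    key_cols = ["animal_id", "analyte", "occasion"]
    for idx, row in plasma.iterrows():
        if float(row["time_h"]) < 0:
            raise ValidationError(f"negative time {row['time_h']}", row=int(idx), table="plasma")
    for (aid, analyte, occ), grp in plasma.groupby(key_cols, sort=True):
        grp = grp.sort_values("time_h")
        first = grp.iloc[0]
        dose = DoseEvent(analyte=str(analyte), dose_per_bw=float(first["dose_mg_per_kg"]),
                         occasion=str(occ))
        records = []
        for idx, row in grp.iterrows():
            blq = bool(int(row["blq"]))
            conc = row["conc_ug_per_ml"]
            conc_val = None if blq else float(conc)
            if not blq and (conc is None or (isinstance(conc, float) and math.isnan(conc))):
                raise ValidationError("quantifiable row has empty concentration",
                                      row=int(idx), table="plasma")
            try:
                records.append(ConcentrationRecord(
                    time_h=float(row["time_h"]), concentration=conc_val,
                    lloq=float(row["lloq_ug_per_ml"]), blq=blq,
                ))
            except ValidationError as exc:
                raise ValidationError(str(exc), row=int(idx), table="plasma") from exc
        ds.profiles.append(PlasmaProfile(
            animal_id=str(aid), group=str(first["group"]), occasion=str(occ),
            dose=dose, body_weight=float(first["body_weight_kg"]),
            records=tuple(records),
        ))

    for idx, row in urine.iterrows():
        try:
            iv = UrineInterval(
                start_h=float(row["start_h"]), end_h=float(row["end_h"]),
                volume_ml=float(row["volume_ml"]),
                conc_ug_per_ml=float(row["conc_ug_per_ml"]),
                leaked=bool(int(row["leaked"])),
            )
        except ValidationError as exc:
            raise ValidationError(str(exc), row=int(idx), table="urine") from exc
        ds.urine.setdefault((str(row["animal_id"]), str(row["occasion"])), []).append(iv)

    ds.validate()
    return ds


def _profiles_frame(dataset: StudyDataset) -> pd.DataFrame:
    rows = []
    for p in sorted(dataset.profiles, key=lambda p: (p.animal_id, p.analyte, p.occasion)):
        for r in p.records:
            rows.append({
                "animal_id": p.animal_id, "group": p.group, "occasion": p.occasion,
                "analyte": p.analyte, "dose_mg_per_kg": p.dose.dose_per_bw,
                "body_weight_kg": p.body_weight, "time_h": r.time_h,
                "conc_ug_per_ml": r.concentration if not r.blq else None,
                "blq": int(r.blq), "lloq_ug_per_ml": r.lloq,
            })
    return pd.DataFrame(rows, columns=_PLASMA_COLS)


def write_study_tables(dataset: StudyDataset, directory: str | Path) -> dict[str, Path]:
    """Write *dataset* to the four canonical CSVs under *directory*.

    Inverse of :func:`read_study_tables` at value level: reading the written
    files reproduces the dataset exactly.  An empty dataset yields
    headers-only files.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    urine_rows = []
    for (aid, occ) in sorted(dataset.urine):
        for iv in sorted(dataset.urine[(aid, occ)], key=lambda iv: iv.start_h):
            urine_rows.append({
                "animal_id": aid, "occasion": occ, "start_h": iv.start_h,
                "end_h": iv.end_h, "volume_ml": iv.volume_ml,
                "conc_ug_per_ml": iv.conc_ug_per_ml, "leaked": int(iv.leaked),
            })

    animal_rows, hct_rows = [], []
    for aid in sorted(dataset.animals):
        rec = dataset.animals[aid]
        for occ in OCCASIONS:
            if occ not in rec.body_weight:
                continue
            h = rec.hematology.get(occ)
            animal_rows.append({
                "animal_id": aid, "group": rec.group, "occasion": occ,
                "body_weight_kg": rec.body_weight[occ],
                "temp_c": rec.body_temperature.get(occ),
                "leukocytes_per_ul": h.leukocytes if h else None,
                "neutrophils_per_ul": h.neutrophils if h else None,
                "lymphocytes_per_ul": h.lymphocytes if h else None,
                "monocytes_per_ul": h.monocytes if h else None,
            })
        for t, v in rec.hematocrit:
            hct_rows.append({"animal_id": aid, "time_since_fluid_start_h": t, "hct_pct": v})

    frames = {
        "plasma": _profiles_frame(dataset),
        "urine": pd.DataFrame(urine_rows, columns=_URINE_COLS),
        "animals": pd.DataFrame(animal_rows, columns=_ANIMAL_COLS),
        "hematocrit": pd.DataFrame(hct_rows, columns=_HCT_COLS),
    }
    paths = {}
    for name, frame in frames.items():
        path = directory / FILENAMES[name]
        # shortest round-trip float representation -> exact read/write identity
        frame.to_csv(path, index=False, float_format=lambda x: repr(float(x)))
        paths[name] = path
    return paths
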
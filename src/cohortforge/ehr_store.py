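"""Longitudinal patient-level data model: typed tables with CSV round-trip.

Three flat tables, keyed by an opaque patient identifier, emulate the
patient-level extract of a hospital data warehouse:

``patients``
    one row per patient: demographics, anthropometrics, vital status;
``events``
    dated clinical events on one of four dimensions (diagnosis, pharmacy,
    procedure, laboratory) with a care setting; pharmacy rows may carry the
    number of days the dispensing covers;
``encounters``
    dated hospital contacts with a care setting.

Tables are exchanged as headered CSV with ISO-8601 dates.  An unknown
categorical value is the literal string ``"unknown"``; a genuinely missing
optional field is an empty cell — the two are never conflated.  Duplicate
event rows (same patient, date, dimension, code and setting) are dropped at
load with a logged count, because claims extracts commonly repeat lines and
all cohort logic downstream is set-based.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SEX_LEVELS = ("female", "male", "unknown")
MARITAL_LEVELS = ("married", "unmarried", "unknown")
INCOME_LEVELS = ("normal", "low", "unknown")
DIMENSIONS = ("diagnosis", "pharmacy", "procedure", "laboratory")
CARE_SETTINGS = ("outpatient", "admission", "emergency")

PATIENT_COLUMNS = [
    "patient_id", "birth_date", "sex", "bmi",
    "marital_status", "income_level", "occupation", "death_date",
]
EVENT_COLUMNS = ["patient_id", "event_date", "dimension", "code", "setting", "duration_days"]
ENCOUNTER_COLUMNS = ["patient_id", "encounter_date", "setting"]

#: natural key of an event row; duplicates on it are dropped at load
EVENT_KEY = ["patient_id", "event_date", "dimension", "code", "setting"]

TABLE_FILES = {
    "patients": "patients.csv",
    "events": "events.csv",
    "encounters": "encounters.csv",
}


class DatasetError(ValueError):
    """Base class for dataset-level failures."""


class DatasetLoadError(DatasetError):
    """Fatal load failure carrying row-level diagnostics."""

    def __init__(self, message: str, diagnostics: Sequence[str] = ()):
        self.diagnostics = list(diagnostics)
        if self.diagnostics:
            message = message + "\n  " + "\n  ".join(self.diagnostics)
        super().__init__(message)


class ReferentialIntegrityError(DatasetError):
    """A child table references patient ids absent from ``patients``."""

    def __init__(self, table: str, missing_ids: Iterable[str]):
        self.table = table
        self.missing_ids = sorted(set(missing_ids))
        shown = ", ".join(self.missing_ids[:20])
        more = "" if len(self.missing_ids) <= 20 else f" (+{len(self.missing_ids) - 20} more)"
        super().__init__(
            f"{table}: unknown patient_id values: {shown}{more}"
        )


@dataclass(frozen=True)
class Violation:
    """One invariant violation found by :func:`validate_dataset`."""

    table: str
    row_key: str
    rule: str
    message: str


@dataclass
class EhrDataset:
    """Container of the three typed tables."""

    patients: pd.DataFrame
    events: pd.DataFrame
    encounters: pd.DataFrame

    @classmethod
    def empty(cls) -> "EhrDataset":
        return cls.from_records([], [], [])

    @classmethod
    def from_records(
        cls,
        patients: Iterable[Mapping] = (),
        events: Iterable[Mapping] = (),
        encounters: Iterable[Mapping] = (),
    ) -> "EhrDataset":
        """Build a dataset with canonical dtypes from row mappings.

        Missing optional fields may simply be absent from a mapping.
        Duplicate event rows are dropped (logged), as on load.
        """
        pat = pd.DataFrame(list(patients), columns=PATIENT_COLUMNS)
        ev = pd.DataFrame(list(events), columns=EVENT_COLUMNS)
        enc = pd.DataFrame(list(encounters), columns=ENCOUNTER_COLUMNS)
        return cls(
            patients=_canonical_patients(pat),
            events=_dedup_events(_canonical_events(ev)),
            encounters=_canonical_encounters(enc),
        )

    def equals(self, other: "EhrDataset") -> bool:
        return (
            self.patients.reset_index(drop=True).equals(other.patients.reset_index(drop=True))
            and self.events.reset_index(drop=True).equals(other.events.reset_index(drop=True))
            and self.encounters.reset_index(drop=True).equals(
                other.encounters.reset_index(drop=True)
            )
        )

    @property
    def n_patients(self) -> int:
        return len(self.patients)


# ---------------------------------------------------------------------------
# canonical dtypes


def _to_datetime(values) -> pd.Series:
    return pd.to_datetime(pd.Series(values), errors="raise")


def _canonical_patients(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    out["patient_id"] = out["patient_id"].astype(str) if len(out) else out["patient_id"].astype(object)
    out["birth_date"] = pd.to_datetime(out["birth_date"]) if len(out) else pd.Series([], dtype="datetime64[ns]")
    out["death_date"] = pd.to_datetime(out["death_date"]) if len(out) else pd.Series([], dtype="datetime64[ns]")
    out["bmi"] = pd.to_numeric(out["bmi"], errors="raise").astype(float) if len(out) else pd.Series([], dtype=float)
    for col in ("sex", "marital_status", "income_level", "occupation"):
        out[col] = out[col].astype(object)
    out["occupation"] = out["occupation"].where(pd.notna(out["occupation"]), np.nan)
    return out[PATIENT_COLUMNS]


def _canonical_events(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    out["patient_id"] = out["patient_id"].astype(str) if len(out) else out["patient_id"].astype(object)
    out["event_date"] = pd.to_datetime(out["event_date"]) if len(out) else pd.Series([], dtype="datetime64[ns]")
    for col in ("dimension", "code", "setting"):
        out[col] = out[col].astype(object)
    out["duration_days"] = pd.array(out["duration_days"], dtype="Int64") if len(out) else pd.array([], dtype="Int64")
    return out[EVENT_COLUMNS]


def _canonical_encounters(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    out["patient_id"] = out["patient_id"].astype(str) if len(out) else out["patient_id"].astype(object)
    out["encounter_date"] = pd.to_datetime(out["encounter_date"]) if len(out) else pd.Series([], dtype="datetime64[ns]")
    out["setting"] = out["setting"].astype(object)
    return out[ENCOUNTER_COLUMNS]


def _dedup_events(events: pd.DataFrame) -> pd.DataFrame:
    before = len(events)
    out = events.drop_duplicates(subset=EVENT_KEY, keep="first").reset_index(drop=True)
    dropped = before - len(out)
    if dropped:
        logger.info("dropped %d duplicate event row(s)", dropped)
    return out


# ---------------------------------------------------------------------------
# load


def _resolve_paths(source) -> dict[str, Path]:
    if isinstance(source, (str, Path)):
        base = Path(source)
        return {name: base / fname for name, fname in TABLE_FILES.items()}
    return {name: Path(p) for name, p in dict(source).items()}


def _read_raw(path: Path, columns: Sequence[str]) -> pd.DataFrame:
    if not path.exists():
        raise DatasetLoadError(f"missing file: {path}")
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise DatasetLoadError(f"{path}: empty file (expected a header row)") from None
    missing = set(columns) - set(df.columns)
    extra = set(df.columns) - set(columns)
    if missing or extra:
        raise DatasetLoadError(
            f"{path}: bad columns (missing {sorted(missing)}, unexpected {sorted(extra)})"
        )
    return df[list(columns)]


def _parse_date_col(df, col, table, diags, required):
    raw = df[col].str.strip()
    parsed = pd.to_datetime(raw.where(raw != "", None), format="%Y-%m-%d", errors="coerce")
    for i in df.index[raw.ne("") & parsed.isna()]:
        diags.append(f"{table} row {i}: unparseable date {raw[i]!r} in {col}")
    if required:
        for i in df.index[raw.eq("")]:
            diags.append(f"{table} row {i}: missing required date in {col}")
    return parsed


def _parse_float_col(df, col, table, diags):
    raw = df[col].str.strip()
    parsed = pd.to_numeric(raw.where(raw != "", None), errors="coerce")
    for i in df.index[raw.ne("") & parsed.isna()]:
        diags.append(f"{table} row {i}: unparseable number {raw[i]!r} in {col}")
    return parsed.astype(float)


def _parse_int_col(df, col, table, diags):
    raw = df[col].str.strip()
    parsed = pd.to_numeric(raw.where(raw != "", None), errors="coerce")
    for i in df.index[raw.ne("") & parsed.isna()]:
        diags.append(f"{table} row {i}: unparseable integer {raw[i]!r} in {col}")
    return pd.array(parsed, dtype="Int64")


def _check_enum(df, col, levels, table, diags, allow_empty=False):
    raw = df[col].str.strip()
    ok = raw.isin(levels) | (raw.eq("") if allow_empty else False)
    for i in df.index[~ok]:
        diags.append(f"{table} row {i}: invalid {col} value {raw[i]!r}")
    return raw


def load_dataset(source) -> EhrDataset:
    """Read and validate the three tables.

    Parameters
    ----------
    source : path-like or mapping
        Either a directory containing ``patients.csv``, ``events.csv`` and
        ``encounters.csv``, or a mapping ``{"patients": path, ...}``.

    Raises
    ------
    DatasetLoadError
        Missing files, bad headers, or any row-level schema violation
        (unparseable dates/numbers, invalid enum levels) — all offending
        rows are listed.
    ReferentialIntegrityError
        Events or encounters referencing unknown patient ids.
    """
    paths = _resolve_paths(source)
    raw_pat = _read_raw(paths["patients"], PATIENT_COLUMNS)
    raw_ev = _read_raw(paths["events"], EVENT_COLUMNS)
    raw_enc = _read_raw(paths["encounters"], ENCOUNTER_COLUMNS)

    diags: list[str] = []

    pat = pd.DataFrame(index=raw_pat.index)
    pat["patient_id"] = raw_pat["patient_id"].str.strip()
    pat["birth_date"] = _parse_date_col(raw_pat, "birth_date", "patients", diags, required=True)
    pat["sex"] = _check_enum(raw_pat, "sex", SEX_LEVELS, "patients", diags)
    pat["bmi"] = _parse_float_col(raw_pat, "bmi", "patients", diags)
    pat["marital_status"] = _check_enum(raw_pat, "marital_status", MARITAL_LEVELS, "patients", diags)
    pat["income_level"] = _check_enum(raw_pat, "income_level", INCOME_LEVELS, "patients", diags)
    occ = raw_pat["occupation"].str.strip()
    pat["occupation"] = occ.where(occ != "", np.nan)
    pat["death_date"] = _parse_date_col(raw_pat, "death_date", "patients", diags, required=False)

    ev = pd.DataFrame(index=raw_ev.index)
    ev["patient_id"] = raw_ev["patient_id"].str.strip()
    ev["event_date"] = _parse_date_col(raw_ev, "event_date", "events", diags, required=True)
    ev["dimension"] = _check_enum(raw_ev, "dimension", DIMENSIONS, "events", diags)
    ev["code"] = raw_ev["code"].str.strip()
    for i in ev.index[ev["code"].eq("")]:
        diags.append(f"events row {i}: empty code")
    ev["setting"] = _check_enum(raw_ev, "setting", CARE_SETTINGS, "events", diags)
    ev["duration_days"] = _parse_int_col(raw_ev, "duration_days", "events", diags)

    enc = pd.DataFrame(index=raw_enc.index)
    enc["patient_id"] = raw_enc["patient_id"].str.strip()
    enc["encounter_date"] = _parse_date_col(raw_enc, "encounter_date", "encounters", diags, required=True)
    enc["setting"] = _check_enum(raw_enc, "setting", CARE_SETTINGS, "encounters", diags)

    if diags:
        raise DatasetLoadError("dataset failed schema validation", diags)

    known = set(pat["patient_id"])
    for table, frame, _col in (("events", ev, "patient_id"), ("encounters", enc, "patient_id")):
        missing = set(frame["patient_id"]) - known
        if missing:
            raise ReferentialIntegrityError(table, missing)

    ev = _dedup_events(ev)
    return EhrDataset(
        patients=pat[PATIENT_COLUMNS].reset_index(drop=True),
        events=ev[EVENT_COLUMNS].reset_index(drop=True),
        encounters=enc[ENCOUNTER_COLUMNS].reset_index(drop=True),
    )


# ---------------------------------------------------------------------------
# validate


def validate_dataset(ds: EhrDataset) -> list[Violation]:
    """Check every type invariant; returns violations (empty when clean).

    Violations are data, not exceptions: each entry names the table, a row
    key, a stable rule id and a human message.
    """
    out: list[Violation] = []
    pat, ev, enc = ds.patients, ds.events, ds.encounters

    dup = pat["patient_id"][pat["patient_id"].duplicated(keep=False)]
    for i in dup.index:
        out.append(Violation("patients", str(pat.at[i, "patient_id"]),
                             "patient-id-unique", "duplicate patient_id"))
    for i in pat.index:
        pid = str(pat.at[i, "patient_id"])
        birth, death = pat.at[i, "birth_date"], pat.at[i, "death_date"]
        if pd.isna(birth):
            out.append(Violation("patients", pid, "birth-date-present", "missing birth_date"))
        if pd.notna(death) and pd.notna(birth) and death < birth:
            out.append(Violation("patients", pid, "death-after-birth",
                                 f"death_date {death.date()} precedes birth_date {birth.date()}"))
        bmi = pat.at[i, "bmi"]
        if pd.notna(bmi) and not (5 < bmi < 100):
            out.append(Violation("patients", pid, "bmi-range", f"bmi {bmi} outside (5, 100)"))
        for col, levels, rule in (
            ("sex", SEX_LEVELS, "sex-level"),
            ("marital_status", MARITAL_LEVELS, "marital-level"),
            ("income_level", INCOME_LEVELS, "income-level"),
        ):
            v = pat.at[i, col]
            if v not in levels:
                out.append(Violation("patients", pid, rule, f"invalid {col} {v!r}"))

    known = set(pat["patient_id"].astype(str))

    for i in ev.index:
        pid = str(ev.at[i, "patient_id"])
        key = f"events[{i}]"
        if pid not in known:
            out.append(Violation("events", key, "event-patient-resolves",
                                 f"unknown patient_id {pid!r}"))
        if ev.at[i, "dimension"] not in DIMENSIONS:
            out.append(Violation("events", key, "event-dimension",
                                 f"invalid dimension {ev.at[i, 'dimension']!r}"))
        if ev.at[i, "setting"] not in CARE_SETTINGS:
            out.append(Violation("events", key, "event-setting",
                                 f"invalid setting {ev.at[i, 'setting']!r}"))
        if not ev.at[i, "code"]:
            out.append(Violation("events", key, "event-code", "empty code"))
        if pd.isna(ev.at[i, "event_date"]):
            out.append(Violation("events", key, "event-date-present", "missing event_date"))
        dur = ev.at[i, "duration_days"]
        if pd.notna(dur):
            if ev.at[i, "dimension"] != "pharmacy":
                out.append(Violation("events", key, "duration-pharmacy-only",
                                     "duration_days on a non-pharmacy row"))
            elif dur <= 0:
                out.append(Violation("events", key, "duration-positive",
                                     f"non-positive duration_days {dur}"))

    dup_ev = ev.index[ev.duplicated(subset=EVENT_KEY, keep="first")]
    for i in dup_ev:
        out.append(Violation("events", f"events[{i}]", "event-unique", "duplicate event row"))

    for i in enc.index:
        pid = str(enc.at[i, "patient_id"])
        key = f"encounters[{i}]"
        if pid not in known:
            out.append(Violation("encounters", key, "encounter-patient-resolves",
                                 f"unknown patient_id {pid!r}"))
        if enc.at[i, "setting"] not in CARE_SETTINGS:
            out.append(Violation("encounters", key, "encounter-setting",
                                 f"invalid setting {enc.at[i, 'setting']!r}"))
        if pd.isna(enc.at[i, "encounter_date"]):
            out.append(Violation("encounters", key, "encounter-date-present",
                                 "missing encounter_date"))
    return out


# ---------------------------------------------------------------------------
# write


def _fmt_date(v) -> str:
    return "" if pd.isna(v) else pd.Timestamp(v).strftime("%Y-%m-%d")


def _fmt_float(v) -> str:
    return "" if pd.isna(v) else repr(float(v))


def _fmt_int(v) -> str:
    return "" if pd.isna(v) else str(int(v))


def _fmt_str(v) -> str:
    return "" if (v is None or (isinstance(v, float) and np.isnan(v))) else str(v)


def write_dataset(ds: EhrDataset, target) -> None:
    """Serialize the three tables as headered CSV (ISO-8601 dates).

    ``load_dataset(write_dataset(ds))`` reproduces ``ds`` exactly; writing
    the same dataset twice yields byte-identical files.
    """
    paths = _resolve_paths(target)
    if isinstance(target, (str, Path)):
        Path(target).mkdir(parents=True, exist_ok=True)

    pat = pd.DataFrame({
        "patient_id": ds.patients["patient_id"].map(_fmt_str),
        "birth_date": ds.patients["birth_date"].map(_fmt_date),
        "sex": ds.patients["sex"].map(_fmt_str),
        "bmi": ds.patients["bmi"].map(_fmt_float),
        "marital_status": ds.patients["marital_status"].map(_fmt_str),
        "income_level": ds.patients["income_level"].map(_fmt_str),
        "occupation": ds.patients["occupation"].map(_fmt_str),
        "death_date": ds.patients["death_date"].map(_fmt_date),
    }, columns=PATIENT_COLUMNS)
    ev = pd.DataFrame({
        "patient_id": ds.events["patient_id"].map(_fmt_str),
        "event_date": ds.events["event_date"].map(_fmt_date),
        "dimension": ds.events["dimension"].map(_fmt_str),
        "code": ds.events["code"].map(_fmt_str),
        "setting": ds.events["setting"].map(_fmt_str),
        "duration_days": ds.events["duration_days"].map(_fmt_int),
    }, columns=EVENT_COLUMNS)
    enc = pd.DataFrame({
        "patient_id": ds.encounters["patient_id"].map(_fmt_str),
        "encounter_date": ds.encounters["encounter_date"].map(_fmt_date),
        "setting": ds.encounters["setting"].map(_fmt_str),
    }, columns=ENCOUNTER_COLUMNS)

    for frame, name in ((pat, "patients"), (ev, "events"), (enc, "encounters")):
        try:
            frame.to_csv(paths[name], index=False, lineterminator="\n")
        except OSError as exc:
            raise DatasetError(f"cannot write {paths[name]}: {exc}") from exc
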
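"""Domain types and tabular I/O for claims, questionnaire and enrolment data.

The interchange format is one UTF-8 CSV per record type (ISO-8601 dates,
"." decimal separator), mirroring the flat extracts a payer's data
warehouse would hand an analyst:

=================  =========================================================
file               columns
=================  =========================================================
diagnoses.csv      person_id, code, date
prescriptions.csv  person_id, atc_code, date
sick_leave.csv     person_id, start, end, attributed_code
invoices.csv       person_id, date, category, amount, year
enrolment.csv      person_id, invitation_date, enrolment_date, path,
                   sick_leave_insured
gcps_items.csv     person_id, pain_now, pain_avg, pain_worst, interf_daily,
                   interf_social, interf_work, disability_days
=================  =========================================================

In memory each table is a :class:`pandas.DataFrame` with date columns as
``datetime64[ns]``; row-level record classes (:class:`DiagnosisRecord` etc.)
carry the per-record invariants and are used for person-level grouping.
Duplicate rows are deliberately preserved: the chronicity rules count
diagnosis *records*, and claims extracts legitimately repeat codes.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

ICD10_PATTERN = re.compile(r"^[A-Z][0-9]{2}(\.[0-9]{1,2})?$")
ATC_PATTERN = re.compile(r"^[A-Z0-9]+$")

INVOICE_CATEGORIES = ("total_health", "bp_inpatient", "bp_outpatient")
ENROLMENT_PATHS = ("invited", "self_selected")

TABLE_COLUMNS: Mapping[str, tuple[str, ...]] = {
    "diagnoses": ("person_id", "code", "date"),
    "prescriptions": ("person_id", "atc_code", "date"),
    "sick_leave": ("person_id", "start", "end", "attributed_code"),
    "invoices": ("person_id", "date", "category", "amount", "year"),
    "enrolment": (
        "person_id",
        "invitation_date",
        "enrolment_date",
        "path",
        "sick_leave_insured",
    ),
    "gcps_items": (
        "person_id",
        "pain_now",
        "pain_avg",
        "pain_worst",
        "interf_daily",
        "interf_social",
        "interf_work",
        "disability_days",
    ),
}

_DATE_COLUMNS: Mapping[str, tuple[str, ...]] = {
    "diagnoses": ("date",),
    "prescriptions": ("date",),
    "sick_leave": ("start", "end"),
    "invoices": ("date",),
    "enrolment": ("invitation_date", "enrolment_date"),
    "gcps_items": (),
}

_SORT_KEYS: Mapping[str, tuple[str, ...]] = {
    "diagnoses": ("person_id", "date", "code"),
    "prescriptions": ("person_id", "date", "atc_code"),
    "sick_leave": ("person_id", "start", "end", "attributed_code"),
    "invoices": ("person_id", "date", "category", "amount"),
    "enrolment": ("person_id",),
    "gcps_items": ("person_id",),
}


class ValidationError(ValueError):
    """A record violates a domain invariant."""


def _check_icd10(code: str, what: str = "code") -> str:
    if not isinstance(code, str) or not ICD10_PATTERN.match(code):
        raise ValidationError(f"invalid ICD-10 {what}: {code!r}")
    return code


@dataclass(frozen=True)
class DiagnosisRecord:
    """One coded diagnosis (e.g. ``M54.5`` low back pain) on one date."""

    person_id: str
    code: str
    date: dt.date

    def __post_init__(self) -> None:
        _check_icd10(self.code)
        if not isinstance(self.date, dt.date):
            raise ValidationError(f"invalid date: {self.date!r}")


@dataclass(frozen=True)
class PrescriptionRecord:
    """One dispensed prescription identified by its ATC code."""

    person_id: str
    atc_code: str
    date: dt.date

    def __post_init__(self) -> None:
        if not isinstance(self.atc_code, str) or not ATC_PATTERN.match(self.atc_code):
            raise ValidationError(f"invalid ATC code: {self.atc_code!r}")
        if not isinstance(self.date, dt.date):
            raise ValidationError(f"invalid date: {self.date!r}")


@dataclass(frozen=True)
class SickLeaveEpisode:
    """A certified incapacity-to-work episode attributed to one ICD-10 code.

    The episode is closed on both ends: a one-day absence has
    ``start == end`` and ``duration_days == 1``.
    """

    person_id: str
    start: dt.date
    end: dt.date
    attributed_code: str

    def __post_init__(self) -> None:
        _check_icd10(self.attributed_code, "attributed_code")
        if self.end < self.start:
            raise ValidationError(
                f"sick-leave episode ends before it starts: {self.start}..{self.end}"
            )

    @property
    def duration_days(self) -> int:
        return (self.end - self.start).days + 1


@dataclass(frozen=True)
class InvoiceRecord:
    """One submitted health-care bill, in nominal euros of its year.

    ``bp_total`` is always derived as inpatient + outpatient downstream and
    never stored as a category of its own.
    """

    person_id: str
    date: dt.date
    category: str
    amount: float
    year: int

    def __post_init__(self) -> None:
        if self.category not in INVOICE_CATEGORIES:
            raise ValidationError(f"unknown invoice category: {self.category!r}")
        if not np.isfinite(self.amount) or self.amount < 0:
            raise ValidationError(f"invoice amount must be >= 0, got {self.amount!r}")


@dataclass(frozen=True)
class EnrolmentEvent:
    """Registration for the health programme, by invitation or own initiative."""

    person_id: str
    invitation_date: dt.date | None
    enrolment_date: dt.date
    path: str
    sick_leave_insured: bool

    def __post_init__(self) -> None:
        if self.path not in ENROLMENT_PATHS:
            raise ValidationError(f"unknown enrolment path: {self.path!r}")
        if self.path == "invited":
            if self.invitation_date is None:
                raise ValidationError("invited enrolment requires an invitation_date")
            if self.invitation_date > self.enrolment_date:
                raise ValidationError("invitation_date after enrolment_date")


@dataclass
class ClaimsHistory:
    """All dated administrative records for one insured person."""

    person_id: str
    diagnoses: list[DiagnosisRecord] = field(default_factory=list)
    prescriptions: list[PrescriptionRecord] = field(default_factory=list)
    sick_leave: list[SickLeaveEpisode] = field(default_factory=list)
    invoices: list[InvoiceRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        for group in (self.diagnoses, self.prescriptions, self.sick_leave, self.invoices):
            for rec in group:
                if rec.person_id != self.person_id:
                    raise ValidationError(
                        f"record person_id {rec.person_id!r} != history {self.person_id!r}"
                    )


@dataclass(frozen=True)
class RowError:
    """A rejected input row: which file, which row (0-based, data rows), why."""

    table: str
    row: int
    message: str


@dataclass
class TableBundle:
    """The six interchange tables of one dataset, as DataFrames."""

    diagnoses: pd.DataFrame
    prescriptions: pd.DataFrame
    sick_leave: pd.DataFrame
    invoices: pd.DataFrame
    enrolment: pd.DataFrame
    gcps_items: pd.DataFrame

    def table(self, name: str) -> pd.DataFrame:
        return getattr(self, name)

    def persons(self) -> list[str]:
        ids: set[str] = set()
        for name in TABLE_COLUMNS:
            df = self.table(name)
            if len(df):
                ids.update(df["person_id"].astype(str))
        return sorted(ids)


def empty_table(name: str) -> pd.DataFrame:
    cols = TABLE_COLUMNS[name]
    df = pd.DataFrame({c: pd.Series(dtype=object) for c in cols})
    for c in _DATE_COLUMNS[name]:
        df[c] = pd.Series(dtype="datetime64[ns]")
    return df


def empty_bundle() -> TableBundle:
    return TableBundle(**{name: empty_table(name) for name in TABLE_COLUMNS})


# ---------------------------------------------------------------------------
# validation of raw frames


def _validate_frame(name: str, raw: pd.DataFrame) -> tuple[pd.DataFrame, list[RowError]]:
    errors: list[RowError] = []
    df = raw.copy()
    cols = TABLE_COLUMNS[name]
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValidationError(f"{name}: missing columns {missing}")
    df = df[list(cols)]
    bad = pd.Series(False, index=df.index)

    def flag(mask: pd.Series, message: str) -> None:
        for idx in df.index[mask & ~bad]:
            errors.append(RowError(name, int(idx), message))
        bad.loc[mask] = True

    for col in _DATE_COLUMNS[name]:
        optional = name == "enrolment" and col == "invitation_date"
        parsed = pd.to_datetime(df[col], format="ISO8601", errors="coerce")
        blank = df[col].isna() | (df[col].astype(str).str.strip() == "")
        if optional:
            flag(parsed.isna() & ~blank, f"malformed date in {col}")
        else:
            flag(parsed.isna(), f"malformed or missing date in {col}")
        df[col] = parsed

    if name == "diagnoses":
        flag(~df["code"].astype(str).str.match(ICD10_PATTERN), "invalid ICD-10 code")
    elif name == "prescriptions":
        flag(~df["atc_code"].astype(str).str.match(ATC_PATTERN), "invalid ATC code")
    elif name == "sick_leave":
        flag(
            ~df["attributed_code"].astype(str).str.match(ICD10_PATTERN),
            "invalid ICD-10 attributed_code",
        )
        ok = df["start"].notna() & df["end"].notna()
        flag(ok & (df["end"] < df["start"]), "episode ends before it starts")
    elif name == "invoices":
        amount = pd.to_numeric(df["amount"], errors="coerce")
        flag(amount.isna() | (amount < 0), "malformed or negative amount")
        df["amount"] = amount
        year = pd.to_numeric(df["year"], errors="coerce")
        flag(year.isna(), "malformed year")
        df["year"] = year.astype("Int64")
        flag(~df["category"].isin(INVOICE_CATEGORIES), "unknown invoice category")
    elif name == "enrolment":
        flag(~df["path"].isin(ENROLMENT_PATHS), "unknown enrolment path")
        sli = df["sick_leave_insured"].map(_parse_bool)
        flag(sli.isna(), "malformed sick_leave_insured flag")
        df["sick_leave_insured"] = sli
        invited = df["path"] == "invited"
        flag(invited & df["invitation_date"].isna(), "invited row lacks invitation_date")
        both = invited & df["invitation_date"].notna() & df["enrolment_date"].notna()
        flag(both & (df["invitation_date"] > df["enrolment_date"]),
             "invitation_date after enrolment_date")
    elif name == "gcps_items":
        for col, hi in (
            ("pain_now", 10), ("pain_avg", 10), ("pain_worst", 10),
            ("interf_daily", 10), ("interf_social", 10), ("interf_work", 10),
            ("disability_days", 180),
        ):
            v = pd.to_numeric(df[col], errors="coerce")
            flag(v.isna() | (v < 0) | (v > hi) | (v != v.round()),
                 f"{col} must be an integer in 0..{hi}")
            df[col] = v

    out = df.loc[~bad].reset_index(drop=True)
    if name == "enrolment":
        out["sick_leave_insured"] = out["sick_leave_insured"].astype(bool)
        out["path"] = out["path"].astype(str)
    if name == "invoices":
        out["year"] = out["year"].astype(int) if len(out) else out["year"].astype("int64")
        out["amount"] = out["amount"].astype(float)
    if name == "gcps_items":
        for col in TABLE_COLUMNS[name][1:]:
            out[col] = out[col].astype(int) if len(out) else out[col].astype("int64")
    out["person_id"] = out["person_id"].astype(str)
    return out, errors


def _parse_bool(value: object) -> bool | float:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    text = str(value).strip().lower()
    if text in {"true", "1", "yes"}:
        return True
    if text in {"false", "0", "no"}:
        return False
    return float("nan")


# ---------------------------------------------------------------------------
# reading / writing


def table_paths(directory: str | Path) -> dict[str, Path]:
    directory = Path(directory)
    return {name: directory / f"{name}.csv" for name in TABLE_COLUMNS}


def read_tables(
    directory: str | Path,
    *,
    strict: bool = False,
) -> tuple[TableBundle, list[RowError]]:
    """Read the CSV bundle from ``directory``.

    Malformed rows are dropped and reported in the returned error list
    (``strict=True`` raises on the first error instead). A missing file is
    treated as an empty table so that partial bundles still load.
    """
    frames: dict[str, pd.DataFrame] = {}
    errors: list[RowError] = []
    for name, path in table_paths(directory).items():
        if not path.exists():
            frames[name] = empty_table(name)
            continue
        raw = pd.read_csv(path, dtype=str, keep_default_na=False)
        raw = raw.replace({"": None}) if name == "enrolment" else raw
        validated, errs = _validate_frame(name, raw)
        frames[name] = validated
        errors.extend(errs)
    if strict and errors:
        first = errors[0]
        raise ValidationError(f"{first.table} row {first.row}: {first.message}")
    return TableBundle(**frames), errors


def write_tables(bundle: TableBundle, directory: str | Path) -> dict[str, Path]:
    """Write the bundle as CSVs with deterministic column and row order.

    Rows are sorted by (person_id, date, ...); writing the same bundle twice
    yields byte-identical files, and ``read_tables`` inverts ``write_tables``.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = table_paths(directory)
    for name, path in paths.items():
        df = bundle.table(name).copy()
        df = df[list(TABLE_COLUMNS[name])]
        keys = [k for k in _SORT_KEYS[name] if k in df.columns]
        if len(df):
            df = df.sort_values(list(keys), kind="mergesort").reset_index(drop=True)
        for col in _DATE_COLUMNS[name]:
            dates = pd.to_datetime(df[col])
            df[col] = dates.dt.strftime("%Y-%m-%d")
            df.loc[dates.isna(), col] = ""
        if name == "invoices" and len(df):
            df["amount"] = df["amount"].map(lambda a: f"{float(a):.2f}")
        if name == "enrolment" and len(df):
            df["sick_leave_insured"] = df["sick_leave_insured"].map(
                lambda b: "true" if b else "false"
            )
        df.to_csv(path, index=False, lineterminator="\n")
    return paths


# ---------------------------------------------------------------------------
# person-level grouping


def _records(df: pd.DataFrame, cls, converters) -> Iterable:
    for row in df.itertuples(index=False):
        yield cls(*[conv(v) for conv, v in zip(converters, row)])


def _as_date(value) -> dt.date | None:
    if value is None or (isinstance(value, float) and np.isnan(value)) or pd.isna(value):
        return None
    return pd.Timestamp(value).date()


def claims_histories(bundle: TableBundle) -> dict[str, ClaimsHistory]:
    """Group the four claims tables into one :class:`ClaimsHistory` per person."""
    histories: dict[str, ClaimsHistory] = {
        pid: ClaimsHistory(pid) for pid in bundle.persons()
    }
    for rec in _records(bundle.diagnoses, DiagnosisRecord, (str, str, _as_date)):
        histories[rec.person_id].diagnoses.append(rec)
    for rec in _records(bundle.prescriptions, PrescriptionRecord, (str, str, _as_date)):
        histories[rec.person_id].prescriptions.append(rec)
    for rec in _records(
        bundle.sick_leave, SickLeaveEpisode, (str, _as_date, _as_date, str)
    ):
        histories[rec.person_id].sick_leave.append(rec)
    for rec in _records(
        bundle.invoices, InvoiceRecord, (str, _as_date, str, float, int)
    ):
        histories[rec.person_id].invoices.append(rec)
    return histories


def enrolment_events(bundle: TableBundle) -> dict[str, EnrolmentEvent]:
    events: dict[str, EnrolmentEvent] = {}
    for row in bundle.enrolment.itertuples(index=False):
        ev = EnrolmentEvent(
            person_id=str(row.person_id),
            invitation_date=_as_date(row.invitation_date),
            enrolment_date=_as_date(row.enrolment_date),
            path=str(row.path),
            sick_leave_insured=bool(row.sick_leave_insured),
        )
        events[ev.person_id] = ev
    return events
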
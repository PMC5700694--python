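"""Domain types and deterministic derivations for AI breeding-event records.

A *service* is a single artificial-insemination event on a heifer; a
*calving* later confirms (or refutes) its outcome.  This module owns the
CSV schema shared by every pipeline stage and the small deterministic
derivations: age at service, calendar-month category, inter-service
interval bins and the service-number category.

Dates are ISO-8601 calendar dates; every duration is a whole number of
days.  The canonical CSV dialect is UTF-8, comma-separated, with a header
row and the literal string ``NA`` for missing values.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .errors import DomainError, SchemaError

#: Closed set of breed categories; FR (Friesian) is the reference level.
BREEDS = ("FR", "FRX", "HO", "JE", "JEX", "MO", "NO", "NR", "Other")

#: Month-of-service categories within the spring breeding season.
MONTHS = ("April", "May", "JuneJuly")

#: Inter-service interval bins (days); boundaries inclusive as labelled.
INTERVAL_LABELS = ("<=17", "18-24", "25-35", "36-48", ">=49")

#: Service-number categories: third and later services are pooled.
SERVICE_NUMBER_LABELS = ("1", "2", "3+")

OUTCOMES = ("positive", "negative", "unknown")

SERVICE_COLUMNS = [
    "herd_id",
    "animal_id",
    "birth_date",
    "service_date",
    "service_number",
    "sire_id",
    "breed",
    "civ_pta",
]
CALVING_COLUMNS = ["animal_id", "calving_date", "is_abortion"]


@dataclass
class ServiceRecord:
    """One AI breeding event with its covariates and (possibly unknown) outcome."""

    herd_id: str
    animal_id: str
    birth_date: dt.date
    service_date: dt.date
    service_number: int
    sire_id: Optional[str] = None
    breed: Optional[str] = None
    civ_pta: Optional[float] = None
    interservice_days: Optional[int] = None
    outcome: str = "unknown"

    def __post_init__(self):
        if self.service_date <= self.birth_date:
            raise DomainError(
                f"service_date {self.service_date} not after birth_date {self.birth_date}"
            )
        if self.service_number < 1:
            raise DomainError(f"service_number must be >= 1, got {self.service_number}")
        if self.outcome not in OUTCOMES:
            raise DomainError(f"unknown outcome {self.outcome!r}")

    @property
    def age_days(self) -> int:
        return compute_age_days(self.birth_date, self.service_date)


@dataclass
class CalvingRecord:
    """A calving (or abortion) event used to confirm service outcomes."""

    animal_id: str
    calving_date: dt.date
    is_abortion: bool = False


@dataclass
class ParseIssue:
    """A recoverable row-level problem encountered while reading a table."""

    row: int
    column: str
    message: str


@dataclass
class ParseResult:
    services: pd.DataFrame
    calvings: pd.DataFrame
    issues: list = field(default_factory=list)


def compute_age_days(birth_date: dt.date, service_date: dt.date) -> int:
    """Whole-day age at service; the service must postdate birth."""
    if service_date <= birth_date:
        raise DomainError(f"service {service_date} not after birth {birth_date}")
    return (service_date - birth_date).days


def bin_interservice_interval(days: int) -> str:
    """Map an inter-service interval (days, >= 3) onto its category.

    Intervals below three days belong to a single oestrus and must have
    been removed by cleaning before this derivation is applied.
    """
    days = int(days)
    if days < 3:
        raise DomainError(f"interval {days} < 3 days: same-oestrus cleaning was skipped")
    if days <= 17:
        return INTERVAL_LABELS[0]
    if days <= 24:
        return INTERVAL_LABELS[1]
    if days <= 35:
        return INTERVAL_LABELS[2]
    if days <= 48:
        return INTERVAL_LABELS[3]
    return INTERVAL_LABELS[4]


def categorize_service_number(n: int) -> str:
    """1 -> "1", 2 -> "2", three or more -> "3+"."""
    n = int(n)
    if n < 1:
        raise DomainError(f"service number must be >= 1, got {n}")
    if n >= 3:
        return "3+"
    return str(n)


def month_category(service_date: dt.date) -> str:
    """April / May / JuneJuly from the calendar month of service.

    Services outside April-July are carryover events and must have been
    removed before categorisation.
    """
    m = service_date.month
    if m == 4:
        return "April"
    if m == 5:
        return "May"
    if m in (6, 7):
        return "JuneJuly"
    raise DomainError(f"service month {m} outside the April-July breeding season")


def _parse_dates(raw: pd.Series, column: str, issues: list) -> pd.Series:
    parsed = pd.to_datetime(raw, format="%Y-%m-%d", errors="coerce")
    bad = parsed.isna() & raw.notna()
    for idx in raw.index[bad]:
        issues.append(ParseIssue(int(idx), column, f"unparseable date {raw[idx]!r}"))
    return parsed


def read_services(path, issues=None) -> pd.DataFrame:
    """Read a services table from the canonical CSV dialect.

    Rows with unparseable dates are dropped and reported as
    :class:`ParseIssue` entries in ``issues`` (if provided); rows with
    missing breed or CIV PTA are retained and flagged ``incomplete`` so
    they can be dropped at the modelling stage rather than at parse.
    """
    df = pd.read_csv(path, dtype=str, na_values=["NA"], keep_default_na=False)
    missing = [c for c in SERVICE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"services table missing required columns: {missing}")
    if issues is None:
        issues = []
    out = pd.DataFrame(index=df.index)
    out["herd_id"] = df["herd_id"]
    out["animal_id"] = df["animal_id"]
    out["birth_date"] = _parse_dates(df["birth_date"], "birth_date", issues)
    out["service_date"] = _parse_dates(df["service_date"], "service_date", issues)
    out["service_number"] = pd.to_numeric(df["service_number"], errors="coerce").astype("Int64")
    out["sire_id"] = df["sire_id"]
    out["breed"] = df["breed"]
    unknown = out["breed"].notna() & ~out["breed"].isin(BREEDS)
    if unknown.any():
        import warnings

        warnings.warn(
            f"{int(unknown.sum())} unknown breed label(s) mapped to 'Other'", stacklevel=2
        )
        out.loc[unknown, "breed"] = "Other"
    out["civ_pta"] = pd.to_numeric(df["civ_pta"], errors="coerce")
    out["outcome"] = df["outcome"] if "outcome" in df.columns else "unknown"
    out["outcome"] = out["outcome"].fillna("unknown")
    if "record_id" in df.columns:
        out["record_id"] = df["record_id"]
    bad_rows = out["birth_date"].isna() | out["service_date"].isna()
    out = out[~bad_rows].copy()
    out["incomplete"] = out["breed"].isna() | out["civ_pta"].isna()
    return out.reset_index(drop=True)


def read_calvings(path, issues=None) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, na_values=["NA"], keep_default_na=False)
    missing = [c for c in CALVING_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"calvings table missing required columns: {missing}")
    if issues is None:
        issues = []
    out = pd.DataFrame(index=df.index)
    out["animal_id"] = df["animal_id"]
    out["calving_date"] = _parse_dates(df["calving_date"], "calving_date", issues)
    out["is_abortion"] = df["is_abortion"].str.lower().isin(["true", "1", "yes"])
    out = out[out["calving_date"].notna()].copy()
    return out.reset_index(drop=True)


def parse_service_table(services_path, calvings_path) -> ParseResult:
    """Read both tables, collecting row-level issues instead of failing."""
    issues: list = []
    services = read_services(services_path, issues)
    calvings = read_calvings(calvings_path, issues)
    return ParseResult(services=services, calvings=calvings, issues=issues)


def _format_dates(s: pd.Series) -> pd.Series:
    return pd.to_datetime(s).dt.strftime("%Y-%m-%d")


def write_services(df: pd.DataFrame, path) -> None:
    out = df.copy()
    for col in ("birth_date", "service_date"):
        out[col] = _format_dates(out[col])
    cols = SERVICE_COLUMNS + [c for c in ("outcome", "record_id") if c in out.columns]
    out = out[cols]
    out["service_number"] = out["service_number"].astype("Int64")
    out["civ_pta"] = out["civ_pta"].map(lambda v: "" if pd.isna(v) else format(v, ".6g"))
    out.to_csv(path, index=False, na_rep="NA")


def write_calvings(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out["calving_date"] = _format_dates(out["calving_date"])
    out["is_abortion"] = np.where(out["is_abortion"], "true", "false")
    out[CALVING_COLUMNS].to_csv(path, index=False, na_rep="NA")


def derive_covariates(df: pd.DataFrame) -> pd.DataFrame:
    """Attach the deterministic derivations used by the models.

    Adds ``age_days``, ``month_cat``, ``service_number_cat`` and (where an
    inter-service interval is present) ``interval_cat``.
    """
    out = df.copy()
    birth = pd.to_datetime(out["birth_date"])
    service = pd.to_datetime(out["service_date"])
    age = (service - birth).dt.days
    if (age <= 0).any():
        raise DomainError("service on or before birth date")
    out["age_days"] = age.astype(int)
    out["month_cat"] = [month_category(d) for d in service.dt.date]
    out["service_number_cat"] = [categorize_service_number(n) for n in out["service_number"]]
    if "interservice_days" in out.columns:
        out["interval_cat"] = [
            bin_interservice_interval(d) if pd.notna(d) else pd.NA
            for d in out["interservice_days"]
        ]
    return out
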
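"""Service-record cleaning: outcome confirmation from calvings and removal
of invalid breeding events, with a full audit trail.

The rules, applied in a fixed order within each animal's breeding season:

1. *Same-oestrus removal* — services less than three days after the
   previous service belong to the same oestrus; only the first of such a
   run is retained (a positive outcome on a removed duplicate transfers to
   the retained service).
2. *Outcome assignment* — the gestation from the season's final service to
   the next non-abortion calving confirms the conceiving service.  Too
   short (< 267 d): an earlier service whose gestation falls in the normal
   range is marked positive and later services are removed.  Too long
   (> 300 d): the final service is removed (presumed embryonic loss
   followed by an unrecorded conceiving service) and no conception is
   attributed.  A final service recorded negative but followed by a
   calving within the normal range is corrected to positive.
3. *Problem-season removal* — seasons with repeated short inter-service
   intervals (possible ovarian dysfunction) are removed whole.
4. *Carryover removal* — services outside the spring breeding window in
   seasons with no conception are removed.
5. *Renumbering* — service numbers and inter-service intervals are
   recalculated from the surviving records.

The pipeline is idempotent: cleaning already-clean data changes nothing
and reports an all-zero audit.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .errors import ConfigError, DataIntegrityError, DomainError
from .records import derive_covariates

SEASON_KEYS = ["herd_id", "animal_id", "season_year"]


@dataclass(frozen=True)
class GestationRule:
    """Plausible-gestation window used to confirm conception.

    ``expected_days`` +/- ``tolerance_days`` is the correction window for
    final services recorded negative; [``min_days``, ``max_days``] is the
    validity window for attributing a conception at all.
    """

    min_days: int = 267
    max_days: int = 300
    expected_days: int = 282
    tolerance_days: int = 15


@dataclass(frozen=True)
class CleaningConfig:
    gestation: GestationRule = field(default_factory=GestationRule)
    season_start_month: int = 4
    season_start_day: int = 1
    season_end_month: int = 7
    season_end_day: int = 31
    # "repeatedly bred after short intervals": >= k_min_services services
    # with >= min_short_gaps inter-service gaps <= short_gap_days
    k_min_services: int = 3
    short_gap_days: int = 10
    min_short_gaps: int = 2


@dataclass
class CleaningAudit:
    """Counts of every correction and removal applied by the pipeline."""

    n_input: int = 0
    n_output: int = 0
    n_removed_same_oestrus: int = 0
    n_reassigned_short_gestation: int = 0
    n_removed_long_gestation: int = 0
    n_corrected_negative_finals: int = 0
    n_removed_problem_seasons: int = 0
    n_removed_problem_season_records: int = 0
    n_removed_carryover: int = 0

    @property
    def total_removed(self) -> int:
        return (
            self.n_removed_same_oestrus
            + self.n_reassigned_short_gestation
            + self.n_removed_long_gestation
            + self.n_removed_problem_season_records
            + self.n_removed_carryover
        )

    def as_dict(self) -> dict:
        return asdict(self)


def compute_gestation(service_date, calving_date) -> int:
    """Whole days from service to the following calving."""
    service_date = pd.Timestamp(service_date)
    calving_date = pd.Timestamp(calving_date)
    if calving_date <= service_date:
        raise DomainError(f"calving {calving_date.date()} not after service {service_date.date()}")
    return int((calving_date - service_date).days)


def _with_season(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    out["season_year"] = pd.to_datetime(out["service_date"]).dt.year
    return out


def _sort_seasons(df: pd.DataFrame) -> pd.DataFrame:
    return df.sort_values(SEASON_KEYS + ["service_date"], kind="stable")


def remove_same_oestrus(df: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Drop services < 3 days after their predecessor within a season.

    Runs of closely-spaced services collapse onto the first service of the
    run; a positive outcome recorded on a removed service transfers to the
    retained one.
    """
    if df.empty:
        return df.copy(), 0
    df = _sort_seasons(_with_season(df)).reset_index(drop=True)
    gap = pd.to_datetime(df["service_date"]).diff().dt.days.copy()
    first = df.groupby(SEASON_KEYS, sort=False).cumcount() == 0
    gap = gap.where(~first)
    removed = gap < 3
    # retained predecessor of each record (group-safe: a group's first
    # record is never removed)
    kept_idx = df.index.to_series().where(~removed).ffill()
    for i in df.index[removed & (df["outcome"] == "positive")]:
        df.loc[int(kept_idx[i]), "outcome"] = "positive"
    out = df[~removed].drop(columns="season_year").reset_index(drop=True)
    return out, int(removed.sum())


def assign_service_outcomes(
    services: pd.DataFrame, calvings: pd.DataFrame, rule: GestationRule = GestationRule()
) -> tuple[pd.DataFrame, dict]:
    """Confirm outcomes from calvings; reassign, remove or correct services.

    Returns the surviving records (with ``outcome`` set for every record)
    and the counts of reassignment removals, long-gestation removals and
    negative-final corrections.
    """
    df = _sort_seasons(_with_season(services)).reset_index(drop=True)
    calv = calvings.sort_values(["animal_id", "calving_date"], kind="stable")
    calv_by_animal = {k: g for k, g in calv.groupby("animal_id", sort=False)}
    counts = {"reassigned": 0, "removed_long": 0, "corrected": 0}
    drop: list[int] = []
    outcome = df["outcome"].copy()

    for _, season in df.groupby(SEASON_KEYS, sort=False):
        idx = season.index.to_numpy()
        dates = pd.to_datetime(season["service_date"]).to_numpy()
        if np.any(np.diff(dates) < np.timedelta64(0, "D")):
            raise DomainError("services not ordered by date within a season")
        animal = season["animal_id"].iloc[0]
        last_date = pd.Timestamp(dates[-1])
        cand = calv_by_animal.get(animal)
        calving = None
        if cand is not None:
            after = cand[pd.to_datetime(cand["calving_date"]) > last_date]
            if not after.empty:
                normal = after[~after["is_abortion"]]
                in_window = [
                    c
                    for c in pd.to_datetime(normal["calving_date"])
                    if rule.min_days <= (c - last_date).days <= rule.max_days
                ]
                if len(in_window) > 1:
                    raise DataIntegrityError(
                        f"animal {animal}: two calvings within one gestation window"
                    )
                calving = after.iloc[0]
        if calving is None or calving["is_abortion"]:
            outcome[idx] = "negative"
            continue
        g_final = compute_gestation(last_date, calving["calving_date"])
        recorded_final = outcome[idx[-1]]
        if g_final < rule.min_days:
            gest = np.array(
                [compute_gestation(d, calving["calving_date"]) for d in dates[:-1]],
                dtype=float,
            )
            aligned = np.flatnonzero((gest >= rule.min_days) & (gest <= rule.max_days))
            if aligned.size:
                # prefer gestation nearest the expected length; ties go to
                # the later service
                best = aligned[
                    np.lexsort((-aligned, np.abs(gest[aligned] - rule.expected_days)))
                ][0]
                outcome[idx] = "negative"
                outcome[idx[best]] = "positive"
                removed = idx[best + 1 :]
                drop.extend(removed.tolist())
                counts["reassigned"] += len(removed)
            else:
                # no earlier service aligns; treat the final service as the
                # conceiver unless it was explicitly recorded negative
                outcome[idx[:-1]] = "negative"
                outcome[idx[-1]] = "positive" if recorded_final != "negative" else "negative"
        elif g_final > rule.max_days:
            if recorded_final == "negative":
                # unexplained calving after a recorded-negative final:
                # nothing to remove, no conception attributed
                outcome[idx] = "negative"
            else:
                drop.append(int(idx[-1]))
                counts["removed_long"] += 1
                outcome[idx[:-1]] = "negative"
        else:
            outcome[idx[:-1]] = "negative"
            if recorded_final == "negative":
                counts["corrected"] += 1
            outcome[idx[-1]] = "positive"

    df["outcome"] = outcome
    out = df.drop(index=drop).drop(columns="season_year").reset_index(drop=True)
    return out, counts


def flag_problem_seasons(
    df: pd.DataFrame,
    k_min_services: int = 3,
    short_gap_days: int = 10,
    min_short_gaps: int = 2,
) -> list[tuple]:
    """Identify animal-seasons repeatedly bred after short intervals."""
    if df.empty:
        return []
    df = _sort_seasons(_with_season(df))
    flagged = []
    for key, season in df.groupby(SEASON_KEYS, sort=False):
        if len(season) < k_min_services:
            continue
        gaps = pd.to_datetime(season["service_date"]).diff().dt.days.dropna()
        if int((gaps <= short_gap_days).sum()) >= min_short_gaps:
            flagged.append(key)
    return flagged


def _season_window(year: int, config: CleaningConfig) -> tuple[pd.Timestamp, pd.Timestamp]:
    start = pd.Timestamp(dt.date(year, config.season_start_month, config.season_start_day))
    end = pd.Timestamp(dt.date(year, config.season_end_month, config.season_end_day))
    if end < start:
        raise ConfigError("season end before season start")
    return start, end


def remove_carryover(df: pd.DataFrame, config: CleaningConfig = CleaningConfig()) -> tuple[pd.DataFrame, int]:
    """Remove out-of-window services in seasons with no conception."""
    if df.empty:
        return df.copy(), 0
    df = _with_season(df)
    dates = pd.to_datetime(df["service_date"])
    outside = pd.Series(False, index=df.index)
    for year, grp in df.groupby("season_year"):
        start, end = _season_window(int(year), config)
        d = dates[grp.index]
        outside[grp.index] = (d < start) | (d > end)
    pregnant = df.groupby(SEASON_KEYS)["outcome"].transform(lambda s: (s == "positive").any())
    removed = outside & ~pregnant
    out = df[~removed].drop(columns="season_year").reset_index(drop=True)
    return out, int(removed.sum())


def renumber_services(df: pd.DataFrame) -> pd.DataFrame:
    """Recompute service numbers and inter-service intervals post-cleaning."""
    if df.empty:
        return df.copy()
    df = _sort_seasons(_with_season(df)).reset_index(drop=True)
    if df.duplicated(subset=["herd_id", "animal_id", "service_date"]).any():
        raise DataIntegrityError("duplicate (animal, service_date) after cleaning")
    df["service_number"] = df.groupby(SEASON_KEYS, sort=False).cumcount() + 1
    gaps = pd.to_datetime(df["service_date"]).diff().dt.days.copy()
    gaps = gaps.where(df["service_number"] != 1)
    df["interservice_days"] = gaps.astype("Int64")
    return df.drop(columns="season_year")


def clean_pipeline(
    services: pd.DataFrame,
    calvings: pd.DataFrame,
    config: CleaningConfig = CleaningConfig(),
) -> tuple[pd.DataFrame, CleaningAudit]:
    """Apply every cleaning rule in order and return (cleaned, audit)."""
    audit = CleaningAudit(n_input=len(services))
    df = services.copy()
    if "outcome" not in df.columns:
        df["outcome"] = "unknown"

    df, audit.n_removed_same_oestrus = remove_same_oestrus(df)
    df, counts = assign_service_outcomes(df, calvings, config.gestation)
    audit.n_reassigned_short_gestation = counts["reassigned"]
    audit.n_removed_long_gestation = counts["removed_long"]
    audit.n_corrected_negative_finals = counts["corrected"]

    flagged = flag_problem_seasons(
        df, config.k_min_services, config.short_gap_days, config.min_short_gaps
    )
    if flagged:
        df = _with_season(df)
        key = pd.MultiIndex.from_frame(df[SEASON_KEYS])
        mask = key.isin(flagged)
        audit.n_removed_problem_seasons = len(flagged)
        audit.n_removed_problem_season_records = int(mask.sum())
        df = df[~mask].drop(columns="season_year").reset_index(drop=True)

    df, audit.n_removed_carryover = remove_carryover(df, config)
    df = renumber_services(df)
    df = derive_covariates(df)
    audit.n_output = len(df)
    assert audit.n_output == audit.n_input - audit.total_removed
    return df.reset_index(drop=True), audit
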
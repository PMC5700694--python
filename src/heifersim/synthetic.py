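"""Synthetic herd, breeding-season and defect generation.

The generator emulates the structure of the study data: 12 seasonal
spring-calving herds (two research herds with ten breeding seasons each,
ten commercial herds with four or five), April-July services, roughly
1.2-1.4 services per animal-season, and conception driven by the
packaged published odds-ratio model with herd-year random intercepts.
Recording defects of the kinds the cleaning rules target can then be
planted at configured rates, each logged in a :class:`DefectLedger` so a
cleaning audit can be checked against exact planted counts.

Defect classes are planted disjointly by animal-season by default so the
ledger is an exact oracle; clean-up of a defected dataset recovers the
original record set (same record ids, same outcomes).
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit

from .errors import ConfigError
from .generative import GenerativeParams, calibrate_intercept, published_params
from .records import month_category

# Per-herd structure loosely following the study's descriptive table:
# two research herds then ten commercial herds.
HERD_IDS = tuple(f"H{i:02d}" for i in range(1, 13))
HERD_YEARS = {
    "H01": tuple(range(2001, 2011)),
    "H02": tuple(range(2001, 2011)),
    **{
        f"H{i:02d}": tuple(range(2009, 2014)) if i % 2 else tuple(range(2010, 2014))
        for i in range(3, 13)
    },
}
HERD_SIZE_MEAN = (43, 27, 40, 11, 30, 16, 14, 12, 18, 29, 16, 9)
AGE_MEAN = (447, 455, 440, 537, 464, 488, 475, 445, 493, 461, 518, 463)
AGE_SD = (30, 45, 33, 79, 58, 57, 61, 18, 68, 61, 53, 72)
# April/May/June/July service-month proportions per herd
MONTH_MIX = (
    (65.65, 27.70, 5.88, 0.76),
    (50.30, 36.14, 12.05, 1.51),
    (37.18, 61.54, 1.28, 0.00),
    (50.00, 7.81, 32.81, 9.38),
    (32.14, 56.55, 10.12, 1.19),
    (26.58, 41.77, 18.99, 12.66),
    (63.22, 22.99, 13.79, 0.00),
    (32.35, 66.18, 1.47, 0.00),
    (5.63, 80.28, 14.08, 0.00),
    (48.05, 50.65, 1.30, 0.00),
    (63.89, 27.78, 8.33, 0.00),
    (40.00, 31.11, 24.44, 4.44),
)
BREED_MIX = {
    "FR": 0.30,
    "HO": 0.35,
    "FRX": 0.10,
    "JE": 0.04,
    "JEX": 0.04,
    "MO": 0.03,
    "NO": 0.02,
    "NR": 0.06,
    "Other": 0.06,
}


@dataclass(frozen=True)
class DefectRates:
    """Planting probabilities for each recording-defect class."""

    duplicate_service: float = 0.02  # per service
    reassignment: float = 0.03  # per conceiving season
    negative_final: float = 0.03  # per conceiving season
    embryonic_loss: float = 0.15  # per non-conceiving season
    carryover: float = 0.30  # per non-conceiving season
    problem_season: float = 0.01  # new animal-seasons per existing animal
    missing_breed: float = 0.02  # per record
    missing_civ: float = 0.02  # per record

    def validate(self):
        for name, v in self.__dict__.items():
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"defect rate {name}={v} outside [0, 1]")


@dataclass(frozen=True)
class SyntheticConfig:
    herd_ids: tuple = HERD_IDS
    herd_years: dict = field(default_factory=lambda: dict(HERD_YEARS))
    herd_size_mean: tuple = HERD_SIZE_MEAN
    herd_size_sd_frac: float = 0.25
    age_mean: tuple = AGE_MEAN
    age_sd: tuple = AGE_SD
    month_mix: tuple = MONTH_MIX
    breed_mix: dict = field(default_factory=lambda: dict(BREED_MIX))
    civ_mean: float = 0.0
    civ_sd: float = 1.5
    generative: GenerativeParams = field(default_factory=published_params)
    gestation_mean: float = 282.0
    gestation_sd: float = 4.0
    gestation_range: tuple = (270.0, 294.0)
    return_interval_mean: float = 21.0
    return_interval_sd: float = 3.0
    return_interval_range: tuple = (11.0, 35.0)
    # probability a failed heifer is re-detected in oestrus and served
    # again; < 1 leaves a realistic fraction of seasons without conception
    rebreed_prob: float = 0.85
    season_end_month_day: tuple = (7, 31)
    defect_rates: DefectRates = field(default_factory=DefectRates)
    seed: int = 0

    def validate(self):
        for mix in self.month_mix:
            if abs(sum(mix) / 100.0 - 1.0) > 0.02:
                raise ConfigError(f"month mix {mix} does not sum to 100%")
        if abs(sum(self.breed_mix.values()) - 1.0) > 1e-6:
            raise ConfigError("breed mix does not sum to 1")
        if self.civ_sd < 0 or self.gestation_sd < 0 or self.return_interval_sd < 0:
            raise ConfigError("standard deviations must be nonnegative")
        self.defect_rates.validate()


@dataclass
class DefectLedger:
    """Record identifiers of every planted defect, by class."""

    duplicates: list = field(default_factory=list)
    reassignment_extras: list = field(default_factory=list)
    negative_final_flips: list = field(default_factory=list)
    embryonic_long_extras: list = field(default_factory=list)
    carryovers: list = field(default_factory=list)
    problem_seasons: list = field(default_factory=list)
    problem_season_records: list = field(default_factory=list)
    missing_breed: list = field(default_factory=list)
    missing_civ: list = field(default_factory=list)

    def counts(self) -> dict:
        return {
            "duplicates": len(self.duplicates),
            "reassignment_extras": len(self.reassignment_extras),
            "negative_final_flips": len(self.negative_final_flips),
            "embryonic_long_extras": len(self.embryonic_long_extras),
            "carryovers": len(self.carryovers),
            "problem_seasons": len(self.problem_seasons),
            "problem_season_records": len(self.problem_season_records),
            "missing_breed": len(self.missing_breed),
            "missing_civ": len(self.missing_civ),
        }


def _truncated_normal(rng, mean, sd, lo, hi, size=None):
    x = rng.normal(mean, sd, size=size)
    return np.clip(x, lo, hi)


def covariate_sampler_from_config(config: SyntheticConfig):
    """Marginal first-service covariate sampler used to calibrate the intercept."""
    weights = np.array(
        [m * len(config.herd_years[h]) for m, h in zip(config.herd_size_mean, config.herd_ids)],
        dtype=float,
    )
    weights /= weights.sum()
    breeds = list(config.breed_mix)
    breed_p = np.array([config.breed_mix[b] for b in breeds])
    months = np.array(["April", "May", "JuneJuly", "JuneJuly"])

    def sampler(n, rng):
        h = rng.choice(len(config.herd_ids), size=n, p=weights)
        age = np.array(
            [
                _truncated_normal(rng, config.age_mean[i], config.age_sd[i], 380, 900)
                for i in h
            ]
        )
        mix = np.array(config.month_mix, dtype=float)[h] / 100.0
        mix /= mix.sum(axis=1, keepdims=True)
        mcol = np.array([rng.choice(4, p=m) for m in mix])
        return pd.DataFrame(
            {
                "age_days": age,
                "civ_pta": rng.normal(config.civ_mean, config.civ_sd, size=n),
                "breed": rng.choice(breeds, size=n, p=breed_p),
                "month_cat": months[mcol],
            }
        )

    return sampler


def calibrated_params(config: SyntheticConfig, seed: int | None = None) -> GenerativeParams:
    """Config's generative parameters with the intercept calibrated."""
    params = config.generative
    if params.intercept is not None:
        return params
    c = calibrate_intercept(
        params,
        covariate_sampler_from_config(config),
        seed=config.seed if seed is None else seed,
    )
    return params.with_intercept(c)


def generate_population(config: SyntheticConfig, rng=None) -> pd.DataFrame:
    """Heifer roster: herd, year, animal, birth date, breed, CIV PTA.

    Also carries each heifer's first service date (drawn from the herd's
    month mix), from which the birth date is back-computed so that age at
    first service follows the configured per-herd distribution.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    breeds = list(config.breed_mix)
    breed_p = np.array([config.breed_mix[b] for b in breeds])
    rows = []
    k = 0
    for i, herd in enumerate(config.herd_ids):
        mix = np.asarray(config.month_mix[i], dtype=float)
        mix = mix / mix.sum()
        for year in config.herd_years[herd]:
            n = max(2, int(round(rng.normal(
                config.herd_size_mean[i], config.herd_size_sd_frac * config.herd_size_mean[i]
            ))))
            for _ in range(n):
                k += 1
                month = int(rng.choice([4, 5, 6, 7], p=mix))
                day = int(rng.integers(1, 29))
                first_service = dt.date(year, month, day)
                age = float(_truncated_normal(rng, config.age_mean[i], config.age_sd[i], 380, 900))
                rows.append(
                    {
                        "herd_id": herd,
                        "year": year,
                        "animal_id": f"A{k:05d}",
                        "birth_date": first_service - dt.timedelta(days=int(round(age))),
                        "breed": rng.choice(breeds, p=breed_p),
                        "civ_pta": float(rng.normal(config.civ_mean, config.civ_sd)),
                        "first_service_date": first_service,
                    }
                )
    return pd.DataFrame(rows)


def generate_breeding_season(
    roster: pd.DataFrame, config: SyntheticConfig, rng=None, params: GenerativeParams | None = None
):
    """Simulate one breeding season per heifer in the roster.

    Conception at each service is a Bernoulli draw from the generative
    model plus the heifer's herd-year random intercept; failures return
    to service after roughly one oestrous cycle until the season ends.
    Returns (services, calvings, empty DefectLedger).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if params is None:
        params = calibrated_params(config, seed=int(rng.integers(2**31)))
    re_sd = params.random_effect_sd
    u_by_group = {
        key: rng.normal(0.0, re_sd) for key in roster.groupby(["herd_id", "year"]).groups
    }
    end_md = config.season_end_month_day
    service_rows, calving_rows = [], []
    rid = 0
    for row in roster.itertuples(index=False):
        u = u_by_group[(row.herd_id, row.year)]
        season_end = dt.date(row.year, end_md[0], end_md[1])
        date = row.first_service_date
        n_serv = 0
        prev_date = None
        while date <= season_end:
            n_serv += 1
            rid += 1
            rec = {
                "record_id": f"R{rid:06d}",
                "herd_id": row.herd_id,
                "animal_id": row.animal_id,
                "birth_date": row.birth_date,
                "service_date": date,
                "service_number": n_serv,
                "sire_id": f"S{int(rng.integers(1, 41)):03d}",
                "breed": row.breed,
                "civ_pta": row.civ_pta,
            }
            age10 = ((date - row.birth_date).days - params.age_center_days) / 10.0
            m = month_category(date)
            eta = (
                params.intercept
                + params.age_log_or_per_10d * age10
                + params.civ_log_or_per_day * row.civ_pta
                + params.breed_log_or.get(row.breed, 0.0)
                + params.month_log_or.get(m, 0.0)
                + params.age_month_log_or.get(m, 0.0) * age10
            )
            p = float(expit(eta + u))
            conceived = rng.random() < p
            rec["outcome"] = "positive" if conceived else "negative"
            rec["interservice_days"] = None if prev_date is None else (date - prev_date).days
            service_rows.append(rec)
            if conceived:
                gest = int(round(_truncated_normal(
                    rng, config.gestation_mean, config.gestation_sd, *config.gestation_range
                )))
                calving_rows.append(
                    {
                        "animal_id": row.animal_id,
                        "calving_date": date + dt.timedelta(days=gest),
                        "is_abortion": False,
                    }
                )
                break
            if rng.random() >= config.rebreed_prob:
                break
            prev_date = date
            gap = int(round(_truncated_normal(
                rng,
                config.return_interval_mean,
                config.return_interval_sd,
                *config.return_interval_range,
            )))
            date = date + dt.timedelta(days=gap)
    services = pd.DataFrame(service_rows)
    calvings = pd.DataFrame(calving_rows, columns=["animal_id", "calving_date", "is_abortion"])
    for col in ("birth_date", "service_date"):
        services[col] = pd.to_datetime(services[col])
    calvings["calving_date"] = pd.to_datetime(calvings["calving_date"])
    return services, calvings, DefectLedger()


def generate_dataset(config: SyntheticConfig, with_defects: bool = False):
    """Roster + season simulation (+ optional defect injection) in one call."""
    rng = np.random.default_rng(config.seed)
    roster = generate_population(config, rng)
    services, calvings, ledger = generate_breeding_season(roster, config, rng)
    if with_defects:
        services, calvings, ledger = inject_defects(services, calvings, config, rng)
    return services, calvings, ledger


def _season_frame(services: pd.DataFrame) -> pd.DataFrame:
    df = services.copy()
    df["season_year"] = pd.to_datetime(df["service_date"]).dt.year
    return df


def inject_defects(services: pd.DataFrame, calvings: pd.DataFrame, config: SyntheticConfig, rng=None):
    """Plant recording defects at the configured rates.

    Classes are disjoint by animal-season: a season receives at most one
    season-level defect, and duplicate services (planted first, per
    service) exclude their season from the season-level classes.
    Missing values are planted per record in seasons untouched by the
    outcome-perturbing classes.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    rates = config.defect_rates
    df = _season_frame(services).sort_values(
        ["herd_id", "animal_id", "season_year", "service_date"], kind="stable"
    )
    calv = calvings.copy()
    ledger = DefectLedger()
    season_of = df.set_index("record_id")[["herd_id", "animal_id", "season_year"]]
    used: set = set()
    new_rows = []
    calv_by_animal = calv.set_index("animal_id")["calving_date"].to_dict()

    # 1. duplicate services (same-oestrus repeats), per service
    dup_mask = rng.random(len(df)) < rates.duplicate_service
    for rec in df[dup_mask].itertuples(index=False):
        key = (rec.herd_id, rec.animal_id, rec.season_year)
        used.add(key)
        new = rec._asdict()
        new["record_id"] = f"DUP-{rec.record_id}"
        new["service_date"] = rec.service_date + pd.Timedelta(days=int(rng.integers(1, 3)))
        new["outcome"] = "negative"
        new_rows.append(new)
        ledger.duplicates.append(new["record_id"])

    seasons = df.groupby(["herd_id", "animal_id", "season_year"], sort=False)
    pregnant_keys, open_keys = [], []
    for key, grp in seasons:
        if key in used:
            continue
        (pregnant_keys if (grp["outcome"] == "positive").any() else open_keys).append(key)

    def pick(keys, rate):
        chosen = [k for k in keys if k not in used and rng.random() < rate]
        used.update(chosen)
        return chosen

    groups = dict(list(seasons))

    # 2. embryonic loss, reassignment form: the true conceiving service is
    # replaced in the record by a later presumptive service whose implied
    # gestation is too short.  Planted only on single-service seasons so
    # the true conceiver is unambiguously the best-aligned earlier service
    # and the ledger stays an exact oracle.
    single_pregnant = [k for k in pregnant_keys if len(groups[k]) == 1]
    for key in pick(single_pregnant, rates.reassignment):
        grp = groups[key]
        final = grp.iloc[-1]
        calving = calv_by_animal[final["animal_id"]]
        gest = (pd.Timestamp(calving) - pd.Timestamp(final["service_date"])).days
        new = final.to_dict()
        new["record_id"] = f"REA-{final['record_id']}"
        new["service_date"] = final["service_date"] + pd.Timedelta(days=int(gest - 250))
        new["outcome"] = "positive"
        new_rows.append(new)
        df.loc[df["record_id"] == final["record_id"], "outcome"] = "negative"
        ledger.reassignment_extras.append(new["record_id"])

    # 3. conceiving final service mis-recorded as negative
    for key in pick(pregnant_keys, rates.negative_final):
        final = groups[key].iloc[-1]
        df.loc[df["record_id"] == final["record_id"], "outcome"] = "negative"
        ledger.negative_final_flips.append(final["record_id"])

    # 4. embryonic loss, over-long form: an extra recorded-positive service
    # whose calving arrives far too late to be its result
    for key in pick(open_keys, rates.embryonic_loss):
        final = groups[key].iloc[-1]
        new = final.to_dict()
        new["record_id"] = f"EMB-{final['record_id']}"
        new["service_date"] = final["service_date"] + pd.Timedelta(days=25)
        new["outcome"] = "positive"
        new_rows.append(new)
        calv = pd.concat(
            [
                calv,
                pd.DataFrame(
                    {
                        "animal_id": [final["animal_id"]],
                        "calving_date": [new["service_date"] + pd.Timedelta(days=310)],
                        "is_abortion": [False],
                    }
                ),
            ],
            ignore_index=True,
        )
        ledger.embryonic_long_extras.append(new["record_id"])

    # 5. carryover autumn services for non-pregnant heifers
    for key in pick(open_keys, rates.carryover):
        final = groups[key].iloc[-1]
        new = final.to_dict()
        new["record_id"] = f"CAR-{final['record_id']}"
        new["service_date"] = pd.Timestamp(
            dt.date(int(key[2]), 9, 1)
        ) + pd.Timedelta(days=int(rng.integers(0, 60)))
        new["outcome"] = "negative"
        new_rows.append(new)
        ledger.carryovers.append(new["record_id"])

    # 6. whole problem seasons on fresh animals (repeated short returns)
    n_animals = df["animal_id"].nunique()
    n_problem = int(rng.binomial(n_animals, rates.problem_season))
    herd_years = list({(h, y) for h, _, y in pregnant_keys + open_keys})
    for j in range(n_problem):
        herd, year = herd_years[int(rng.integers(len(herd_years)))]
        animal = f"PS{j:04d}"
        date = dt.date(int(year), 5, int(rng.integers(1, 15)))
        birth = date - dt.timedelta(days=int(rng.integers(420, 520)))
        key = (herd, animal, int(year))
        ledger.problem_seasons.append(key)
        for s in range(4):
            rec_id = f"PRB-{j:04d}-{s}"
            new_rows.append(
                {
                    "record_id": rec_id,
                    "herd_id": herd,
                    "animal_id": animal,
                    "birth_date": pd.Timestamp(birth),
                    "service_date": pd.Timestamp(date),
                    "service_number": s + 1,
                    "sire_id": "S001",
                    "breed": "HO",
                    "civ_pta": 0.0,
                    "outcome": "negative",
                    "interservice_days": None,
                    "season_year": int(year),
                }
            )
            ledger.problem_season_records.append(rec_id)
            date = date + dt.timedelta(days=int(rng.integers(4, 11)))

    # 7. missing covariates, per record, in untouched seasons
    for rec in df.itertuples(index=False):
        key = (rec.herd_id, rec.animal_id, rec.season_year)
        if key in used:
            continue
        if rng.random() < rates.missing_breed:
            df.loc[df["record_id"] == rec.record_id, "breed"] = pd.NA
            ledger.missing_breed.append(rec.record_id)
        if rng.random() < rates.missing_civ:
            df.loc[df["record_id"] == rec.record_id, "civ_pta"] = np.nan
            ledger.missing_civ.append(rec.record_id)

    out = pd.concat([df, pd.DataFrame(new_rows)], ignore_index=True)
    out = out.drop(columns="season_year").sort_values(
        ["herd_id", "animal_id", "service_date"], kind="stable"
    )
    calv = calv.sort_values(["animal_id", "calving_date"], kind="stable")
    return out.reset_index(drop=True), calv.reset_index(drop=True), ledger
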
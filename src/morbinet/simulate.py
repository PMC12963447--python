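"""Synthetic longitudinal cohort generator.

Simulates adult populations with dated chronic/acute diagnosis onsets, death,
and planted directed pairwise co-occurrence enrichment, so that every
downstream stage (index computation, stratification, transition prediction,
network construction) can be tested against known ground truth. All
distributional choices are synthetic stand-ins for routinely collected health
records; none are estimated from real data.

The model is discrete-time with annual steps. For each patient, condition and
calendar year, one Bernoulli draw decides onset with probability

    h = base_hazard * exp(age_slope * (age - 50)) * sex_factor * prod(pair multipliers)

clipped to [0, 1], where ``sex_factor`` is ``sex_multiplier`` for women and 1
for men, and a pair multiplier is active from the calendar year after its
antecedent's onset. Chronic, neoplastic and pregnancy-related groups are
absorbing (at most one onset per patient); acute groups may recur. Death is
drawn before onsets within each follow-up year and is absorbing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import date

import numpy as np
import pandas as pd

from .codemap import CHRONICITY_CLASSES, CodeMap, GroupInfo, WeightTable

__all__ = [
    "ConditionSpec",
    "PairEffect",
    "SimConfig",
    "ConfigError",
    "generate_cohort",
    "make_toy_codemap",
    "default_config",
    "codemap_from_config",
    "weights_from_config",
    "AGE_BANDS",
]

#: (label, lower, upper) adult age bands; lower edge inclusive
AGE_BANDS = (
    ("18-40", 18.0, 40.0),
    ("40-60", 40.0, 60.0),
    ("60-70", 60.0, 70.0),
    ("70-80", 70.0, 80.0),
    (">80", 80.0, 95.0),
)

AGE_BAND_LABELS = tuple(b[0] for b in AGE_BANDS)


class ConfigError(ValueError):
    """A simulation configuration field violates its invariants."""


@dataclass(frozen=True)
class ConditionSpec:
    """One diagnostic group with its annual onset hazard model.

    base_hazard is the annual onset probability for a never-affected
    50-year-old man; age_slope is a log-linear modifier per year of age and
    sex_multiplier scales the hazard for women.
    """

    group_id: str
    base_hazard: float
    age_slope: float = 0.0
    sex_multiplier: float = 1.0
    chronicity: str = "chronic"
    organ_system: str = "general"
    weight: float = 1.0

    def validate(self) -> None:
        if not 0.0 <= self.base_hazard <= 1.0:
            raise ConfigError(f"base_hazard for {self.group_id!r} must be in [0,1]")
        if self.weight < 0:
            raise ConfigError(f"weight for {self.group_id!r} must be >= 0")
        if self.sex_multiplier < 0:
            raise ConfigError(f"sex_multiplier for {self.group_id!r} must be >= 0")
        if self.chronicity not in CHRONICITY_CLASSES:
            raise ConfigError(f"chronicity for {self.group_id!r} must be one of {sorted(CHRONICITY_CLASSES)}")


@dataclass(frozen=True)
class PairEffect:
    """Planted directed enrichment: after the antecedent's onset, the
    consequent's annual hazard is multiplied by hazard_multiplier (from the
    following calendar year onward). A multiplier of 1 encodes independence.
    """

    antecedent: str
    consequent: str
    hazard_multiplier: float

    def validate(self) -> None:
        if self.antecedent == self.consequent:
            raise ConfigError("pair effect antecedent must differ from consequent")
        if self.hazard_multiplier < 0:
            raise ConfigError("hazard_multiplier must be >= 0")


@dataclass(frozen=True)
class SimConfig:
    """Full specification of one synthetic cohort."""

    n_patients: int
    start_date: date = date(2013, 1, 1)
    end_date: date = date(2022, 12, 31)
    history_years: int = 10
    conditions: tuple[ConditionSpec, ...] = ()
    pair_effects: tuple[PairEffect, ...] = ()
    death_hazard: dict = field(default_factory=dict)  # age band label -> annual prob
    sex_ratio: float = 0.518
    age_distribution: dict = field(default_factory=dict)  # age band label -> weight
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients <= 0:
            raise ConfigError("n_patients must be positive")
        if not self.start_date < self.end_date:
            raise ConfigError("start_date must precede end_date")
        if self.history_years < 0:
            raise ConfigError("history_years must be non-negative")
        if not 0.0 <= self.sex_ratio <= 1.0:
            raise ConfigError("sex_ratio must be in [0,1]")
        group_ids = [c.group_id for c in self.conditions]
        if len(set(group_ids)) != len(group_ids):
            raise ConfigError("conditions contain duplicate group_ids")
        for c in self.conditions:
            c.validate()
        for p in self.pair_effects:
            p.validate()
            if p.antecedent not in group_ids or p.consequent not in group_ids:
                raise ConfigError(
                    f"pair_effects reference unknown group: {p.antecedent!r}->{p.consequent!r}"
                )
        for label, h in self.death_hazard.items():
            if label not in AGE_BAND_LABELS:
                raise ConfigError(f"death_hazard has unknown age band {label!r}")
            if h < 0:
                raise ConfigError(f"death_hazard for {label!r} must be >= 0")
        if self.age_distribution:
            unknown = set(self.age_distribution) - set(AGE_BAND_LABELS)
            if unknown:
                raise ConfigError(f"age_distribution has unknown bands {sorted(unknown)}")
            total = sum(self.age_distribution.values())
            if not np.isclose(total, 1.0, atol=1e-6):
                raise ConfigError("age_distribution weights must sum to 1")


#: Baseline age-band weights for an adult general population (heavy-tailed
#: towards younger adults, as in southern-European regional registries).
DEFAULT_AGE_DISTRIBUTION = {
    "18-40": 0.475,
    "40-60": 0.351,
    "60-70": 0.109,
    "70-80": 0.054,
    ">80": 0.011,
}

#: Annual all-cause death probability by attained age band; yields roughly
#: 90% ten-year survival for the default age mix.
DEFAULT_DEATH_HAZARD = {
    "18-40": 0.0005,
    "40-60": 0.003,
    "60-70": 0.010,
    "70-80": 0.040,
    ">80": 0.120,
}

_ORGAN_SYSTEMS = (
    "circulatory",
    "endocrine",
    "mental",
    "musculoskeletal",
    "respiratory",
    "genitourinary",
    "digestive",
    "nervous",
)


def default_config(n_patients: int = 20_000, seed: int = 0) -> SimConfig:
    """Study-analogue default cohort: 10 years of follow-up (2013-2022) plus
    10 years of pre-baseline history, with a roster of common chronic
    conditions (metabolic, mental-health, cardiovascular, renal...) and
    directed enrichments reflecting well-known sequential patterns
    (metabolic disorders before hypertension and diabetes, substance use
    before anxiety, hypertension and diabetes before chronic kidney disease).
    """
    conditions = (
        ConditionSpec("METAB", 0.020, 0.030, 1.1, "chronic", "endocrine", 1.0),
        ConditionSpec("ANX", 0.018, -0.010, 1.8, "chronic", "mental", 0.8),
        ConditionSpec("HTN", 0.012, 0.060, 0.9, "chronic", "circulatory", 1.2),
        ConditionSpec("OSTEO", 0.008, 0.060, 1.4, "chronic", "musculoskeletal", 1.0),
        ConditionSpec("SUBST", 0.010, -0.020, 0.5, "chronic", "mental", 1.1),
        ConditionSpec("DM2", 0.006, 0.050, 0.9, "chronic", "endocrine", 1.5),
        ConditionSpec("CKD", 0.003, 0.080, 0.9, "chronic", "genitourinary", 2.5),
        ConditionSpec("MOOD", 0.010, 0.000, 1.6, "chronic", "mental", 1.2),
        ConditionSpec("THYR", 0.006, 0.020, 2.5, "chronic", "endocrine", 0.7),
        ConditionSpec("COPD", 0.004, 0.050, 0.8, "chronic", "respiratory", 1.8),
        ConditionSpec("NEO", 0.004, 0.060, 1.0, "neoplastic", "neoplasm", 3.0),
        ConditionSpec("PREG", 0.002, -0.080, 5.0, "pregnancy", "pregnancy", 0.5),
        ConditionSpec("ARI", 0.050, 0.000, 1.0, "acute", "respiratory", 0.3),
        ConditionSpec("INJ", 0.030, 0.010, 0.8, "acute", "musculoskeletal", 0.2),
    )
    pair_effects = (
        PairEffect("METAB", "HTN", 2.2),
        PairEffect("METAB", "DM2", 2.5),
        PairEffect("METAB", "OSTEO", 1.5),
        PairEffect("SUBST", "ANX", 2.0),
        PairEffect("ANX", "MOOD", 2.0),
        PairEffect("ANX", "HTN", 1.3),
        PairEffect("HTN", "CKD", 2.5),
        PairEffect("DM2", "CKD", 2.0),
    )
    return SimConfig(
        n_patients=n_patients,
        conditions=conditions,
        pair_effects=pair_effects,
        death_hazard=dict(DEFAULT_DEATH_HAZARD),
        age_distribution=dict(DEFAULT_AGE_DISTRIBUTION),
        seed=seed,
    )


def codemap_from_config(config: SimConfig) -> CodeMap:
    """Code map matching the raw codes that generate_cohort emits."""
    entries = {}
    for c in config.conditions:
        entries[f"{c.group_id}-01"] = GroupInfo(c.group_id, c.chronicity, c.organ_system)
    return CodeMap(entries)


def weights_from_config(config: SimConfig) -> WeightTable:
    return WeightTable({c.group_id: c.weight for c in config.conditions})


def _age_band_index(ages: np.ndarray) -> np.ndarray:
    edges = np.array([b[1] for b in AGE_BANDS[1:]])  # 40, 60, 70, 80
    return np.searchsorted(edges, ages, side="right")


def age_band_label(ages) -> np.ndarray:
    """Vectorised age -> band label (lower edge inclusive)."""
    idx = _age_band_index(np.asarray(ages, dtype=float))
    return np.asarray(AGE_BAND_LABELS, dtype=object)[idx]


def generate_cohort(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate one cohort.

    Returns (patients, events): patients has columns patient_id, sex
    ('F'/'M'), birth_date, death_date (NaT if alive at end of follow-up);
    events has patient_id, code, onset_date. Events span
    [start_date - history_years, end_date]; deaths occur only during
    follow-up (the cohort is alive at baseline by construction). The draw
    schedule is fixed by the configuration's shape (one death vector and two
    vectors per condition each year), so cohorts with the same seed differ
    only through the hazards that changed.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    conditions = config.conditions
    n_cond = len(conditions)

    # --- demographics ---------------------------------------------------
    band_probs = np.array(
        [config.age_distribution.get(l, 0.0) for l in AGE_BAND_LABELS]
        if config.age_distribution
        else [1 / len(AGE_BAND_LABELS)] * len(AGE_BAND_LABELS)
    )
    band_probs = band_probs / band_probs.sum()
    band_idx = rng.choice(len(AGE_BANDS), size=n, p=band_probs)
    lo = np.array([b[1] for b in AGE_BANDS])[band_idx]
    hi = np.array([b[2] for b in AGE_BANDS])[band_idx]
    age0 = lo + rng.random(n) * (hi - lo)  # age at baseline
    female = rng.random(n) < config.sex_ratio

    start = pd.Timestamp(config.start_date)
    end = pd.Timestamp(config.end_date)
    birth = start - pd.to_timedelta(np.round(age0 * 365.25), unit="D")

    # --- yearly simulation ----------------------------------------------
    first_year = config.start_date.year - config.history_years
    last_year = config.end_date.year
    years = np.arange(first_year, last_year + 1)

    is_absorbing = np.array([c.chronicity != "acute" for c in conditions])
    base = np.array([c.base_hazard for c in conditions])
    slope = np.array([c.age_slope for c in conditions])
    sexmul = np.array([c.sex_multiplier for c in conditions])
    gidx = {c.group_id: j for j, c in enumerate(conditions)}
    effects = [
        (gidx[p.antecedent], gidx[p.consequent], p.hazard_multiplier)
        for p in config.pair_effects
    ]

    # onset bookkeeping: year index of first onset (absorbing groups), or
    # a sentinel for "never"; used for pair-effect activation
    NEVER = last_year + 1
    onset_year = np.full((n, n_cond), NEVER, dtype=np.int32)
    alive = np.ones(n, dtype=bool)
    death_ts = np.full(n, np.datetime64("NaT"), dtype="datetime64[ns]")

    ev_patient: list[np.ndarray] = []
    ev_cond: list[np.ndarray] = []
    ev_date: list[np.ndarray] = []

    death_bands = np.array([config.death_hazard.get(l, 0.0) for l in AGE_BAND_LABELS])

    for year in years:
        year_start = pd.Timestamp(year, 1, 1)
        year_days = 366 if pd.Timestamp(year, 12, 31).dayofyear == 366 else 365
        age_y = (year_start - birth).days / 365.25

        # deaths first (follow-up only; everyone is alive at baseline)
        u_death = rng.random(n)
        if year >= config.start_date.year:
            h_death = death_bands[_age_band_index(age_y)]
            dies = alive & (u_death < h_death)
            day_frac = rng.random(n)  # full-width draw keeps stream stable
            if dies.any():
                offs = np.floor(day_frac[dies] * year_days).astype(int)
                ts = year_start + pd.to_timedelta(offs, unit="D")
                death_ts[dies] = np.minimum(ts.values, end.to_numpy())
                alive[dies] = False

        eligible_age = age_y >= 18.0
        for j, cond in enumerate(conditions):
            u = rng.random(n)
            u_day = rng.random(n)
            mult = np.ones(n)
            for a_idx, c_idx, m in effects:
                if c_idx == j:
                    active = onset_year[:, a_idx] < year
                    mult = np.where(active, mult * m, mult)
            hazard = base[j] * np.exp(slope[j] * (age_y - 50.0))
            hazard = np.where(female, hazard * sexmul[j], hazard)
            hazard = np.clip(hazard * mult, 0.0, 1.0)
            can = alive & eligible_age
            if is_absorbing[j]:
                can &= onset_year[:, j] == NEVER
            onset = can & (u < hazard)
            if not onset.any():
                continue
            if is_absorbing[j]:
                onset_year[onset, j] = year
            offs = np.floor(u_day[onset] * year_days).astype(int)
            ts = (year_start + pd.to_timedelta(offs, unit="D")).values
            ts = np.minimum(ts, end.to_numpy())
            idx = np.nonzero(onset)[0]
            ev_patient.append(idx)
            ev_cond.append(np.full(idx.size, j, dtype=np.int32))
            ev_date.append(ts)

    patient_ids = np.array([f"P{i:07d}" for i in range(n)], dtype=object)
    patients = pd.DataFrame(
        {
            "patient_id": patient_ids,
            "sex": np.where(female, "F", "M"),
            "birth_date": birth,
            "death_date": pd.to_datetime(death_ts),
        }
    )

    if ev_patient:
        pi = np.concatenate(ev_patient)
        ci = np.concatenate(ev_cond)
        di = np.concatenate(ev_date)
        codes = np.array([f"{c.group_id}-01" for c in conditions], dtype=object)
        events = pd.DataFrame(
            {
                "patient_id": patient_ids[pi],
                "code": codes[ci],
                "onset_date": pd.to_datetime(di),
            }
        )
        events = events.sort_values(
            ["patient_id", "onset_date", "code"], kind="mergesort"
        ).reset_index(drop=True)
    else:
        events = pd.DataFrame(
            {
                "patient_id": pd.Series([], dtype=object),
                "code": pd.Series([], dtype=object),
                "onset_date": pd.Series([], dtype="datetime64[ns]"),
            }
        )
    return patients, events


def make_toy_codemap(n_groups: int) -> CodeMap:
    """Small stand-in for a clinical grouping of raw diagnosis codes.

    Produces n_groups diagnostic groups (G01, G02, ...), each with two raw
    codes, cycling chronicity classes so that at least one chronic and one
    acute group are always present, and cycling organ systems.
    """
    if n_groups < 2:
        raise ConfigError("n_groups must be >= 2")
    chronicity_cycle = ("chronic", "acute", "chronic", "neoplastic", "chronic", "pregnancy")
    entries = {}
    for i in range(n_groups):
        gid = f"G{i + 1:02d}"
        chron = chronicity_cycle[i % len(chronicity_cycle)]
        organ = "pregnancy" if chron == "pregnancy" else _ORGAN_SYSTEMS[i % len(_ORGAN_SYSTEMS)]
        info = GroupInfo(gid, chron, organ)
        entries[f"{gid}.0"] = info
        entries[f"{gid}.1"] = info
    return CodeMap(entries)


def write_cohort(patients: pd.DataFrame, events: pd.DataFrame, out_dir) -> None:
    """Write patients.csv / events.csv with ISO-8601 dates."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    p = patients.copy()
    p["birth_date"] = pd.to_datetime(p["birth_date"]).dt.strftime("%Y-%m-%d")
    p["death_date"] = pd.to_datetime(p["death_date"]).dt.strftime("%Y-%m-%d")
    p.to_csv(out / "patients.csv", index=False)
    e = events.copy()
    e["onset_date"] = pd.to_datetime(e["onset_date"]).dt.strftime("%Y-%m-%d")
    e.to_csv(out / "events.csv", index=False)


def read_cohort(in_dir) -> tuple[pd.DataFrame, pd.DataFrame]:
    from pathlib import Path

    p = pd.read_csv(Path(in_dir) / "patients.csv", parse_dates=["birth_date", "death_date"])
    e = pd.read_csv(Path(in_dir) / "events.csv", parse_dates=["onset_date"])
    return p, e
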
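"""Morbidity index: validation, grouping, weighted summation, stratification.

The index is a case-mix summary of an individual's diagnostic burden:
validated diagnoses are grouped into diagnostic groups, persistent groups
(chronic, neoplastic, pregnancy-related) stay active from onset onward while
acute groups contribute only within a one-year window before the evaluation
date, and the complexity weights of the active groups are summed into a
continuous, non-negative score. Population percentiles of the score at the
50th, 80th and 95th centiles cut the population into four risk strata
(low, moderate, high, very high); crossing the 80th-percentile threshold is
the clinical-complexity transition studied downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .codemap import PERSISTENT_CLASSES, WeightTable

__all__ = [
    "STRATA",
    "GroupRule",
    "ValidationRules",
    "PatientStateAtDate",
    "StratumThresholds",
    "validate_diagnoses",
    "patient_state",
    "compute_index",
    "assign_morbidity_group",
    "compute_thresholds",
    "stratify",
    "stratify_values",
    "index_trajectory",
    "cohort_index_table",
]

STRATA = ("low", "moderate", "high", "very_high")

DEFAULT_ACUTE_WINDOW_DAYS = 365


@dataclass(frozen=True)
class GroupRule:
    """Demographic plausibility constraints for one diagnostic group."""

    min_age: float | None = None
    max_age: float | None = None
    allowed_sex: str | None = None  # 'F' or 'M'

    def __post_init__(self):
        if self.min_age is not None and self.max_age is not None:
            if self.min_age > self.max_age:
                raise ValueError("min_age must not exceed max_age")


@dataclass
class ValidationRules:
    """Per-group plausibility rules applied before index computation."""

    group_rules: dict[str, GroupRule] = field(default_factory=dict)

    def rule_for(self, group_id: str) -> GroupRule | None:
        return self.group_rules.get(group_id)


@dataclass
class PatientStateAtDate:
    """Active diagnostic groups of one patient at an evaluation date."""

    patient_id: str
    as_of_date: pd.Timestamp
    active_groups: set  # of (group_id, chronicity)
    organ_systems: set  # organ systems of active chronic groups

    @property
    def n_chronic(self) -> int:
        return sum(1 for _, c in self.active_groups if c == "chronic")

    @property
    def n_organ_systems(self) -> int:
        return len(self.organ_systems)

    @property
    def has_neoplasia(self) -> bool:
        return any(c == "neoplastic" for _, c in self.active_groups)

    @property
    def has_pregnancy(self) -> bool:
        return any(c == "pregnancy" for _, c in self.active_groups)

    @property
    def has_acute(self) -> bool:
        return any(c == "acute" for _, c in self.active_groups)


@dataclass(frozen=True)
class StratumThresholds:
    """Index values at the 50th/80th/95th population percentiles."""

    p50: float
    p80: float
    p95: float

    def __post_init__(self):
        if not (self.p50 <= self.p80 <= self.p95):
            raise ValueError("thresholds must satisfy p50 <= p80 <= p95")


def validate_diagnoses(
    events: pd.DataFrame,
    patients: pd.DataFrame,
    rules: ValidationRules | None = None,
    period: tuple | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Filter mapped diagnosis events for demographic and temporal plausibility.

    Parameters
    ----------
    events
        Mapped events with patient_id, group_id, onset_date (see
        :func:`morbinet.codemap.map_events`).
    patients
        Patient table with patient_id, sex, birth_date.
    rules
        Optional per-group constraints (minimum/maximum onset age, allowed
        sex).
    period
        Optional (start, end) analysis period; events dated outside it are
        rejected with reason ``"out of period"``.

    Returns
    -------
    (kept, rejections)
        ``kept`` is the subset of ``events`` passing every applicable rule;
        ``rejections`` records one row per dropped event with a ``reason``
        column ("pre-birth", "out of period", "age below minimum",
        "age above maximum", "sex not allowed").
    """
    rules = rules or ValidationRules()
    merged = events.merge(
        patients[["patient_id", "sex", "birth_date"]], on="patient_id", how="left"
    )
    onset = pd.to_datetime(merged["onset_date"])
    birth = pd.to_datetime(merged["birth_date"])
    age_at_onset = (onset - birth).dt.days / 365.25

    reason = pd.Series(pd.NA, index=merged.index, dtype=object)
    pre_birth = onset < birth
    reason[pre_birth] = "pre-birth"
    if period is not None:
        start, end = pd.Timestamp(period[0]), pd.Timestamp(period[1])
        out = (onset < start) | (onset > end)
        reason[out & reason.isna()] = "out of period"
    for gid, rule in rules.group_rules.items():
        in_group = merged["group_id"] == gid
        if rule.min_age is not None:
            bad = in_group & (age_at_onset < rule.min_age)
            reason[bad & reason.isna()] = "age below minimum"
        if rule.max_age is not None:
            bad = in_group & (age_at_onset > rule.max_age)
            reason[bad & reason.isna()] = "age above maximum"
        if rule.allowed_sex is not None:
            bad = in_group & (merged["sex"] != rule.allowed_sex)
            reason[bad & reason.isna()] = "sex not allowed"

    dropped = reason.notna()
    kept = events.loc[~dropped.values].copy()
    rejections = events.loc[dropped.values].copy()
    rejections["reason"] = reason[dropped].values
    return kept, rejections


def patient_state(
    events: pd.DataFrame,
    as_of_date,
    acute_window_days: int = DEFAULT_ACUTE_WINDOW_DAYS,
    patient_id: str = "",
) -> PatientStateAtDate:
    """Active groups of one patient's mapped events at an evaluation date.

    Persistent groups (chronic/neoplastic/pregnancy) are active iff their
    onset is on or before the date; acute groups iff the onset lies in the
    half-open window (date - acute_window_days, date].
    """
    as_of = pd.Timestamp(as_of_date)
    window_start = as_of - pd.Timedelta(days=acute_window_days)
    active: set = set()
    organs: set = set()
    if len(events):
        onset = pd.to_datetime(events["onset_date"])
        persistent = events["chronicity"].isin(PERSISTENT_CLASSES) & (onset <= as_of)
        acute = (events["chronicity"] == "acute") & (onset > window_start) & (onset <= as_of)
        act = events.loc[persistent | acute]
        active = set(zip(act["group_id"], act["chronicity"]))
        organs = set(act.loc[act["chronicity"] == "chronic", "organ_system"])
    return PatientStateAtDate(patient_id, as_of, active, organs)


def compute_index(state: PatientStateAtDate, weights: WeightTable) -> float:
    """Weighted sum of the patient's active diagnostic groups (0 if none)."""
    return float(sum(weights.weight(g) for g, _ in state.active_groups))


def assign_morbidity_group(state: PatientStateAtDate) -> str:
    """Mutually exclusive morbidity category, by hierarchy.

    Active neoplasia takes precedence, then pregnancy/childbirth, then the
    count of organ systems affected by chronic conditions, then recent acute
    illness; anything else is healthy.
    """
    if state.has_neoplasia:
        return "neoplasia"
    if state.has_pregnancy:
        return "pregnancy"
    if state.n_chronic >= 1:
        return f"chronic_{state.n_organ_systems}_systems"
    if state.has_acute:
        return "acute"
    return "healthy"


def compute_thresholds(
    index_values: Iterable[float], percentiles: Sequence[float] = (50, 80, 95)
) -> StratumThresholds:
    """Percentile cut points of a reference index distribution.

    Uses linear interpolation between order statistics. Requires at least 20
    values; smaller samples give unstable strata.
    """
    values = np.asarray(list(index_values), dtype=float)
    if values.size < 20:
        raise ValueError(f"need >= 20 index values to compute thresholds, got {values.size}")
    q = np.percentile(values, percentiles, method="linear")
    return StratumThresholds(float(q[0]), float(q[1]), float(q[2]))


def stratify(index_value: float, thresholds: StratumThresholds) -> str:
    """Risk stratum of one index value; boundaries inclusive on the lower edge."""
    if index_value < thresholds.p50:
        return "low"
    if index_value < thresholds.p80:
        return "moderate"
    if index_value < thresholds.p95:
        return "high"
    return "very_high"


def stratify_values(values, thresholds: StratumThresholds) -> np.ndarray:
    """Vectorised :func:`stratify`."""
    v = np.asarray(values, dtype=float)
    edges = np.array([thresholds.p50, thresholds.p80, thresholds.p95])
    idx = np.searchsorted(edges, v, side="right")
    return np.asarray(STRATA, dtype=object)[idx]


def index_trajectory(
    patient: Mapping,
    events: pd.DataFrame,
    weights: WeightTable,
    evaluation_dates: Sequence,
    thresholds: StratumThresholds | None = None,
    acute_window_days: int = DEFAULT_ACUTE_WINDOW_DAYS,
) -> pd.DataFrame:
    """Yearly index series for one patient.

    One row per evaluation date not after the patient's death, each
    consistent with patient_state -> compute_index -> stratify at that date.
    """
    pid = patient["patient_id"]
    death = patient.get("death_date", pd.NaT)
    death = pd.Timestamp(death) if pd.notna(death) else pd.NaT
    rows = []
    for d in evaluation_dates:
        d = pd.Timestamp(d)
        if pd.notna(death) and d > death:
            break
        state = patient_state(events, d, acute_window_days, patient_id=pid)
        value = compute_index(state, weights)
        row = {
            "patient_id": pid,
            "date": d,
            "index": value,
            "morbidity_group": assign_morbidity_group(state),
        }
        if thresholds is not None:
            row["stratum"] = stratify(value, thresholds)
        rows.append(row)
    return pd.DataFrame(rows)


def cohort_index_table(
    patients: pd.DataFrame,
    events: pd.DataFrame,
    weights: WeightTable,
    evaluation_dates: Sequence,
    acute_window_days: int = DEFAULT_ACUTE_WINDOW_DAYS,
) -> pd.DataFrame:
    """Index of every patient at every evaluation date (vectorised).

    Returns a long table (patient_id, date, index) with one row per patient
    per date not after that patient's death. Equivalent to per-patient
    :func:`index_trajectory` but computed with table operations.
    """
    ev = events.copy()
    ev["onset_date"] = pd.to_datetime(ev["onset_date"])
    wmap = weights.as_dict()
    default = weights.default
    death = patients.set_index("patient_id")["death_date"]

    out = []
    for d in evaluation_dates:
        d = pd.Timestamp(d)
        window_start = d - pd.Timedelta(days=acute_window_days)
        persistent = ev["chronicity"].isin(PERSISTENT_CLASSES) & (ev["onset_date"] <= d)
        acute = (
            (ev["chronicity"] == "acute")
            & (ev["onset_date"] > window_start)
            & (ev["onset_date"] <= d)
        )
        act = ev.loc[persistent | acute, ["patient_id", "group_id"]].drop_duplicates()
        w = act["group_id"].map(wmap)
        if w.isna().any():
            if default is None:
                missing = sorted(act.loc[w.isna(), "group_id"].unique())
                from .codemap import MissingWeightError

                raise MissingWeightError(f"no weight for groups {missing} and no default")
            w = w.fillna(default)
        scores = w.groupby(act["patient_id"].values).sum()
        frame = pd.DataFrame({"patient_id": patients["patient_id"]})
        frame["date"] = d
        frame["index"] = frame["patient_id"].map(scores).fillna(0.0)
        dd = frame["patient_id"].map(death)
        frame = frame.loc[dd.isna() | (d <= dd)]
        out.append(frame)
    table = pd.concat(out, ignore_index=True)
    return table
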
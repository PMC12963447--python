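"""Outcome detection and baseline predictor construction.

The endpoint is the first passage of a patient's morbidity index from the
low/moderate strata (index below the population's 80th percentile) to the
high/very-high strata (index at or above it) on a yearly evaluation grid.
The primary analysis restricts to individuals below the 80th-percentile
threshold at baseline who remain alive through the whole follow-up; a
multi-state tabulation over {low/moderate, high/very-high, dead} quantifies
what that restriction leaves out.

Three nested predictor sets are built at baseline: a base set (age, sex), a
complexity set adding six longitudinal morbidity summaries, and a
full-disease set further adding one binary indicator per chronic diagnostic
group present at baseline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .codemap import WeightTable
from .index import (
    DEFAULT_ACUTE_WINDOW_DAYS,
    StratumThresholds,
    cohort_index_table,
    stratify,
    stratify_values,
)
from .simulate import AGE_BAND_LABELS, age_band_label

__all__ = [
    "TransitionOutcome",
    "detect_transition",
    "transition_outcomes",
    "build_features",
    "build_feature_table",
    "multistate_tabulation",
    "descriptive_summary",
    "CHRONIC_COUNT_BINS",
]

FEATURE_SPECS = ("base", "complexity", "full_disease")

COMPLEXITY_FEATURES = (
    "n_chronic",
    "years_since_first_chronic",
    "years_since_last_chronic",
    "index_now",
    "index_at_first_chronic",
    "index_at_penultimate_chronic",
)

CHRONIC_COUNT_BINS = ("0", "1", "2", "3", "4", "5", "6", "7", ">=8")


@dataclass
class TransitionOutcome:
    """Per-patient endpoint: did the index ever reach the 80th percentile."""

    patient_id: str
    eligible: bool
    event: bool
    transition_date: pd.Timestamp | None


def detect_transition(
    series: pd.DataFrame,
    thresholds: StratumThresholds,
    death_date=None,
    end_date=None,
) -> TransitionOutcome:
    """First passage of one patient's index series above the P80 threshold.

    ``series`` is one patient's (date, index) table with the first row at
    baseline. The patient is eligible for the primary analysis iff the
    baseline index is below p80 and the patient is alive at ``end_date``.
    A baseline at or above p80 marks the patient ineligible (not an error).
    """
    if not len(series):
        raise ValueError("series must be nonempty")
    s = series.sort_values("date")
    pid = str(s["patient_id"].iloc[0]) if "patient_id" in s.columns else ""
    crossed = s.loc[s["index"].values >= thresholds.p80]
    event = len(crossed) > 0
    transition_date = pd.Timestamp(crossed["date"].iloc[0]) if event else None
    baseline_ok = float(s["index"].iloc[0]) < thresholds.p80
    alive_at_end = True
    if death_date is not None and pd.notna(death_date) and end_date is not None:
        alive_at_end = pd.Timestamp(death_date) > pd.Timestamp(end_date)
    eligible = baseline_ok and alive_at_end
    return TransitionOutcome(pid, eligible, event, transition_date)


def transition_outcomes(
    index_table: pd.DataFrame,
    thresholds: StratumThresholds,
    patients: pd.DataFrame,
    end_date,
) -> pd.DataFrame:
    """Vectorised :func:`detect_transition` over a cohort index table.

    Returns one row per patient: baseline_index, baseline_stratum, eligible,
    event, transition_date (NaT if no crossing).
    """
    end = pd.Timestamp(end_date)
    t = index_table.sort_values(["patient_id", "date"])
    baseline = t.groupby("patient_id", sort=True).first()
    crossing = t.loc[t["index"].values >= thresholds.p80]
    first_cross = crossing.groupby("patient_id")["date"].min()

    out = pd.DataFrame(index=baseline.index)
    out["baseline_index"] = baseline["index"]
    out["baseline_stratum"] = stratify_values(baseline["index"].values, thresholds)
    death = patients.set_index("patient_id")["death_date"].reindex(out.index)
    alive_at_end = death.isna() | (death > end)
    out["alive_at_end"] = alive_at_end
    out["eligible"] = (baseline["index"] < thresholds.p80) & alive_at_end
    out["transition_date"] = first_cross.reindex(out.index)
    out["event"] = out["transition_date"].notna()
    return out.reset_index()


def _index_at_dates(
    dates_by_patient: pd.Series,
    events: pd.DataFrame,
    weights: WeightTable,
    acute_window_days: int = DEFAULT_ACUTE_WINDOW_DAYS,
) -> pd.Series:
    """Morbidity index of each patient at a patient-specific date.

    ``dates_by_patient``: Series indexed by patient_id holding one evaluation
    date per patient (NaT rows get index 0).
    """
    from .codemap import PERSISTENT_CLASSES

    ev = events.merge(
        dates_by_patient.rename("ref_date"), left_on="patient_id", right_index=True
    )
    onset = pd.to_datetime(ev["onset_date"])
    ref = pd.to_datetime(ev["ref_date"])
    persistent = ev["chronicity"].isin(PERSISTENT_CLASSES) & (onset <= ref)
    acute = (
        (ev["chronicity"] == "acute")
        & (onset > ref - pd.Timedelta(days=acute_window_days))
        & (onset <= ref)
    )
    act = ev.loc[persistent | acute, ["patient_id", "group_id"]].drop_duplicates()
    wmap = weights.as_dict()
    w = act["group_id"].map(wmap)
    if weights.default is not None:
        w = w.fillna(weights.default)
    scores = w.groupby(act["patient_id"].values).sum()
    return scores.reindex(dates_by_patient.index).fillna(0.0)


def build_feature_table(
    patients: pd.DataFrame,
    events: pd.DataFrame,
    weights: WeightTable,
    baseline_date,
    spec: str = "complexity",
    acute_window_days: int = DEFAULT_ACUTE_WINDOW_DAYS,
    study_period: tuple | None = None,
) -> pd.DataFrame:
    """Baseline predictors for every patient, per model specification.

    base: age (years at baseline) and is_female. complexity: adds the number
    of chronic conditions at baseline, years since the first and the most
    recent chronic onset, the index at baseline, and the index evaluated at
    the first and at the penultimate chronic onset dates. full_disease: adds
    one 0/1 column ``has_<group>`` per chronic diagnostic group present at
    baseline. Patients with no chronic condition get 0 for every
    time-since/index-at feature; with exactly one, the penultimate-onset
    feature is evaluated at that single onset.
    """
    if spec not in FEATURE_SPECS:
        raise ValueError(f"unknown feature spec {spec!r}")
    baseline = pd.Timestamp(baseline_date)
    if study_period is not None:
        start, end = pd.Timestamp(study_period[0]), pd.Timestamp(study_period[1])
        if not (start <= baseline <= end):
            raise ValueError(f"baseline {baseline.date()} outside study period")

    pidx = patients.set_index("patient_id")
    out = pd.DataFrame(index=pidx.index)
    out["age"] = (baseline - pd.to_datetime(pidx["birth_date"])).dt.days / 365.25
    out["is_female"] = (pidx["sex"] == "F").astype(int)
    if spec == "base":
        return out.reset_index()

    ev = events.copy()
    ev["onset_date"] = pd.to_datetime(ev["onset_date"])
    chronic = ev.loc[(ev["chronicity"] == "chronic") & (ev["onset_date"] <= baseline)]
    # first onset per patient-group, then per-patient ordered onset dates
    onsets = (
        chronic.groupby(["patient_id", "group_id"], sort=True)["onset_date"]
        .min()
        .reset_index()
        .sort_values(["patient_id", "onset_date", "group_id"], kind="mergesort")
    )
    g = onsets.groupby("patient_id")["onset_date"]
    first = g.first()
    last = g.last()
    n_chronic = g.size()
    # penultimate onset; for a single chronic condition, that onset itself
    pos_from_end = onsets.groupby("patient_id").cumcount(ascending=False)
    sizes = onsets["patient_id"].map(n_chronic)
    take = (pos_from_end == 1) | (sizes == 1)
    penult = onsets.loc[take].set_index("patient_id")["onset_date"]

    out["n_chronic"] = n_chronic.reindex(out.index).fillna(0).astype(int)
    out["years_since_first_chronic"] = (
        ((baseline - first).dt.days / 365.25).reindex(out.index).fillna(0.0)
    )
    out["years_since_last_chronic"] = (
        ((baseline - last).dt.days / 365.25).reindex(out.index).fillna(0.0)
    )
    baseline_dates = pd.Series(baseline, index=out.index)
    out["index_now"] = _index_at_dates(baseline_dates, ev, weights, acute_window_days)
    out["index_at_first_chronic"] = _index_at_dates(
        first.reindex(out.index), ev, weights, acute_window_days
    )
    out["index_at_penultimate_chronic"] = _index_at_dates(
        penult.reindex(out.index), ev, weights, acute_window_days
    )
    if spec == "full_disease":
        present = onsets.assign(v=1).pivot_table(
            index="patient_id", columns="group_id", values="v", fill_value=0
        )
        for gid in sorted(present.columns):
            out[f"has_{gid}"] = present[gid].reindex(out.index).fillna(0).astype(int)
    return out.reset_index()


def build_features(
    patient,
    events: pd.DataFrame,
    weights: WeightTable,
    baseline_date,
    spec: str = "complexity",
    acute_window_days: int = DEFAULT_ACUTE_WINDOW_DAYS,
) -> dict:
    """Predictors for a single patient (see :func:`build_feature_table`)."""
    p = pd.DataFrame([dict(patient)])
    ev = events.loc[events["patient_id"] == patient["patient_id"]]
    table = build_feature_table(p, ev, weights, baseline_date, spec, acute_window_days)
    return table.iloc[0].to_dict()


def multistate_tabulation(
    index_table: pd.DataFrame,
    thresholds: StratumThresholds,
    patients: pd.DataFrame,
    grid_dates,
) -> pd.DataFrame:
    """Occupancy of {low_moderate, high_veryhigh, dead} at each grid date.

    Death is absorbing; every patient contributes exactly one state per
    date, so rows sum to the cohort size. Once a patient's index reaches the
    p80 threshold, subsequent alive states remain high_veryhigh only if the
    index stays there — occupancy reflects the current index, not history.
    """
    death = patients.set_index("patient_id")["death_date"]
    wide = index_table.pivot(index="patient_id", columns="date", values="index")
    wide = wide.reindex(patients["patient_id"])
    rows = []
    for d in grid_dates:
        d = pd.Timestamp(d)
        dead = death.reindex(wide.index).notna() & (death.reindex(wide.index) < d)
        vals = wide[d] if d in wide.columns else pd.Series(np.nan, index=wide.index)
        high = ~dead & (vals >= thresholds.p80)
        low = ~dead & ~high
        rows.append(
            {
                "date": d,
                "low_moderate": int(low.sum()),
                "high_veryhigh": int(high.sum()),
                "dead": int(dead.sum()),
            }
        )
    return pd.DataFrame(rows)


def _quantiles(values: np.ndarray) -> tuple[float, float]:
    q25, q75 = np.percentile(values, [25, 75], method="linear")
    return float(q25), float(q75)


def descriptive_summary(
    patients: pd.DataFrame,
    events: pd.DataFrame,
    weights: WeightTable,
    thresholds: StratumThresholds,
    baseline_date,
    end_date,
    acute_window_days: int = DEFAULT_ACUTE_WINDOW_DAYS,
) -> dict:
    """Cohort characteristics at baseline and at the end of follow-up.

    Produces, for each of the two time points: age-band counts, sex counts,
    risk-strata counts, mean/SD and interquartile range of the morbidity
    index, the distribution of the chronic-condition count (0..7, >=8), and
    mean years since the first and the most recent chronic onset among
    patients with at least one chronic condition.
    """
    summary: dict = {"n_patients": int(len(patients))}
    for label, when in (("baseline", baseline_date), ("end_of_study", end_date)):
        when = pd.Timestamp(when)
        age = (when - pd.to_datetime(patients["birth_date"])).dt.days / 365.25
        bands = pd.Series(age_band_label(age.values))
        tab = cohort_index_table(patients, events, weights, [when], acute_window_days)
        idx = tab.set_index("patient_id")["index"].reindex(patients["patient_id"]).fillna(0.0)
        strata = pd.Series(stratify_values(idx.values, thresholds))
        chronic = events.loc[
            (events["chronicity"] == "chronic")
            & (pd.to_datetime(events["onset_date"]) <= when)
        ]
        onsets = chronic.groupby(["patient_id", "group_id"])["onset_date"].min()
        per_patient = onsets.groupby("patient_id")
        n_cond = per_patient.size().reindex(patients["patient_id"]).fillna(0).astype(int)
        binned = np.minimum(n_cond.values, 8)
        first = per_patient.min()
        last = per_patient.max()
        ys_first = (when - pd.to_datetime(first)).dt.days / 365.25
        ys_last = (when - pd.to_datetime(last)).dt.days / 365.25
        q25, q75 = _quantiles(idx.values)
        summary[label] = {
            "age_bands": {b: int((bands == b).sum()) for b in AGE_BAND_LABELS},
            "sex": {s: int((patients["sex"] == s).sum()) for s in ("F", "M")},
            "strata": {s: int((strata == s).sum()) for s in ("low", "moderate", "high", "very_high")},
            "index_mean": float(idx.mean()),
            "index_sd": float(idx.std()),
            "index_iqr": (q25, q75),
            "chronic_count_bins": {
                CHRONIC_COUNT_BINS[k]: int((binned == k).sum()) for k in range(9)
            },
            "n_with_condition": int(len(first)),
            "mean_years_since_first": float(ys_first.mean()) if len(first) else float("nan"),
            "mean_years_since_last": float(ys_last.mean()) if len(last) else float("nan"),
        }
    return summary
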
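"""Prediction of the complexity transition with four learner families.

The binary endpoint (reaching the high/very-high strata within follow-up) is
modelled with a generalized linear model, a random forest, a single-hidden-
layer neural network, and gradient-boosted trees, each over three nested
predictor specifications (base, complexity, full_disease). Protocol: a
stratified 70/30 train/test split; hyperparameters chosen by repeated
stratified 5-fold cross-validation inside the training partition only;
discrimination reported on the held-out test set as AUROC and AUPRC;
variable contributions measured uniformly as permutation importance so the
four learner families are comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.inspection import permutation_importance
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import GridSearchCV, RepeatedStratifiedKFold, train_test_split
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.ensemble import RandomForestClassifier
from xgboost import XGBClassifier

__all__ = [
    "LEARNERS",
    "SPEC_NAMES",
    "ModelSpec",
    "FittedModel",
    "EvalResult",
    "split_cohort",
    "fit_and_tune",
    "evaluate",
    "compare_specs",
    "dedicated_vs_general",
]

LEARNERS = ("glm", "random_forest", "neural_net", "xgboost")
SPEC_NAMES = ("base", "complexity", "full_disease")

OUTCOME_COL = "event"

#: small fixed hyperparameter grids searched inside the training partition
DEFAULT_GRIDS: dict[str, dict] = {
    "glm": {"model__C": [0.01, 1.0, 100.0]},
    "random_forest": {"model__max_depth": [4, 12]},
    "neural_net": {"model__alpha": [1e-4, 1e-2]},
    "xgboost": {"model__max_depth": [2, 4]},
}


@dataclass(frozen=True)
class ModelSpec:
    """One predictor specification x learner combination."""

    spec_name: str
    learner: str
    hyperparameters: dict | None = None
    seed: int = 0
    cv_repeats: int = 3

    def __post_init__(self):
        if self.spec_name not in SPEC_NAMES:
            raise ValueError(f"unknown spec {self.spec_name!r}")
        if self.learner not in LEARNERS:
            raise ValueError(f"unknown learner {self.learner!r}")


@dataclass
class FittedModel:
    spec: ModelSpec
    estimator: Pipeline
    feature_names: list[str]
    chosen_hyperparameters: dict
    dropped_features: list[str] = field(default_factory=list)

    def predict_scores(self, rows: pd.DataFrame) -> np.ndarray:
        return self.estimator.predict_proba(rows[self.feature_names].values)[:, 1]


@dataclass
class EvalResult:
    auroc: float
    auprc: float
    n_test: int
    event_rate: float
    importances: dict[str, float]
    test_fingerprint: int = 0


def _feature_columns(rows: pd.DataFrame) -> list[str]:
    return [c for c in rows.columns if c not in (OUTCOME_COL, "patient_id")]


def split_cohort(
    rows: pd.DataFrame, train_fraction: float = 0.7, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stratified, disjoint, exhaustive train/test partition."""
    if len(rows) < 10:
        raise ValueError("need at least 10 rows to split")
    y = rows[OUTCOME_COL].astype(int)
    if y.nunique() < 2:
        raise ValueError("both outcome classes must be present to split")
    train, test = train_test_split(
        rows, train_size=train_fraction, stratify=y, random_state=seed
    )
    return train, test


def _make_pipeline(spec: ModelSpec) -> Pipeline:
    seed = spec.seed
    if spec.learner == "glm":
        model = LogisticRegression(max_iter=2000)
    elif spec.learner == "random_forest":
        model = RandomForestClassifier(n_estimators=200, random_state=seed, n_jobs=1)
    elif spec.learner == "neural_net":
        model = MLPClassifier(
            hidden_layer_sizes=(16,), max_iter=400, random_state=seed
        )
    else:  # xgboost
        model = XGBClassifier(
            n_estimators=150,
            learning_rate=0.1,
            random_state=seed,
            n_jobs=1,
            eval_metric="logloss",
        )
    return Pipeline([("scale", StandardScaler()), ("model", model)])


def fit_and_tune(spec: ModelSpec, train: pd.DataFrame) -> FittedModel:
    """Fit one spec x learner with internal repeated 5-fold tuning.

    Only the training partition is seen; zero-variance features are dropped
    with a warning. The chosen hyperparameters are recorded on the result.
    """
    import warnings

    features = _feature_columns(train)
    X = train[features]
    variances = X.var(axis=0)
    dropped = [c for c in features if variances[c] == 0]
    if dropped:
        warnings.warn(f"dropping zero-variance features: {dropped}")
        features = [c for c in features if c not in dropped]
        X = train[features]
    y = train[OUTCOME_COL].astype(int).values

    pipeline = _make_pipeline(spec)
    grid = spec.hyperparameters or DEFAULT_GRIDS[spec.learner]
    cv = RepeatedStratifiedKFold(
        n_splits=5, n_repeats=spec.cv_repeats, random_state=spec.seed
    )
    search = GridSearchCV(pipeline, grid, scoring="roc_auc", cv=cv, n_jobs=1, refit=True)
    search.fit(X.values, y)
    fitted = FittedModel(
        spec=spec,
        estimator=search.best_estimator_,
        feature_names=features,
        chosen_hyperparameters=dict(search.best_params_),
        dropped_features=dropped,
    )
    return fitted


def _fingerprint(test: pd.DataFrame) -> int:
    if "patient_id" in test.columns:
        key = tuple(sorted(map(str, test["patient_id"])))
    else:
        key = tuple(sorted(test.index))
    return hash(key)


def evaluate(
    model: FittedModel,
    test: pd.DataFrame,
    n_permutations: int = 5,
    compute_importance: bool = True,
) -> EvalResult:
    """Held-out discrimination metrics and permutation importances.

    AUROC is the rank statistic (probability a random event row outranks a
    random non-event row, ties counted one half); AUPRC is the step-wise
    integral of the precision-recall curve. Importance per feature is the
    mean AUROC drop over seeded score-column permutations.
    """
    y = test[OUTCOME_COL].astype(int).values
    if len(np.unique(y)) < 2:
        raise ValueError("test partition must contain both outcome classes")
    X = test[model.feature_names]
    scores = model.estimator.predict_proba(X.values)[:, 1]
    auroc = float(roc_auc_score(y, scores))
    auprc = float(average_precision_score(y, scores))
    importances: dict[str, float] = {}
    if compute_importance:
        # wrapper exposing named columns to sklearn's permutation importance
        result = permutation_importance(
            model.estimator,
            X.values,
            y,
            scoring="roc_auc",
            n_repeats=n_permutations,
            random_state=model.spec.seed,
        )
        importances = dict(zip(model.feature_names, result.importances_mean.tolist()))
    return EvalResult(
        auroc=auroc,
        auprc=auprc,
        n_test=int(len(test)),
        event_rate=float(y.mean()),
        importances=importances,
        test_fingerprint=_fingerprint(test),
    )


def compare_specs(results: dict[tuple[str, str], EvalResult]) -> pd.DataFrame:
    """Tabulate spec x learner metrics evaluated on one common test set.

    Raises if the entries were not evaluated on identical test rows; adds
    the AUROC difference of each row against the base spec for the same
    learner where available.
    """
    if len(results) < 2:
        raise ValueError("need at least two evaluated specs to compare")
    fingerprints = {r.test_fingerprint for r in results.values()}
    if len(fingerprints) != 1:
        raise ValueError("results were evaluated on different test sets")
    rows = []
    for (spec_name, learner), r in sorted(results.items()):
        rows.append(
            {
                "spec": spec_name,
                "learner": learner,
                "auroc": r.auroc,
                "auprc": r.auprc,
                "n_test": r.n_test,
                "event_rate": r.event_rate,
            }
        )
    table = pd.DataFrame(rows)
    base = table.loc[table["spec"] == "base"].set_index("learner")["auroc"]
    table["auroc_vs_base"] = table.apply(
        lambda row: row["auroc"] - base[row["learner"]] if row["learner"] in base.index else np.nan,
        axis=1,
    )
    return table


def dedicated_vs_general(
    features: pd.DataFrame,
    condition_columns: list[str],
    spec: ModelSpec,
    min_prevalence: float = 0.01,
    min_subgroup: int = 60,
    train_fraction: float = 0.7,
) -> pd.DataFrame:
    """General model vs condition-dedicated models on baseline subgroups.

    For each condition indicator column with baseline prevalence above
    ``min_prevalence``, the general model (fitted on the full training
    partition) is evaluated on the subgroup's test rows and compared with a
    dedicated model trained only on the subgroup's training rows, under the
    same spec/learner/seed protocol. Subgroups too small to split (or with a
    single outcome class) are skipped with a log entry.
    """
    import logging

    logger = logging.getLogger(__name__)
    train, test = split_cohort(features, train_fraction, spec.seed)
    model_cols = [c for c in features.columns if c not in condition_columns]
    general = fit_and_tune(spec, train[model_cols])
    rows = []
    n = len(features)
    for cond in condition_columns:
        prevalence = float(features[cond].mean())
        if prevalence <= min_prevalence:
            logger.info("skipping %s: baseline prevalence %.3f <= %.2f", cond, prevalence, min_prevalence)
            continue
        sub_train = train.loc[train[cond] == 1, model_cols]
        sub_test = test.loc[test[cond] == 1, model_cols]
        if len(sub_train) < min_subgroup or len(sub_test) < 10:
            logger.info("skipping %s: subgroup too small", cond)
            continue
        if sub_train[OUTCOME_COL].nunique() < 2 or sub_test[OUTCOME_COL].nunique() < 2:
            logger.info("skipping %s: single outcome class in subgroup", cond)
            continue
        general_eval = evaluate(general, sub_test, compute_importance=False)
        dedicated = fit_and_tune(spec, sub_train)
        dedicated_eval = evaluate(dedicated, sub_test, compute_importance=False)
        rows.append(
            {
                "condition": cond,
                "prevalence": prevalence,
                "n_subgroup_test": len(sub_test),
                "auroc_general": general_eval.auroc,
                "auroc_dedicated": dedicated_eval.auroc,
                "auroc_diff": dedicated_eval.auroc - general_eval.auroc,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "condition",
            "prevalence",
            "n_subgroup_test",
            "auroc_general",
            "auroc_dedicated",
            "auroc_diff",
        ],
    )
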
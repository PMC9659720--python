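"""Dataset-origin discrimination: classifier two-sample testing.

High hull coverage is a necessary but not sufficient condition for a
homogeneous population: two cohorts may share a support yet differ in
density. The second diagnostic therefore trains classifiers to predict
which site a patient record came from. A cross-validated, grid-searched
ROC AUC near 0.5 means the sites are indistinguishable; a high AUC
reveals diverging underlying distributions. The exercise is repeated
after dropping low-coverage features to separate support effects from
genuine density differences.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import (
    f1_score,
    precision_score,
    recall_score,
    roc_auc_score,
)
from sklearn.model_selection import (
    GridSearchCV,
    StratifiedKFold,
    train_test_split,
)
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .cohorts import CohortTable

__all__ = [
    "FAMILIES",
    "DEFAULT_GRIDS",
    "OriginClassificationReport",
    "make_origin_dataset",
    "train_origin_classifiers",
    "rerun_excluding_flagged",
    "OriginDiscrimination",
    "OriginDiscriminationResults",
]

FAMILIES = (
    "logistic-regression",
    "random-forest",
    "support-vector-machine",
    "adaboost",
)

# Small, desk-scale grids; fully overridable per run.
DEFAULT_GRIDS: dict[str, dict] = {
    "logistic-regression": {"clf__C": [0.01, 0.1, 1.0, 10.0]},
    "random-forest": {"n_estimators": [100, 300], "max_depth": [None, 10]},
    "support-vector-machine": {"clf__C": [0.1, 1.0, 10.0]},
    "adaboost": {"n_estimators": [50, 200]},
}


@dataclasses.dataclass(frozen=True)
class OriginClassificationReport:
    """One classifier family's result for one site pair and feature variant."""

    site_pair: tuple[str, str]
    model_family: str
    feature_variant: str  # "all" | "excluding-flagged"
    cv_auc: float
    test_auc: float
    precision: float
    recall: float
    f1: float
    chosen_hyperparameters: dict
    seed: int
    n_features: int


def _build_estimator(family: str, seed: int):
    """Estimator for a family. Scaling (train-split statistics, via a
    pipeline) is applied for the margin-based families only; tree
    ensembles consume raw values. Class weights are balanced for
    logistic regression, random forest and SVM."""
    if family == "logistic-regression":
        return Pipeline(
            [
                ("scale", StandardScaler()),
                ("clf", LogisticRegression(class_weight="balanced", max_iter=5000)),
            ]
        )
    if family == "random-forest":
        return RandomForestClassifier(class_weight="balanced", random_state=seed)
    if family == "support-vector-machine":
        return Pipeline(
            [
                ("scale", StandardScaler()),
                ("clf", SVC(kernel="rbf", class_weight="balanced")),
            ]
        )
    if family == "adaboost":
        return AdaBoostClassifier(random_state=seed)
    raise ValueError(f"unknown model family {family!r}; valid: {list(FAMILIES)}")


def _scores(model, X) -> np.ndarray:
    if hasattr(model, "decision_function"):
        return model.decision_function(X)
    return model.predict_proba(X)[:, 1]


def make_origin_dataset(
    a: CohortTable, b: CohortTable
) -> tuple[pd.DataFrame, np.ndarray]:
    """Stack two cohorts into a labeled design matrix (0 = first site, 1 = second).

    Row provenance is retained in a (site, patient) MultiIndex.
    """
    if a.features != b.features:
        raise ValueError(
            f"cohorts {a.site_id!r} and {b.site_id!r} must share an identical "
            f"feature list; got {a.features} vs {b.features}"
        )
    for c in (a, b):
        if c.has_missing():
            raise ValueError(f"site {c.site_id!r} has missing values; impute first")
    X = pd.concat(
        [a.data, b.data],
        keys=[a.site_id, b.site_id],
        names=["site_id", "patient_id"],
    )
    y = np.concatenate([np.zeros(a.n_patients, int), np.ones(b.n_patients, int)])
    return X, y


def train_origin_classifiers(
    X: pd.DataFrame,
    y: np.ndarray,
    families: Sequence[str] | None = None,
    grids: Mapping[str, Mapping] | None = None,
    seed: int = 0,
    test_size: float = 0.2,
    site_pair: tuple[str, str] | None = None,
    feature_variant: str = "all",
    n_folds: int = 5,
) -> list[OriginClassificationReport]:
    """Grid-searched origin classifiers with a stratified 80/20 split.

    For each family the hyperparameters maximizing ROC AUC under
    stratified ``n_folds``-fold cross-validation on the train split are
    selected, the model is refit on the full train split, and ROC AUC,
    precision, recall and F1 are reported on the held-out test split.
    """
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError(f"origin labels must be binary, got classes {classes}")
    if counts.min() < n_folds:
        raise ValueError(
            f"minority class has {counts.min()} members; need at least "
            f"{n_folds} for stratified {n_folds}-fold cross-validation"
        )
    families = list(families) if families is not None else list(FAMILIES)
    grids = dict(grids or {})
    if site_pair is None:
        idx = X.index
        if isinstance(idx, pd.MultiIndex):
            sites = idx.get_level_values(0).unique()
            site_pair = (str(sites[0]), str(sites[-1]))
        else:
            site_pair = ("0", "1")

    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, test_size=test_size, stratify=y, random_state=seed
    )
    cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    reports = []
    for family in families:
        est = _build_estimator(family, seed)
        grid = grids.get(family, DEFAULT_GRIDS[family])
        search = GridSearchCV(est, grid, scoring="roc_auc", cv=cv, n_jobs=1)
        search.fit(X_tr, y_tr)
        best = search.best_estimator_
        y_score = _scores(best, X_te)
        y_pred = best.predict(X_te)
        reports.append(
            OriginClassificationReport(
                site_pair=site_pair,
                model_family=family,
                feature_variant=feature_variant,
                cv_auc=float(search.best_score_),
                test_auc=float(roc_auc_score(y_te, y_score)),
                precision=float(precision_score(y_te, y_pred, zero_division=0)),
                recall=float(recall_score(y_te, y_pred, zero_division=0)),
                f1=float(f1_score(y_te, y_pred, zero_division=0)),
                chosen_hyperparameters=dict(search.best_params_),
                seed=seed,
                n_features=X.shape[1],
            )
        )
    return reports


def rerun_excluding_flagged(
    a: CohortTable,
    b: CohortTable,
    flagged_union: frozenset | set,
    families: Sequence[str] | None = None,
    grids: Mapping[str, Mapping] | None = None,
    seed: int = 0,
    test_size: float = 0.2,
) -> list[OriginClassificationReport]:
    """Retrain origin classifiers after dropping the flagged features.

    ``flagged_union`` is the union of low-coverage features over both
    directions of the site pair; at least 2 features must remain.
    """
    flagged = set(flagged_union)
    not_present = flagged - set(a.features)
    if not_present:
        raise ValueError(f"flagged features {sorted(not_present)} not in the cohorts")
    remaining = [f for f in a.features if f not in flagged]
    if len(remaining) < 2:
        raise ValueError(
            f"only {len(remaining)} features would remain after excluding "
            f"{sorted(flagged)}; need at least 2"
        )
    X, y = make_origin_dataset(a.select_features(remaining), b.select_features(remaining))
    return train_origin_classifiers(
        X,
        y,
        families=families,
        grids=grids,
        seed=seed,
        test_size=test_size,
        site_pair=(a.site_id, b.site_id),
        feature_variant="excluding-flagged",
    )


class OriginDiscrimination:
    """Origin-discrimination analysis for one site pair.

    ``fit()`` trains every requested family on all features and, when a
    flagged set is supplied, retrains on the reduced feature set.
    """

    def __init__(
        self,
        a: CohortTable,
        b: CohortTable,
        flagged: frozenset | set | None = None,
        families: Sequence[str] | None = None,
        grids: Mapping[str, Mapping] | None = None,
        seed: int = 0,
        test_size: float = 0.2,
    ) -> None:
        self.a = a
        self.b = b
        self.flagged = frozenset(flagged) if flagged else frozenset()
        self.families = list(families) if families is not None else list(FAMILIES)
        self.grids = dict(grids or {})
        self.seed = int(seed)
        self.test_size = float(test_size)

    def fit(self) -> "OriginDiscriminationResults":
        X, y = make_origin_dataset(self.a, self.b)
        reports = train_origin_classifiers(
            X,
            y,
            families=self.families,
            grids=self.grids,
            seed=self.seed,
            test_size=self.test_size,
            site_pair=(self.a.site_id, self.b.site_id),
        )
        if self.flagged:
            reports += rerun_excluding_flagged(
                self.a,
                self.b,
                self.flagged,
                families=self.families,
                grids=self.grids,
                seed=self.seed,
                test_size=self.test_size,
            )
        return OriginDiscriminationResults(
            site_pair=(self.a.site_id, self.b.site_id), reports=reports
        )


@dataclasses.dataclass
class OriginDiscriminationResults:
    site_pair: tuple[str, str]
    reports: list

    def best(self, feature_variant: str = "all") -> OriginClassificationReport:
        """Highest-test-AUC family for a variant: the pair's headline result."""
        cands = [r for r in self.reports if r.feature_variant == feature_variant]
        if not cands:
            raise ValueError(f"no reports for variant {feature_variant!r}")
        return max(cands, key=lambda r: r.test_auc)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "site_a": r.site_pair[0],
                "site_b": r.site_pair[1],
                "model_family": r.model_family,
                "feature_variant": r.feature_variant,
                "cv_auc": r.cv_auc,
                "test_auc": r.test_auc,
                "precision": r.precision,
                "recall": r.recall,
                "f1": r.f1,
                "n_features": r.n_features,
                "chosen_hyperparameters": repr(r.chosen_hyperparameters),
                "seed": r.seed,
            }
            for r in self.reports
        ]
        return pd.DataFrame(rows)

    def summary(self) -> str:
        df = self.to_frame()
        cols = ["model_family", "feature_variant", "cv_auc", "test_auc", "precision", "recall", "f1"]
        head = f"Origin discrimination {self.site_pair[0]} vs {self.site_pair[1]}"
        best = self.best()
        return "\n".join(
            [
                head,
                df[cols].round(3).to_string(index=False),
                f"headline (best test AUC, all features): {best.model_family} "
                f"AUC={best.test_auc:.3f}",
            ]
        )
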
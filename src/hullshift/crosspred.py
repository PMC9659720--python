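"""Cross-site generalization harness for endpoint models.

One random-forest endpoint classifier is trained per site (stratified
80/20 internal split, balanced class weights, grid-searched). The
diagonal of the resulting matrix is internal held-out test ROC AUC; the
off-diagonal entry (train, test) is the train-site model's ROC AUC on
the full external cohort, which contributes no training data. The drop
(internal minus external) quantifies transportability, and its
directional pattern can be read against the directional hull coverages.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import GridSearchCV, StratifiedKFold, train_test_split

from .cohorts import CohortTable

__all__ = [
    "CrossPredictionMatrix",
    "cross_predict",
    "CrossPrediction",
    "CrossPredictionResults",
]

DEFAULT_RF_GRID = {"n_estimators": [100, 300], "max_depth": [None, 10]}


@dataclasses.dataclass(frozen=True)
class CrossPredictionMatrix:
    """train-site x test-site endpoint ROC AUC."""

    sites: tuple
    auc: pd.DataFrame  # index = train site, columns = test site

    def __getitem__(self, pair: tuple[str, str]) -> float:
        train, test = pair
        return float(self.auc.loc[train, test])

    def drop(self, train: str, test: str) -> float:
        """Generalization drop: internal AUC minus external AUC."""
        return float(self.auc.loc[train, train] - self.auc.loc[train, test])


class CrossPrediction:
    """Per-site endpoint models evaluated on every site."""

    def __init__(
        self,
        cohorts: Sequence[CohortTable],
        seed: int = 0,
        grid: Mapping | None = None,
        test_size: float = 0.2,
        n_folds: int = 5,
    ) -> None:
        if len(cohorts) < 2:
            raise ValueError("need at least two labeled cohorts")
        feats = cohorts[0].features
        for c in cohorts:
            if c.features != feats:
                raise ValueError("cohorts must share an identical feature list")
            if c.endpoint is None:
                raise ValueError(f"site {c.site_id!r} has no endpoint labels")
            if c.endpoint.nunique() < 2:
                raise ValueError(
                    f"site {c.site_id!r} has a single endpoint class; cannot train"
                )
            if c.has_missing():
                raise ValueError(f"site {c.site_id!r} has missing values; impute first")
        self.cohorts = list(cohorts)
        self.seed = int(seed)
        self.grid = dict(grid or DEFAULT_RF_GRID)
        self.test_size = float(test_size)
        self.n_folds = int(n_folds)

    def fit(self) -> "CrossPredictionResults":
        sites = [c.site_id for c in self.cohorts]
        auc = pd.DataFrame(np.nan, index=sites, columns=sites)
        auc.index.name = "train_site"
        auc.columns.name = "test_site"
        models = {}
        for c in self.cohorts:
            X = c.data
            y = c.endpoint.to_numpy()
            X_tr, X_te, y_tr, y_te = train_test_split(
                X, y, test_size=self.test_size, stratify=y, random_state=self.seed
            )
            cv = StratifiedKFold(
                n_splits=self.n_folds, shuffle=True, random_state=self.seed
            )
            search = GridSearchCV(
                RandomForestClassifier(
                    class_weight="balanced", random_state=self.seed
                ),
                self.grid,
                scoring="roc_auc",
                cv=cv,
                n_jobs=1,
            )
            search.fit(X_tr, y_tr)
            model = search.best_estimator_
            models[c.site_id] = model
            auc.loc[c.site_id, c.site_id] = roc_auc_score(
                y_te, model.predict_proba(X_te)[:, 1]
            )
            for other in self.cohorts:
                if other.site_id == c.site_id:
                    continue
                score = model.predict_proba(other.data)[:, 1]
                auc.loc[c.site_id, other.site_id] = roc_auc_score(
                    other.endpoint.to_numpy(), score
                )
        matrix = CrossPredictionMatrix(sites=tuple(sites), auc=auc)
        return CrossPredictionResults(matrix=matrix, models=models, seed=self.seed)


@dataclasses.dataclass
class CrossPredictionResults:
    matrix: CrossPredictionMatrix
    models: dict
    seed: int

    def drops_frame(self) -> pd.DataFrame:
        m = self.matrix
        rows = [
            {
                "train_site": tr,
                "test_site": te,
                "auc_internal": m[tr, tr],
                "auc_external": m[tr, te],
                "drop": m.drop(tr, te),
            }
            for tr in m.sites
            for te in m.sites
            if tr != te
        ]
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = [
            "Cross-prediction ROC AUC (rows: train site, columns: test site;",
            "diagonal: internal held-out test)",
            "",
            self.matrix.auc.round(3).to_string(),
        ]
        drops = self.drops_frame()
        worst = drops.loc[drops["drop"].idxmax()]
        lines += [
            "",
            f"largest generalization drop: {worst.train_site} -> {worst.test_site} "
            f"({worst['drop']:.3f})",
        ]
        return "\n".join(lines)

    def to_csv(self, outdir) -> None:
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.matrix.auc.to_csv(outdir / "crossprediction_matrix.csv")
        self.drops_frame().to_csv(outdir / "crossprediction_drops.csv", index=False)

    def plot_heatmap(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(4.5, 4))
        m = self.matrix.auc
        im = ax.imshow(m.to_numpy(), vmin=0.5, vmax=1, cmap="magma")
        ax.set_xticks(range(len(m.columns)), m.columns)
        ax.set_yticks(range(len(m.index)), m.index)
        ax.set_xlabel("test site")
        ax.set_ylabel("train site")
        for i in range(len(m.index)):
            for j in range(len(m.columns)):
                ax.text(j, i, f"{m.iat[i, j]:.2f}", ha="center", va="center", color="w")
        ax.figure.colorbar(im, ax=ax, label="ROC AUC")
        return ax


def cross_predict(
    cohorts: Sequence[CohortTable],
    seed: int = 0,
    grid: Mapping | None = None,
    test_size: float = 0.2,
) -> CrossPredictionMatrix:
    """Convenience wrapper returning the fitted cross-prediction matrix."""
    return CrossPrediction(cohorts, seed=seed, grid=grid, test_size=test_size).fit().matrix
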
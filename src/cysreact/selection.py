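"""Elastic-net feature selection with a coefficient-magnitude threshold sweep.

A combined L1/L2-penalized linear model is fit to the (standardized)
feature matrix with 0/1-coded labels; hyperparameters (regularization
strength and L1 ratio) come from 10-fold cross-validation along the
coordinate-descent path. A sweep over coefficient-magnitude thresholds then
scores, by cross-validated classification, the feature subset surviving
each threshold, and the threshold maximizing the score (smallest on ties)
defines the selected feature list. Two independent selections are run in
the full pipeline — one for the occurrence task, one for the direction task.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import ElasticNetCV, LogisticRegression
from sklearn.model_selection import KFold, StratifiedKFold, cross_val_score


@dataclass
class SelectionResult:
    coefficients: pd.Series
    threshold: float
    selected: list[str]
    score_curve: list[tuple[float, float]] = field(default_factory=list)


def _standardize(X: pd.DataFrame) -> pd.DataFrame:
    """Zero mean, unit variance per feature; constant features become all
    zeros so their coefficients are exactly 0."""
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    sd = sd.where(sd > 0, 1.0)
    return (X - mu) / sd


def fit_elastic_net(
    X: pd.DataFrame,
    y,
    l1_ratio_grid=(0.1, 0.5, 0.7, 0.9, 0.95, 0.99),
    n_alphas: int = 50,
    folds: int = 10,
    seed: int = 42,
) -> pd.Series:
    """Coefficients of the CV-best elastic net, indexed by feature name.

    Labels are coded 0/1 and fit by penalized least squares (the elastic
    net's native objective); coefficients are on the standardized-feature
    scale, so their magnitudes are comparable across features.
    """
    y = np.asarray(y, dtype=float)
    Xs = _standardize(X)
    cv = KFold(n_splits=min(folds, len(y)), shuffle=True, random_state=seed)
    model = ElasticNetCV(
        l1_ratio=list(l1_ratio_grid),
        alphas=n_alphas,  # path length; grid laid out automatically
        cv=cv,
        random_state=seed,
        max_iter=5000,
    )
    model.fit(Xs.to_numpy(), y)
    return pd.Series(model.coef_, index=X.columns)


def default_threshold_grid(coefficients: pd.Series, n: int = 50) -> np.ndarray:
    """50 log-spaced thresholds spanning (0, max|coef|]."""
    max_c = float(np.abs(coefficients).max())
    if max_c == 0:
        return np.array([0.0])
    return np.geomspace(max_c * 1e-4, max_c, n)


def threshold_sweep(
    coefficients: pd.Series,
    X: pd.DataFrame,
    y,
    thresholds: np.ndarray | None = None,
    folds: int = 10,
    seed: int = 42,
    scoring: str = "accuracy",
) -> SelectionResult:
    """Score each threshold's surviving feature subset by cross-validated
    classification; keep the maximizer (ties -> smallest threshold).

    A threshold that eliminates every feature is scored at chance level
    (majority-class accuracy, or 0.5 for AUC).
    """
    y = np.asarray(y).astype(int)
    if thresholds is None:
        thresholds = default_threshold_grid(coefficients)
    thresholds = np.sort(np.asarray(thresholds, dtype=float))
    Xs = _standardize(X)
    abs_coef = coefficients.abs()
    chance = (
        max(np.bincount(y)) / len(y) if scoring == "accuracy" else 0.5
    )
    cv = StratifiedKFold(n_splits=min(folds, min(np.bincount(y))), shuffle=True, random_state=seed)
    curve: list[tuple[float, float]] = []
    cache: dict[frozenset, float] = {}
    for t in thresholds:
        surviving = list(abs_coef.index[abs_coef > t])
        key = frozenset(surviving)
        if key in cache:
            score = cache[key]
        elif not surviving:
            score = chance
        else:
            clf = LogisticRegression(max_iter=1000)
            score = float(
                np.mean(
                    cross_val_score(
                        clf, Xs[surviving].to_numpy(), y, cv=cv,
                        scoring="accuracy" if scoring == "accuracy" else "roc_auc",
                    )
                )
            )
        cache[key] = score
        curve.append((float(t), score))
    scores = np.array([s for _, s in curve])
    best = int(np.argmax(scores))  # first max = smallest threshold on ties
    t_best = float(thresholds[best])
    selected = list(abs_coef.index[abs_coef > t_best])
    return SelectionResult(
        coefficients=coefficients,
        threshold=t_best,
        selected=selected,
        score_curve=curve,
    )


def select_features(
    X: pd.DataFrame,
    y,
    folds: int = 10,
    seed: int = 42,
    scoring: str = "accuracy",
    l1_ratio_grid=(0.1, 0.5, 0.7, 0.9, 0.95, 0.99),
    n_alphas: int = 50,
    thresholds: np.ndarray | None = None,
) -> SelectionResult:
    """Fit the elastic net then run the threshold sweep; one-call API."""
    coef = fit_elastic_net(
        X, y, l1_ratio_grid=l1_ratio_grid, n_alphas=n_alphas, folds=folds, seed=seed
    )
    return threshold_sweep(
        coef, X, y, thresholds=thresholds, folds=folds, seed=seed, scoring=scoring
    )


def write_selection_tsv(result: SelectionResult, path) -> None:
    pd.DataFrame(
        {
            "feature": result.coefficients.index,
            "coefficient": result.coefficients.values,
            "selected": [
                f in set(result.selected) for f in result.coefficients.index
            ],
        }
    ).to_csv(path, sep="\t", index=False)


def read_selected_features(path) -> list[str]:
    df = pd.read_csv(path, sep="\t")
    return list(df.loc[df["selected"], "feature"])
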
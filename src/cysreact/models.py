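"""Gradient-boosted classifiers, the hierarchical tri-classifier, baseline
comparators and proteome scanning.

The predictor is hierarchical: a binary *occurrence* classifier (changed vs
unchanged) gates a binary *direction* classifier (increased vs decreased).
A site is labelled 0 (unchanged) when the occurrence probability falls
below the cutoff; otherwise the direction classifier assigns +1 or -1.
Both stages are XGBoost models trained at library defaults except
n_estimators (chosen by cross-validation) and max_depth / min_child_weight
(grid-searched).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GridSearchCV, StratifiedKFold, cross_val_score
from sklearn.naive_bayes import GaussianNB
from sklearn.svm import SVC
from xgboost import XGBClassifier

from . import metrics as M
from .encoders import EncoderConfig, encode_site
from .seqdata import CysteineSite, ProteinRecord, enumerate_cysteine_windows


@dataclass(frozen=True)
class HyperparameterProtocol:
    """Search space for the two tuned XGBoost knobs plus n_estimators.

    ``default()`` mirrors the full tuning protocol; ``fast()`` pins a
    single sensible configuration for desk-scale runs where a full grid
    search is unnecessary.
    """

    n_estimators_grid: tuple[int, ...] = (50, 100, 200, 400, 800)
    max_depth_grid: tuple[int, ...] = (3, 4, 6, 8, 10)
    min_child_weight_grid: tuple[int, ...] = (1, 3, 5)
    cv_folds: int = 10

    @classmethod
    def default(cls) -> "HyperparameterProtocol":
        return cls()

    @classmethod
    def fast(cls) -> "HyperparameterProtocol":
        return cls(
            n_estimators_grid=(200,),
            max_depth_grid=(4,),
            min_child_weight_grid=(1,),
            cv_folds=3,
        )


def _base_xgb(seed: int, **kw) -> XGBClassifier:
    return XGBClassifier(
        random_state=seed,
        n_jobs=1,
        eval_metric="logloss",
        **kw,
    )


def train_binary(
    X: pd.DataFrame,
    y,
    protocol: HyperparameterProtocol = HyperparameterProtocol(),
    seed: int = 42,
) -> tuple[XGBClassifier, dict]:
    """Fit one binary XGBoost stage under the tuning protocol.

    Returns the fitted classifier and a manifest recording the search
    space and the chosen values.
    """
    y = np.asarray(y).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("training data contains a single class")
    Xa = X.to_numpy() if isinstance(X, pd.DataFrame) else np.asarray(X)
    folds = min(protocol.cv_folds, int(np.bincount(y).min()))
    cv = StratifiedKFold(n_splits=max(folds, 2), shuffle=True, random_state=seed)

    # grid-search max_depth / min_child_weight at a moderate tree count
    if len(protocol.max_depth_grid) * len(protocol.min_child_weight_grid) > 1:
        gs = GridSearchCV(
            _base_xgb(seed, n_estimators=100),
            {
                "max_depth": list(protocol.max_depth_grid),
                "min_child_weight": list(protocol.min_child_weight_grid),
            },
            scoring="roc_auc",
            cv=cv,
        )
        gs.fit(Xa, y)
        depth = gs.best_params_["max_depth"]
        mcw = gs.best_params_["min_child_weight"]
    else:
        depth = protocol.max_depth_grid[0]
        mcw = protocol.min_child_weight_grid[0]

    # n_estimators by cross-validation at the chosen depth parameters
    if len(protocol.n_estimators_grid) > 1:
        cv_scores = {
            n: float(
                np.mean(
                    cross_val_score(
                        _base_xgb(seed, n_estimators=n, max_depth=depth, min_child_weight=mcw),
                        Xa, y, scoring="roc_auc", cv=cv,
                    )
                )
            )
            for n in protocol.n_estimators_grid
        }
        n_est = max(cv_scores, key=cv_scores.get)
    else:
        n_est = protocol.n_estimators_grid[0]
        cv_scores = {}

    clf = _base_xgb(seed, n_estimators=n_est, max_depth=depth, min_child_weight=mcw)
    clf.fit(Xa, y)
    manifest = {
        "seed": seed,
        "n_estimators": int(n_est),
        "max_depth": int(depth),
        "min_child_weight": int(mcw),
        "n_estimators_cv_scores": cv_scores,
        "search_space": {
            "n_estimators": list(protocol.n_estimators_grid),
            "max_depth": list(protocol.max_depth_grid),
            "min_child_weight": list(protocol.min_child_weight_grid),
        },
    }
    return clf, manifest


def train_occurrence(X, y_changed, protocol=HyperparameterProtocol(), seed=42):
    """Occurrence stage: positive class = changed (1), negative = unchanged (0)."""
    return train_binary(X, y_changed, protocol, seed)


def train_direction(X, y_increased, protocol=HyperparameterProtocol(), seed=42):
    """Direction stage on changed sites only: positive = increased (1),
    negative = decreased (0). SMOTE-Tomek rebalancing is applied upstream,
    on the training split only."""
    return train_binary(X, y_increased, protocol, seed)


def train_direct_tri(X, y_tri, protocol=HyperparameterProtocol(), seed=42):
    """Single multi-class booster over {-1, 0, +1}; a comparator for the
    hierarchical design, not the primary predictor."""
    y = np.asarray(y_tri).astype(int)
    y_enc = y + 1  # {-1,0,1} -> {0,1,2}
    Xa = X.to_numpy() if isinstance(X, pd.DataFrame) else np.asarray(X)
    clf = _base_xgb(
        seed,
        n_estimators=protocol.n_estimators_grid[0],
        max_depth=protocol.max_depth_grid[0],
        min_child_weight=protocol.min_child_weight_grid[0],
        objective="multi:softprob",
        num_class=3,
    )
    clf.fit(Xa, y_enc)
    return clf


def _booster_of(clf):
    """The underlying Booster (identity if already one)."""
    return clf.get_booster() if hasattr(clf, "get_booster") else clf.booster


class _BinaryBooster:
    """Minimal predict_proba adapter around a persisted binary Booster;
    models round-trip through text JSON and reload to identical scores."""

    def __init__(self, booster):
        self.booster = booster

    @classmethod
    def load(cls, path) -> "_BinaryBooster":
        import xgboost as xgb

        booster = xgb.Booster()
        booster.load_model(str(path))
        return cls(booster)

    def predict_proba(self, X) -> np.ndarray:
        import xgboost as xgb

        p = self.booster.predict(xgb.DMatrix(np.asarray(X)))
        return np.column_stack([1.0 - p, p])


@dataclass
class HierarchicalModel:
    """The trained artifact: two gated binary stages plus their selected
    feature lists and decision cutoffs."""

    occurrence_clf: XGBClassifier
    direction_clf: XGBClassifier
    occurrence_features: list[str]
    direction_features: list[str]
    occurrence_cutoff: float = 0.5
    direction_cutoff: float = 0.5
    manifest: dict = field(default_factory=dict)

    def _check_columns(self, X: pd.DataFrame) -> None:
        missing = (set(self.occurrence_features) | set(self.direction_features)) - set(
            X.columns
        )
        if missing:
            raise KeyError(f"missing feature column(s): {sorted(missing)[:5]}")

    def predict_proba(self, X: pd.DataFrame) -> pd.DataFrame:
        """Per site: P(changed) from the occurrence stage and P(increased)
        from the direction stage (computed for every site; only gated sites
        use it for the label)."""
        self._check_columns(X)
        p_changed = self.occurrence_clf.predict_proba(
            X[self.occurrence_features].to_numpy()
        )[:, 1]
        p_increased = self.direction_clf.predict_proba(
            X[self.direction_features].to_numpy()
        )[:, 1]
        return pd.DataFrame(
            {"p_changed": p_changed, "p_increased": p_increased}, index=X.index
        )

    def predict_tri(self, X: pd.DataFrame) -> np.ndarray:
        """Tri-class labels in {-1, 0, +1}; a site below the occurrence
        cutoff is 0 regardless of the direction stage."""
        proba = self.predict_proba(X)
        labels = np.zeros(len(X), dtype=int)
        changed = proba["p_changed"].to_numpy() >= self.occurrence_cutoff
        inc = proba["p_increased"].to_numpy() >= self.direction_cutoff
        labels[changed & inc] = 1
        labels[changed & ~inc] = -1
        return labels

    def save(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        _booster_of(self.occurrence_clf).save_model(outdir / "occurrence.json")
        _booster_of(self.direction_clf).save_model(outdir / "direction.json")
        meta = {
            "occurrence_features": self.occurrence_features,
            "direction_features": self.direction_features,
            "occurrence_cutoff": self.occurrence_cutoff,
            "direction_cutoff": self.direction_cutoff,
            "manifest": self.manifest,
        }
        (outdir / "model_manifest.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, outdir) -> "HierarchicalModel":
        outdir = Path(outdir)
        meta = json.loads((outdir / "model_manifest.json").read_text())
        occ = _BinaryBooster.load(outdir / "occurrence.json")
        dire = _BinaryBooster.load(outdir / "direction.json")
        return cls(
            occurrence_clf=occ,
            direction_clf=dire,
            occurrence_features=meta["occurrence_features"],
            direction_features=meta["direction_features"],
            occurrence_cutoff=meta["occurrence_cutoff"],
            direction_cutoff=meta["direction_cutoff"],
            manifest=meta["manifest"],
        )


BASELINES = {
    "SVM": lambda seed: SVC(probability=True, random_state=seed),
    "NB": lambda seed: GaussianNB(),
    "LR": lambda seed: LogisticRegression(max_iter=1000, random_state=seed),
    "RF": lambda seed: RandomForestClassifier(random_state=seed),
    "XGBoost": lambda seed: _base_xgb(seed),
}


def run_baselines(
    X_train: pd.DataFrame,
    y_train,
    X_val: pd.DataFrame,
    y_val,
    seed: int = 42,
) -> pd.DataFrame:
    """Fit each comparator at library defaults; one metrics row per method."""
    rows = []
    for name, factory in BASELINES.items():
        clf = factory(seed)
        clf.fit(X_train.to_numpy(), np.asarray(y_train).astype(int))
        scores = clf.predict_proba(X_val.to_numpy())[:, 1]
        preds = (scores >= 0.5).astype(int)
        rep = M.evaluation_report(y_val, preds, scores)
        rep["method"] = name
        rows.append(rep)
    return pd.DataFrame(rows).set_index("method")


def scan_proteome(
    records: dict[str, ProteinRecord],
    model: HierarchicalModel,
    config: EncoderConfig = EncoderConfig(),
    impute_iupred: float | None = None,
    batch_size: int = 2048,
) -> tuple[pd.DataFrame, dict]:
    """Predict every cysteine in a set of proteins.

    Windows containing nonstandard residues are dropped and counted.
    Returns the prediction table (protein_id, position, peptide, p_changed,
    p_increased, label) and a summary of class and drop counts; the counts
    are simple tallies of the returned table.
    """
    names = list(config.feature_names())
    meta: list[tuple[str, int, str]] = []
    feats: list[np.ndarray] = []
    n_dropped = 0
    for pid, rec in records.items():
        scan = enumerate_cysteine_windows(rec, config.window_length)
        n_dropped += scan.n_dropped
        for pos, w in scan.windows:
            site = CysteineSite(pid, pos)
            fv = encode_site(site, rec, config, impute_iupred=impute_iupred)
            meta.append((pid, pos, w.peptide))
            feats.append(fv.values)
    if feats:
        X = pd.DataFrame(np.vstack(feats), columns=names)
        proba = model.predict_proba(X)
        labels = model.predict_tri(X)
    else:
        proba = pd.DataFrame(columns=["p_changed", "p_increased"])
        labels = np.array([], dtype=int)
    df = pd.DataFrame(meta, columns=["protein_id", "position", "peptide"])
    df["p_changed"] = proba["p_changed"].to_numpy()
    df["p_increased"] = proba["p_increased"].to_numpy()
    df["label"] = labels
    summary = {
        "n_scanned": len(df),
        "n_dropped": n_dropped,
        "n_increased": int((df["label"] == 1).sum()),
        "n_decreased": int((df["label"] == -1).sum()),
        "n_unchanged": int((df["label"] == 0).sum()),
    }
    return df, summary
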
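"""Stratified splitting and class rebalancing.

Rebalancing combines minority oversampling (SMOTE: synthetic points on
segments between a minority sample and one of its k nearest minority
neighbours) with Tomek-link cleaning (a mutually-nearest opposite-class
pair; the majority member is removed). Resampling is applied to training
data only — validation data never enters any resampling operation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist


@dataclass
class DatasetSplit:
    """Index-level stratified split; ``train``/``validation`` are positional
    index arrays into the original dataset."""

    train: np.ndarray
    validation: np.ndarray
    seed: int
    fraction: float


def stratified_split(y, fraction: float, seed: int = 42) -> DatasetSplit:
    """Per class, floor(fraction * n_class) samples go to validation,
    chosen uniformly without replacement; the rest to train.

    Floor rounding makes class counts exact: a 20% split of (80, 290, 370)
    yields validation (16, 58, 74) and train (64, 232, 296).
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    y = np.asarray(y)
    if y.size == 0:
        raise ValueError("empty label vector")
    rng = np.random.default_rng(seed)
    val_idx: list[int] = []
    for cls in np.unique(y):
        members = np.flatnonzero(y == cls)
        if members.size == 0:
            raise ValueError(f"class {cls} empty")
        n_val = int(np.floor(fraction * members.size))
        chosen = rng.choice(members, size=n_val, replace=False)
        val_idx.extend(chosen.tolist())
    val = np.array(sorted(val_idx), dtype=int)
    train = np.setdiff1d(np.arange(y.size), val)
    return DatasetSplit(train=train, validation=val, seed=seed, fraction=fraction)


def smote(
    minority: np.ndarray,
    n_new: int,
    k: int = 5,
    seed: int = 42,
    lam: float | None = None,
) -> np.ndarray:
    """Generate ``n_new`` synthetic minority points.

    Each synthetic point is x + lam * (x_nn - x) for a uniformly chosen
    minority point x, one of its k nearest minority neighbours x_nn
    (Euclidean, self excluded) and lam ~ Uniform(0, 1). A fixed ``lam``
    may be supplied to pin the interpolation fraction.
    """
    minority = np.asarray(minority, dtype=float)
    n = len(minority)
    if n < 2:
        raise ValueError("need at least 2 minority samples for SMOTE")
    if n <= k:
        warnings.warn(f"minority size {n} <= k={k}; reducing k to {n - 1}")
        k = n - 1
    rng = np.random.default_rng(seed)
    if n_new == 0:
        return np.empty((0, minority.shape[1]))
    d = cdist(minority, minority)
    np.fill_diagonal(d, np.inf)
    nn = np.argsort(d, axis=1, kind="stable")[:, :k]  # (n, k)
    base = rng.integers(0, n, size=n_new)
    pick = rng.integers(0, k, size=n_new)
    lams = (
        np.full(n_new, lam) if lam is not None else rng.uniform(0.0, 1.0, size=n_new)
    )
    x = minority[base]
    xn = minority[nn[base, pick]]
    return x + lams[:, None] * (xn - x)


def tomek_links(X, y) -> np.ndarray:
    """Indices of majority-class members of Tomek links.

    A pair (i, j) of opposite classes is a Tomek link iff each is the
    other's unique nearest neighbour. Only majority members are returned;
    minority samples are never removed.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError("tomek_links requires binary labels")
    majority = classes[np.argmax(counts)]
    d = cdist(X, X)
    np.fill_diagonal(d, np.inf)
    nn = np.argmin(d, axis=0)
    removable = set()
    for i in range(len(y)):
        j = nn[i]
        if y[i] != y[j] and nn[j] == i:
            m = i if y[i] == majority else j
            removable.add(int(m))
    return np.array(sorted(removable), dtype=int)


def smote_tomek(
    X, y, seed: int = 42, k: int = 5
) -> tuple[np.ndarray, np.ndarray]:
    """SMOTE the minority class up to the majority size, then drop the
    majority members of any Tomek links in the combined set.

    Returns the resampled (X, y); synthetic rows carry the minority label
    and are appended after the originals. Feature dimensionality is
    preserved. If the input is a DataFrame, column order defines features.
    """
    cols = X.columns if isinstance(X, pd.DataFrame) else None
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError("smote_tomek requires a binary task")
    minority, majority = classes[np.argmin(counts)], classes[np.argmax(counts)]
    n_new = counts.max() - counts.min()
    if n_new > 0:
        synth = smote(X[y == minority], n_new, k=k, seed=seed)
        X_all = np.vstack([X, synth])
        y_all = np.concatenate([y, np.full(n_new, minority, dtype=y.dtype)])
    else:
        X_all, y_all = X, y
    drop = tomek_links(X_all, y_all)
    keep = np.setdiff1d(np.arange(len(y_all)), drop)
    X_out, y_out = X_all[keep], y_all[keep]
    if cols is not None:
        X_out = pd.DataFrame(X_out, columns=cols)
    return X_out, y_out


def write_split_manifest(keys, split: DatasetSplit, y, path) -> None:
    """Replayable record of which site went to which split."""
    keys = list(keys)
    rows = [
        {"site": keys[i], "split": "train", "label": y[i]} for i in split.train
    ] + [
        {"site": keys[i], "split": "validation", "label": y[i]}
        for i in split.validation
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
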
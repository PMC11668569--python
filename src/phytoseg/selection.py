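"""Feature ranking and multicollinearity pruning for the 27-feature stack.

Two selectors are provided, both sklearn-style transformers:

* :class:`RandomForestPermutationRanker` — out-of-bag (OOB) permutation
  importance (mean decrease accuracy): the forest is an explicit bag of
  bootstrap-trained decision trees so that, for every tree, the increase in
  OOB error after permuting one feature can be computed exactly; a feature's
  importance is the mean increase over trees.
* :class:`CorrelationPruner` — correlation-coefficient iterative analysis:
  repeatedly find the remaining pair with the largest absolute Pearson
  correlation and drop the member with the larger mean absolute correlation
  to all other remaining features, until a target count (or correlation
  ceiling) is reached.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.tree import DecisionTreeClassifier

from .indices import IndexStack
from .io import BinaryMask, Region

__all__ = [
    "FeatureTable",
    "build_feature_table",
    "RandomForestPermutationRanker",
    "CorrelationPruner",
    "rf_importance",
    "select_top_k",
    "correlation_matrix",
    "ccia_select",
]


@dataclass
class FeatureTable:
    """Sampled pixels as rows, feature planes as columns, 0/1 disease label."""

    X: np.ndarray
    y: np.ndarray
    names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.float64)
        self.y = np.asarray(self.y).astype(np.int8)
        self.names = tuple(self.names)
        if self.X.ndim != 2 or self.X.shape[1] != len(self.names):
            raise ValueError("X must be (rows, len(names))")
        if self.y.shape != (self.X.shape[0],):
            raise ValueError("labels must align with rows")
        if not np.isfinite(self.X).all():
            raise ValueError("feature table contains non-finite values")


def build_feature_table(
    stack: IndexStack,
    truth: BinaryMask,
    region: Region,
    max_rows: int = 20000,
    seed: int | None = None,
) -> FeatureTable:
    """One row per pixel of the training region (subsampled to ``max_rows``).

    Raises if the region contains a single class, since both importance and
    correlation-based selection are undefined there.
    """
    sub = stack.crop(region)
    labels = truth.array[region.slices].ravel()
    if labels.min() == labels.max():
        raise ValueError("training region contains a single class")
    X = sub.as_table()
    if max_rows is not None and X.shape[0] > max_rows:
        rng = np.random.default_rng(seed)
        idx = rng.choice(X.shape[0], size=max_rows, replace=False)
        idx.sort()
        X, labels = X[idx], labels[idx]
        if labels.min() == labels.max():  # pathological subsample
            raise ValueError("subsample lost one of the classes; raise max_rows")
    return FeatureTable(X, labels, stack.names)


class RandomForestPermutationRanker(BaseEstimator, TransformerMixin):
    """OOB permutation importance over an explicit bootstrap forest.

    Parameters
    ----------
    n_trees : forest size (default 100).
    max_features : per-split feature subsampling, sklearn convention
        (default "sqrt").
    k : if set, ``transform`` keeps the top-k features.
    random_state : seed controlling bootstrap draws, tree construction and
        the permutation passes.
    """

    def __init__(self, n_trees: int = 100, max_features="sqrt", k: int | None = None,
                 random_state: int | None = None):
        self.n_trees = n_trees
        self.max_features = max_features
        self.k = k
        self.random_state = random_state

    def fit(self, X, y, feature_names: Sequence[str] | None = None):
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y)
        if self.n_trees < 10:
            raise ValueError("n_trees must be >= 10")
        if np.unique(y).size < 2:
            raise ValueError("importance is undefined for a single-class label")
        n, p = X.shape
        self.feature_names_in_ = (
            tuple(feature_names) if feature_names is not None
            else tuple(f"f{i}" for i in range(p))
        )
        rng = np.random.default_rng(self.random_state)
        deltas = np.zeros((self.n_trees, p))
        used = np.zeros(p, dtype=bool)
        for k_tree in range(self.n_trees):
            boot = rng.integers(0, n, size=n)
            oob = np.setdiff1d(np.arange(n), boot, assume_unique=False)
            tree = DecisionTreeClassifier(
                max_features=self.max_features,
                random_state=int(rng.integers(0, 2**31 - 1)),
            )
            tree.fit(X[boot], y[boot])
            if oob.size == 0:
                continue
            X_oob = X[oob]
            base_err = np.mean(tree.predict(X_oob) != y[oob])
            for j in range(p):
                perm = rng.permutation(oob.size)
                X_perm = X_oob.copy()
                X_perm[:, j] = X_oob[perm, j]
                perm_err = np.mean(tree.predict(X_perm) != y[oob])
                deltas[k_tree, j] = perm_err - base_err
            used[:] = True
        self.importances_ = deltas.mean(axis=0)
        self.importances_std_ = deltas.std(axis=0)
        order = np.argsort(-self.importances_, kind="stable")
        self.ranking_ = tuple(self.feature_names_in_[i] for i in order)
        self.rank_of_ = {name: r + 1 for r, name in enumerate(self.ranking_)}
        return self

    def top_k(self, k: int) -> tuple[str, ...]:
        if not 1 <= k <= len(self.ranking_):
            raise ValueError(f"k must lie in [1, {len(self.ranking_)}]")
        return self.ranking_[:k]

    def transform(self, X):
        if self.k is None:
            return np.asarray(X)
        keep = [self.feature_names_in_.index(n) for n in self.top_k(self.k)]
        return np.asarray(X)[:, keep]


def rf_importance(
    table: FeatureTable, trees: int = 100, seed: int | None = None
) -> RandomForestPermutationRanker:
    """Fit an OOB permutation-importance ranking on a feature table."""
    ranker = RandomForestPermutationRanker(n_trees=trees, random_state=seed)
    return ranker.fit(table.X, table.y, feature_names=table.names)


def select_top_k(ranker: RandomForestPermutationRanker, k: int) -> tuple[str, ...]:
    """The k highest-importance feature names, importance order preserved."""
    return ranker.top_k(k)


def correlation_matrix(table: FeatureTable) -> np.ndarray:
    """Pearson correlation matrix of the feature columns."""
    X = table.X
    stds = X.std(axis=0)
    constant = np.where(stds == 0)[0]
    if constant.size:
        names = [table.names[i] for i in constant]
        raise ValueError(f"constant feature column(s): {names}")
    return np.corrcoef(X, rowvar=False)


def ccia_select(
    matrix: np.ndarray,
    names: Sequence[str],
    k: int | None = None,
    rho_threshold: float | None = None,
) -> tuple[tuple[str, ...], list[tuple[str, str, float]]]:
    """Iteratively drop one member of the most-correlated remaining pair.

    The dropped member is the one with the larger mean absolute correlation
    to all other remaining features (deterministic; index order breaks exact
    ties). Stops when ``k`` features remain, or — in threshold mode — when
    every remaining pair has |rho| below ``rho_threshold``.

    Returns the kept names and the elimination trace
    ``(dropped, partner, |rho|)``.
    """
    names = list(names)
    rho = np.abs(np.asarray(matrix, dtype=np.float64))
    p = len(names)
    if rho.shape != (p, p):
        raise ValueError("matrix shape must match names")
    if (k is None) == (rho_threshold is None):
        raise ValueError("specify exactly one of k or rho_threshold")
    if k is not None and not 1 <= k <= p:
        raise ValueError(f"k must lie in [1, {p}]")

    alive = list(range(p))
    trace: list[tuple[str, str, float]] = []
    while len(alive) > 1:
        sub = rho[np.ix_(alive, alive)].copy()
        np.fill_diagonal(sub, 0.0)
        i_loc, j_loc = np.unravel_index(np.argmax(sub), sub.shape)
        max_rho = sub[i_loc, j_loc]
        if k is not None and len(alive) <= k:
            break
        if rho_threshold is not None and max_rho < rho_threshold:
            break
        mean_i = sub[i_loc].sum() / (len(alive) - 1)
        mean_j = sub[j_loc].sum() / (len(alive) - 1)
        drop_loc = i_loc if mean_i >= mean_j else j_loc
        keep_loc = j_loc if drop_loc == i_loc else i_loc
        trace.append((names[alive[drop_loc]], names[alive[keep_loc]], float(max_rho)))
        del alive[drop_loc]
    return tuple(names[i] for i in alive), trace


class CorrelationPruner(BaseEstimator, TransformerMixin):
    """sklearn-style wrapper around :func:`ccia_select`."""

    def __init__(self, k: int | None = None, rho_threshold: float | None = None):
        self.k = k
        self.rho_threshold = rho_threshold

    def fit(self, X, y=None, feature_names: Sequence[str] | None = None):
        X = np.asarray(X, dtype=np.float64)
        p = X.shape[1]
        names = (
            tuple(feature_names) if feature_names is not None
            else tuple(f"f{i}" for i in range(p))
        )
        table = FeatureTable(X, np.zeros(X.shape[0]), names)
        matrix = correlation_matrix(table)
        self.selected_, self.trace_ = ccia_select(
            matrix, names, k=self.k, rho_threshold=self.rho_threshold
        )
        self.feature_names_in_ = names
        self.support_ = np.array([n in self.selected_ for n in names])
        return self

    def transform(self, X):
        return np.asarray(X)[:, self.support_]
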
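"""Cluster-density features and balanced-subsample random-forest importance.

Each retained cluster yields 5 per-channel localization densities plus the
15 unique pairwise products d(Ri)*d(Rj), i <= j (squares included), for 20
features total; the products encode the likelihood that two receptor types
co-occupy a cluster.  Rows are labelled 0 (unstimulated) or 1 (stimulated).

Variable importance follows the repeated-forest protocol: for each of
``n_forests`` rounds, draw a class-balanced subsample (66% of the
unstimulated rows and an equal number of stimulated rows, both without
replacement), train a bagged ensemble of 50 decision trees with a minimum
leaf size of 300, and record each feature's "delta error" — the per-tree
out-of-bag correct-classification rate minus the rate after scrambling that
feature's out-of-bag values, averaged over trees.  Informative features
therefore have positive delta error.  The report aggregates mean +/- SD of
the delta error and of the ensemble out-of-bag accuracy over all forests.
"""
from __future__ import annotations

import dataclasses
import itertools
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeClassifier

from .cluster import ClusterTable


# ---------------------------------------------------------------------------
# features


@dataclasses.dataclass
class FeatureMatrix:
    """Clusters x 20 features with a 0/1 condition label per row."""

    X: np.ndarray  # (n, 20) float
    y: np.ndarray  # (n,) int, 0 unstimulated / 1 stimulated
    feature_names: tuple[str, ...]
    cell_ids: np.ndarray  # (n,) object
    channels: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.X)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=list(self.feature_names))
        df.insert(0, "label", self.y)
        df.insert(0, "cell_id", self.cell_ids)
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame, channels: Sequence[str]) -> "FeatureMatrix":
        names = feature_names(channels)
        return cls(
            df[list(names)].to_numpy(float),
            df["label"].to_numpy(int),
            names,
            df["cell_id"].to_numpy(object),
            tuple(channels),
        )


def feature_names(channels: Sequence[str]) -> tuple[str, ...]:
    """5 density names then the 15 product names in canonical i <= j order."""
    single = [f"d_{c}" for c in channels]
    pairs = [
        f"d_{a}*d_{b}"
        for a, b in itertools.combinations_with_replacement(channels, 2)
    ]
    return tuple(single + pairs)


def build_features(cluster_tables: Sequence[ClusterTable]) -> FeatureMatrix:
    """One row per retained cluster across all cells/conditions."""
    if not cluster_tables:
        raise ValueError("build_features needs at least one cluster table")
    channels = cluster_tables[0].channels
    for t in cluster_tables[1:]:
        if t.channels != channels:
            raise ValueError("all cluster tables must share the channel set")
    names = feature_names(channels)
    blocks, labels, cells = [], [], []
    for t in cluster_tables:
        if t.condition not in (0, 1):
            raise ValueError("every cluster table needs a 0/1 condition label")
        ret = t.retained()
        dens = ret[[f"d_{c}" for c in channels]].to_numpy(float)
        prods = np.column_stack(
            [
                dens[:, i] * dens[:, j]
                for i, j in itertools.combinations_with_replacement(range(len(channels)), 2)
            ]
        ) if len(ret) else np.zeros((0, len(names) - len(channels)))
        blocks.append(np.hstack([dens, prods]))
        labels.append(np.full(len(ret), t.condition))
        cells.extend([t.cell_id] * len(ret))
    X = np.vstack(blocks)
    if not np.isfinite(X).all():
        raise ValueError("non-finite feature values; filter degenerate clusters first")
    return FeatureMatrix(
        X, np.concatenate(labels).astype(int), names, np.asarray(cells, object), channels
    )


# ---------------------------------------------------------------------------
# forests


@dataclasses.dataclass
class ForestConfig:
    """Hyper-parameters of the repeated-forest importance procedure."""

    n_trees: int = 50
    min_leaf: int = 300
    n_forests: int = 100
    subsample_fraction: float = 0.66
    max_features: str | int | float = "sqrt"
    seed: int | None = None

    def validate(self) -> None:
        if self.n_trees < 1 or self.min_leaf < 1 or self.n_forests < 1:
            raise ValueError("n_trees, min_leaf and n_forests must be positive")
        if not 0.0 < self.subsample_fraction <= 1.0:
            raise ValueError("subsample_fraction must be in (0, 1]")


def subsample_balanced(matrix: FeatureMatrix, fraction: float, seed=None) -> FeatureMatrix:
    """floor(fraction * n0) class-0 rows and as many class-1 rows, no replacement."""
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    rng = np.random.default_rng(seed)
    idx0 = np.flatnonzero(matrix.y == 0)
    idx1 = np.flatnonzero(matrix.y == 1)
    if len(idx0) == 0 or len(idx1) == 0:
        raise ValueError("both classes must be non-empty")
    n = int(np.floor(fraction * len(idx0)))
    if n < 1:
        raise ValueError("fraction too small: empty class-0 subsample")
    if len(idx1) < n:
        raise ValueError(
            f"insufficient stimulated rows for a balanced subsample ({len(idx1)} < {n})"
        )
    pick0 = rng.choice(idx0, size=n, replace=False)
    pick1 = rng.choice(idx1, size=n, replace=False)
    sel = np.concatenate([pick0, pick1])
    return FeatureMatrix(
        matrix.X[sel], matrix.y[sel], matrix.feature_names, matrix.cell_ids[sel], matrix.channels
    )


@dataclasses.dataclass
class Forest:
    """Bagged decision-tree ensemble with per-tree out-of-bag row sets."""

    trees: list[DecisionTreeClassifier]
    oob_masks: np.ndarray  # (n_trees, n_rows) bool
    classes: np.ndarray
    oob_accuracy: float  # ensemble OOB majority-vote accuracy


def _tree_predict(tree: DecisionTreeClassifier, X32: np.ndarray) -> np.ndarray:
    # low-level predict: skips sklearn input validation in the hot loop
    values = tree.tree_.predict(X32)
    return tree.classes_[np.argmax(values.reshape(len(X32), -1), axis=1)]


def train_forest(matrix: FeatureMatrix, config: ForestConfig, seed=None) -> Forest:
    """Bootstrap-bagged trees (majority vote) with OOB bookkeeping."""
    config.validate()
    X = np.ascontiguousarray(matrix.X, np.float32)
    y = matrix.y
    n = len(X)
    if len(np.unique(y)) < 2:
        raise ValueError("training requires both classes present")
    if n < 2 * config.min_leaf:
        raise ValueError("too few rows for the configured minimum leaf size")
    rng = np.random.default_rng(seed)
    trees, oob_masks = [], np.zeros((config.n_trees, n), bool)
    votes = np.zeros((n, 2), np.int64)
    for t in range(config.n_trees):
        boot = rng.integers(0, n, n)
        oob = np.ones(n, bool)
        oob[boot] = False
        tree = DecisionTreeClassifier(
            criterion="gini",
            min_samples_leaf=config.min_leaf,
            max_features=config.max_features,
            random_state=int(rng.integers(0, 2**31 - 1)),
        )
        tree.fit(X[boot], y[boot])
        trees.append(tree)
        oob_masks[t] = oob
        if oob.any():
            pred = _tree_predict(tree, X[oob])
            votes[np.flatnonzero(oob), pred] += 1
    covered = votes.sum(axis=1) > 0
    if covered.any():
        vote_pred = np.argmax(votes[covered], axis=1)
        oob_acc = float(np.mean(vote_pred == y[covered]))
    else:
        oob_acc = float("nan")
    return Forest(trees, oob_masks, np.array([0, 1]), oob_acc)


def permutation_importance(
    forest: Forest, matrix: FeatureMatrix, seed=None
) -> np.ndarray:
    """Per-feature mean (over trees) OOB delta error.

    delta = per-tree OOB correct rate minus the rate after permuting that
    feature's OOB values; positive for informative features.
    """
    rng = np.random.default_rng(seed)
    X = np.ascontiguousarray(matrix.X, np.float32)
    y = matrix.y
    p = X.shape[1]
    deltas = np.zeros((len(forest.trees), p))
    used = np.zeros(len(forest.trees), bool)
    for t, tree in enumerate(forest.trees):
        oob = forest.oob_masks[t]
        m = int(oob.sum())
        if m == 0:
            continue
        used[t] = True
        Xo = X[oob]
        yo = y[oob]
        # one predict call: base block + p permuted blocks
        stacked = np.tile(Xo, (p + 1, 1))
        for f in range(p):
            perm = rng.permutation(m)
            stacked[(f + 1) * m : (f + 2) * m, f] = Xo[perm, f]
        pred = _tree_predict(tree, stacked)
        correct = (pred == np.tile(yo, p + 1)).reshape(p + 1, m).mean(axis=1)
        deltas[t] = correct[0] - correct[1:]
    if not used.any():
        raise ValueError("no tree has out-of-bag rows")
    return deltas[used].mean(axis=0)


@dataclasses.dataclass
class ImportanceReport:
    """Mean +/- SD permutation importance per feature over the forest ensemble."""

    feature_names: tuple[str, ...]
    mean_delta_error: np.ndarray  # (p,)
    sd_delta_error: np.ndarray  # (p,)
    ranks: np.ndarray  # (p,) 1 = most important
    oob_accuracy_mean: float
    oob_accuracy_sd: float
    n_forests: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature": list(self.feature_names),
                "mean_delta_error": self.mean_delta_error,
                "sd_delta_error": self.sd_delta_error,
                "rank": self.ranks,
            }
        ).sort_values("rank").reset_index(drop=True)

    def top_feature(self) -> str:
        return self.feature_names[int(np.argmin(self.ranks))]


def forest_seed(master_seed, index: int) -> np.random.SeedSequence:
    """Deterministic per-forest seed; forest ``index`` is re-runnable alone."""
    return np.random.SeedSequence(master_seed, spawn_key=(index,))


def importance_ensemble(matrix: FeatureMatrix, config: ForestConfig) -> ImportanceReport:
    """The full repeated-forest procedure: subsample, train, permute, aggregate."""
    config.validate()
    master = config.seed
    if master is None:
        master = np.random.SeedSequence().entropy
    p = len(matrix.feature_names)
    deltas = np.zeros((config.n_forests, p))
    accs = np.zeros(config.n_forests)
    for f in range(config.n_forests):
        ss = forest_seed(master, f)
        s_sub, s_train, s_perm = ss.spawn(3)
        sub = subsample_balanced(matrix, config.subsample_fraction, s_sub)
        forest = train_forest(sub, config, s_train)
        accs[f] = forest.oob_accuracy
        deltas[f] = permutation_importance(forest, sub, s_perm)
    mean = deltas.mean(axis=0)
    sd = deltas.std(axis=0, ddof=0)
    order = np.argsort(-mean, kind="stable")
    ranks = np.empty(p, int)
    ranks[order] = np.arange(1, p + 1)
    return ImportanceReport(
        matrix.feature_names,
        mean,
        sd,
        ranks,
        float(np.nanmean(accs)),
        float(np.nanstd(accs, ddof=0)),
        config.n_forests,
    )
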
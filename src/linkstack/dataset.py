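"""Labeled, balanced link-prediction datasets.

Link prediction is cast as binary classification: observed edges are the
positive class, sampled non-edges the negative class (balanced 1:1, because
real networks are sparse), and the pool is split into train and test rows.

:func:`build_balanced_dataset` also returns the *training graph* — the
network with the test positives removed.  Similarity-only baselines always
score from it; whether the learned features are extracted from the full
observed network (the default protocol: missing-link detection on the
observed graph) or from the training graph (the stricter forecasting
variant) is a pipeline-level policy — see the methods documentation.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd

from .graphio import Network
from .simindex import SimilarityMatrix

__all__ = [
    "SplitConfig",
    "LabeledPairSet",
    "FeatureTable",
    "split_edges",
    "sample_nonedges",
    "build_balanced_dataset",
    "extract_features",
]


@dataclass(frozen=True)
class SplitConfig:
    """Train/test split settings: fraction of links kept for training,
    balanced negative sampling, seed, and number of independent runs."""

    train_fraction: float = 0.9
    balance_negatives: bool = True
    seed: int = 0
    n_runs: int = 10

    def __post_init__(self) -> None:
        if not (0.0 < self.train_fraction < 1.0):
            raise ValueError("train_fraction must be in (0, 1)")
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")


@dataclass
class LabeledPairSet:
    """Unordered node pairs with binary labels, for one role (train or test)."""

    pairs: list[tuple[int, int]]
    labels: np.ndarray
    role: str

    def __post_init__(self) -> None:
        if len(self.pairs) != len(self.labels):
            raise ValueError("pairs and labels length mismatch")
        seen = set()
        for i, j in self.pairs:
            if i == j:
                raise ValueError("self pair")
            key = (min(i, j), max(i, j))
            if key in seen:
                raise ValueError(f"duplicate pair {key}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class FeatureTable:
    """Rows aligned to a pair set; columns are similarity features + label."""

    pairs: list[tuple[int, int]]
    X: np.ndarray
    y: np.ndarray
    feature_names: list[str]

    def __post_init__(self) -> None:
        if self.X.shape != (len(self.pairs), len(self.feature_names)):
            raise ValueError("feature matrix shape mismatch")
        if len(self.y) != len(self.pairs):
            raise ValueError("label length mismatch")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("non-finite feature values")

    @property
    def n_rows(self) -> int:
        return len(self.pairs)

    def select(self, names: Sequence[str]) -> "FeatureTable":
        """Restrict to a feature subset, keeping the table's column order."""
        keep = [n for n in self.feature_names if n in set(names)]
        idx = [self.feature_names.index(n) for n in keep]
        return FeatureTable(self.pairs, self.X[:, idx], self.y, keep)

    def to_dataframe(self, node_ids: Sequence[str] | None = None) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=self.feature_names)
        df["label"] = self.y
        if node_ids is not None:
            df.insert(0, "node_i", [node_ids[i] for i, _ in self.pairs])
            df.insert(1, "node_j", [node_ids[j] for _, j in self.pairs])
        return df

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def split_edges(
    net: Network, cfg: SplitConfig
) -> tuple[list[tuple[int, int]], list[tuple[int, int]]]:
    """Randomly partition the edge set into train and test parts.

    |train| = round(train_fraction * M); reproducible under cfg.seed.
    """
    if net.M < 10:
        raise ValueError(f"need at least 10 edges to split, got {net.M}")
    rng = np.random.default_rng(cfg.seed)
    edges = sorted(net.edges)
    order = rng.permutation(len(edges))
    n_train = round(cfg.train_fraction * len(edges))
    train = [edges[k] for k in order[:n_train]]
    test = [edges[k] for k in order[n_train:]]
    return train, test


def sample_nonedges(
    net: Network,
    n_samples: int,
    exclude: set[tuple[int, int]] | None = None,
    seed: int = 0,
) -> list[tuple[int, int]]:
    """Uniform sample (without replacement) of non-edges of ``net``.

    ``exclude`` removes additional pairs from the pool.  Enumerates the pool
    for small graphs; falls back to rejection sampling when the pool is huge.
    """
    exclude = {(min(i, j), max(i, j)) for i, j in (exclude or set())}
    n = net.N
    total_pairs = n * (n - 1) // 2
    n_excluded = len({e for e in exclude if e not in net.edges})
    available = total_pairs - net.M - n_excluded
    if n_samples > available:
        raise ValueError(
            f"requested {n_samples} non-edges but only {available} available"
        )
    rng = np.random.default_rng(seed)
    if total_pairs <= 2_000_000:
        pool = [
            p
            for p in combinations(range(n), 2)
            if p not in net.edges and p not in exclude
        ]
        idx = rng.choice(len(pool), size=n_samples, replace=False)
        return [pool[k] for k in sorted(idx)]
    # rejection sampling for very large graphs
    chosen: set[tuple[int, int]] = set()
    while len(chosen) < n_samples:
        i, j = rng.integers(0, n, size=2)
        if i == j:
            continue
        p = (min(i, j), max(i, j))
        if p in net.edges or p in exclude or p in chosen:
            continue
        chosen.add(p)
    return sorted(chosen)


def build_balanced_dataset(
    net: Network, cfg: SplitConfig
) -> tuple[LabeledPairSet, LabeledPairSet, Network]:
    """Balanced train/test pair sets plus the feature-computation graph.

    Positives are all M edges; M negatives are sampled uniformly from the
    non-edges.  Both classes are split by ``train_fraction`` so balance holds
    within each role.  The returned training graph is ``net`` minus the test
    positives — the graph similarity baselines score from (and, under the
    holdout feature policy, the feature-computation graph as well).
    """
    train_pos, test_pos = split_edges(net, cfg)
    negatives = sample_nonedges(net, net.M, seed=cfg.seed + 1_000_003)
    rng = np.random.default_rng(cfg.seed + 2_000_003)
    order = rng.permutation(len(negatives))
    n_train_neg = round(cfg.train_fraction * len(negatives))
    train_neg = [negatives[k] for k in order[:n_train_neg]]
    test_neg = [negatives[k] for k in order[n_train_neg:]]

    train = LabeledPairSet(
        train_pos + train_neg,
        np.array([1] * len(train_pos) + [0] * len(train_neg)),
        role="train",
    )
    test = LabeledPairSet(
        test_pos + test_neg,
        np.array([1] * len(test_pos) + [0] * len(test_neg)),
        role="test",
    )
    training_graph = net.without_edges(test_pos)
    return train, test, training_graph


def extract_features(
    pair_set: LabeledPairSet, sim_matrices: Sequence[SimilarityMatrix]
) -> FeatureTable:
    """Look up each pair's score in every similarity matrix (pure lookup)."""
    if not sim_matrices:
        raise ValueError("no similarity matrices given")
    n = sim_matrices[0].values.shape[0]
    for m in sim_matrices:
        if m.values.shape != (n, n):
            raise ValueError(
                f"matrix {m.index_name} has shape {m.values.shape}, expected {(n, n)}"
            )
    for i, j in pair_set.pairs:
        if not (0 <= i < n and 0 <= j < n):
            raise ValueError(f"pair ({i},{j}) outside matrix dimension {n}")
    X = np.empty((len(pair_set), len(sim_matrices)))
    for col, m in enumerate(sim_matrices):
        X[:, col] = [m.values[i, j] for i, j in pair_set.pairs]
    names = [m.index_name for m in sim_matrices]
    return FeatureTable(list(pair_set.pairs), X, pair_set.labels.copy(), names)
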
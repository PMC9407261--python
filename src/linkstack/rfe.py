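"""Random-forest recursive feature elimination.

Feature relevance is measured by the Gini variable importance measure (VIM):
the total impurity decrease attributable to a feature, summed over all split
nodes of all trees of a random forest and then normalized so the
importances sum to 1.  Elimination removes the single lowest-VIM feature,
refits, and repeats until one feature survives.  Each subset size along the
elimination path is scored by repeated k-fold cross-validation accuracy
(CVS), and the subset with the highest CVS — smallest size on ties — is
selected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

from .dataset import FeatureTable

__all__ = [
    "ForestConfig",
    "VimProfile",
    "RfeResult",
    "gini_index",
    "compute_vim",
    "rfe_rank",
    "score_subsets",
    "select_features",
    "run_rfe",
]


@dataclass(frozen=True)
class ForestConfig:
    n_trees: int = 100
    seed: int = 0
    max_depth: int | None = None


@dataclass
class VimProfile:
    """Raw and normalized Gini importances for one fitted forest."""

    feature_names: list[str]
    raw: np.ndarray
    normalized: np.ndarray
    forest_config: ForestConfig


@dataclass
class RfeResult:
    """Elimination order (first removed -> last surviving), the CVS of every
    subset size, and the selected subset."""

    elimination_order: list[str]
    cvs_by_size: dict[int, float]
    selected_features: list[str]
    k_folds: int = 5
    n_repeats: int = 20

    def to_dict(self) -> dict:
        return {
            "elimination_order": self.elimination_order,
            "cvs_by_size": {str(k): v for k, v in sorted(self.cvs_by_size.items())},
            "selected_features": self.selected_features,
            "k_folds": self.k_folds,
            "n_repeats": self.n_repeats,
        }


def gini_index(class_proportions) -> float:
    """Gini impurity 1 - sum_c p_c^2 of a class-proportion vector."""
    p = np.asarray(class_proportions, dtype=float)
    if np.any(p < 0) or not np.isclose(p.sum(), 1.0):
        raise ValueError("class proportions must be non-negative and sum to 1")
    return float(1.0 - np.sum(p**2))


def _check_table(X: np.ndarray, y: np.ndarray) -> None:
    if X.shape[1] < 2:
        raise ValueError("need at least 2 features")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")


def _fit_forest(X: np.ndarray, y: np.ndarray, cfg: ForestConfig) -> RandomForestClassifier:
    rf = RandomForestClassifier(
        n_estimators=cfg.n_trees,
        criterion="gini",
        max_depth=cfg.max_depth,
        random_state=cfg.seed,
        n_jobs=1,
    )
    rf.fit(X, y)
    return rf


def compute_vim(
    table: FeatureTable, forest_config: ForestConfig = ForestConfig()
) -> VimProfile:
    """Gini VIM of every feature under one seeded forest.

    Per-tree importances are the *unnormalized* sample-weighted impurity
    decreases; they are summed across trees and only then normalized, so a
    feature's score is its share of the forest's total impurity decrease.
    """
    X, y = table.X, table.y
    _check_table(X, y)
    rf = _fit_forest(X, y, forest_config)
    raw = np.zeros(X.shape[1])
    for tree in rf.estimators_:
        raw += tree.tree_.compute_feature_importances(normalize=False)
    total = raw.sum()
    normalized = raw / total if total > 0 else np.full_like(raw, 1.0 / len(raw))
    return VimProfile(list(table.feature_names), raw, normalized, forest_config)


def rfe_rank(
    table: FeatureTable, forest_config: ForestConfig = ForestConfig()
) -> list[str]:
    """Elimination order: repeatedly drop the lowest-VIM feature and refit.

    Ties go to the earliest feature in the current column order (first
    argmin), making the order a deterministic function of (table, seed).
    """
    current = table
    order: list[str] = []
    while len(current.feature_names) > 1:
        vim = compute_vim(current, forest_config)
        drop = vim.feature_names[int(np.argmin(vim.normalized))]
        order.append(drop)
        current = current.select([n for n in current.feature_names if n != drop])
    order.append(current.feature_names[0])
    return order


def score_subsets(
    table: FeatureTable,
    elimination_order: list[str],
    k_folds: int = 5,
    n_repeats: int = 20,
    forest_config: ForestConfig = ForestConfig(),
) -> dict[int, float]:
    """CVS (mean k-fold accuracy over repeats) for every subset size.

    The size-s subset is the s last-eliminated features.  Each repetition
    re-randomizes both the fold assignment and the forest seed.
    """
    if k_folds < 2:
        raise ValueError("k_folds must be >= 2")
    if table.n_rows < 2 * k_folds:
        raise ValueError(f"need at least {2 * k_folds} rows, got {table.n_rows}")
    n_feat = len(elimination_order)
    cvs: dict[int, float] = {}
    for size in range(1, n_feat + 1):
        subset = elimination_order[-size:]
        sub = table.select(subset)
        accs = []
        for rep in range(n_repeats):
            rep_seed = (forest_config.seed + 7919 * rep + 31 * size) % (2**31)
            skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=rep_seed)
            for tr, te in skf.split(sub.X, sub.y):
                rf = _fit_forest(
                    sub.X[tr],
                    sub.y[tr],
                    ForestConfig(forest_config.n_trees, rep_seed, forest_config.max_depth),
                )
                accs.append(float(np.mean(rf.predict(sub.X[te]) == sub.y[te])))
        cvs[size] = float(np.mean(accs))
    return cvs


def select_features(
    cvs_by_size: dict[int, float], elimination_order: list[str]
) -> list[str]:
    """Argmax-CVS subset; ties broken toward the smallest size (fewest
    features with the same discriminative power)."""
    best_size = min(sorted(cvs_by_size), key=lambda s: (-cvs_by_size[s], s))
    return elimination_order[-best_size:]


def run_rfe(
    table: FeatureTable,
    k_folds: int = 5,
    n_repeats: int = 20,
    forest_config: ForestConfig = ForestConfig(),
) -> RfeResult:
    """Full pipeline: rank, score every subset size, select."""
    order = rfe_rank(table, forest_config)
    cvs = score_subsets(table, order, k_folds, n_repeats, forest_config)
    selected = select_features(cvs, order)
    return RfeResult(order, cvs, selected, k_folds, n_repeats)
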
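"""Two-level stacking ensemble for link classification.

Level one holds three base learners of deliberately different character —
logistic regression, gradient-boosted decision trees, and XGBoost — each
trained as five fold-models under 5-fold cross-validation.  A training row's
meta-feature from base learner j is the positive-class probability predicted
by the one fold-model that *excluded* that row (out-of-fold discipline:
every row is predicted exactly once, by a model that never saw it).  The
three out-of-fold probability columns plus the label form the meta table on
which the level-two XGBoost "fuse" model is trained.

At test time each base learner's five fold-models all predict and their
probabilities are averaged before being fed to the meta learner.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from sklearn.base import clone
from sklearn.ensemble import GradientBoostingClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GridSearchCV, KFold, StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from xgboost import XGBClassifier

from .dataset import FeatureTable

BASE_LEARNER_NAMES = ("LR", "GBDT", "XGBoost")

__all__ = [
    "BASE_LEARNER_NAMES",
    "StackConfig",
    "StackedModel",
    "default_grids",
    "make_folds",
    "make_base_learner",
    "make_meta_learner",
    "fit_base_oof",
    "fit_meta",
    "fit_stack",
    "predict",
    "classify",
]


def default_grids() -> dict[str, dict[str, list]]:
    """Hyperparameter grids for per-fold-model grid search (tuning='grid_search_cv')."""
    tree_grid = {
        "n_estimators": [50, 100, 200],
        "max_depth": [2, 3, 5],
        "learning_rate": [0.05, 0.1, 0.3],
    }
    return {
        "LR": {"clf__C": [0.01, 0.1, 1.0, 10.0]},
        "GBDT": dict(tree_grid),
        "XGBoost": dict(tree_grid),
    }


@dataclass(frozen=True)
class StackConfig:
    """Stacking configuration.

    ``tuning='none'`` fits every fold-model with the fixed defaults below;
    ``tuning='grid_search_cv'`` tunes each fold-model by grid search with an
    internal ``tuning_cv``-fold CV on its own training partition (the
    out-of-fold boundary is respected either way).
    """

    n_folds: int = 5
    fold_assignment: str = "stratified"  # stratified | random
    tuning: str = "none"  # none | grid_search_cv
    tuning_cv: int = 3
    hyperparameter_grids: dict = field(default_factory=default_grids)
    n_estimators: int = 100
    max_depth: int = 3
    learning_rate: float = 0.1
    lr_C: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.fold_assignment not in ("stratified", "random"):
            raise ValueError("fold_assignment must be 'stratified' or 'random'")
        if self.tuning not in ("none", "grid_search_cv"):
            raise ValueError("tuning must be 'none' or 'grid_search_cv'")


def make_base_learner(name: str, cfg: StackConfig, seed: int):
    """Fresh unfitted base learner by canonical name."""
    if name == "LR":
        return Pipeline(
            [
                ("scale", StandardScaler()),
                ("clf", LogisticRegression(C=cfg.lr_C, max_iter=2000, solver="lbfgs")),
            ]
        )
    if name == "GBDT":
        return GradientBoostingClassifier(
            n_estimators=cfg.n_estimators,
            max_depth=cfg.max_depth,
            learning_rate=cfg.learning_rate,
            random_state=seed,
        )
    if name == "XGBoost":
        return XGBClassifier(
            n_estimators=cfg.n_estimators,
            max_depth=cfg.max_depth,
            learning_rate=cfg.learning_rate,
            tree_method="hist",
            n_jobs=1,
            random_state=seed,
            eval_metric="logloss",
            verbosity=0,
        )
    raise ValueError(f"unknown base learner {name!r}")


def make_meta_learner(cfg: StackConfig, seed: int) -> XGBClassifier:
    """The level-two fuse model: a small XGBoost on the 3 meta-features."""
    return XGBClassifier(
        n_estimators=50,
        max_depth=2,
        learning_rate=0.1,
        tree_method="hist",
        n_jobs=1,
        random_state=seed,
        eval_metric="logloss",
        verbosity=0,
    )


@dataclass
class StackedModel:
    """Fitted stack: n_folds fold-models per base learner plus the meta model."""

    fold_models: dict[str, list]  # learner name -> [model per fold]
    meta_model: object
    fold_index_map: np.ndarray  # training row -> fold id
    feature_names: list[str]
    training_meta_table: np.ndarray  # (n_train, 3 + 1): oof probs + label
    config: StackConfig = field(default_factory=StackConfig)


def make_folds(n_rows: int, labels: np.ndarray, cfg: StackConfig) -> np.ndarray:
    """Row -> fold assignment into near-equal folds; stratified by default."""
    if n_rows < cfg.n_folds:
        raise ValueError(f"need at least {cfg.n_folds} rows, got {n_rows}")
    splitter_cls = StratifiedKFold if cfg.fold_assignment == "stratified" else KFold
    splitter = splitter_cls(n_splits=cfg.n_folds, shuffle=True, random_state=cfg.seed)
    X_dummy = np.zeros((n_rows, 1))
    fold_map = np.empty(n_rows, dtype=np.int64)
    for k, (_, test_idx) in enumerate(splitter.split(X_dummy, labels)):
        fold_map[test_idx] = k
    return fold_map


def _fit_one(name, X, y, cfg: StackConfig, seed: int):
    """Fit one fold-model, optionally grid-searched on its own partition."""
    est = make_base_learner(name, cfg, seed)
    if cfg.tuning == "grid_search_cv":
        grid = cfg.hyperparameter_grids.get(name, {})
        if grid:
            inner = StratifiedKFold(n_splits=cfg.tuning_cv, shuffle=True, random_state=seed)
            gs = GridSearchCV(est, grid, cv=inner, scoring="accuracy", n_jobs=1)
            gs.fit(X, y)
            return gs.best_estimator_
    est.fit(X, y)
    return est


def fit_base_oof(
    table: FeatureTable,
    cfg: StackConfig = StackConfig(),
    fold_index_map: np.ndarray | None = None,
) -> tuple[dict[str, list], np.ndarray, np.ndarray]:
    """Train the 3 x n_folds base fold-models and assemble the OOF meta table.

    Returns (fold_models, training_meta_table, fold_index_map).  Row i's
    meta-features come from the fold-models whose training partition excluded
    row i.  ``fold_index_map`` may be supplied to pin the fold assignment
    (used by leakage audits); otherwise it is drawn from cfg.seed.
    """
    X, y = table.X, table.y
    if fold_index_map is None:
        fold_index_map = make_folds(len(y), y, cfg)
    meta = np.empty((len(y), len(BASE_LEARNER_NAMES) + 1))
    meta[:, -1] = y
    fold_models: dict[str, list] = {name: [] for name in BASE_LEARNER_NAMES}
    for j, name in enumerate(BASE_LEARNER_NAMES):
        for k in range(cfg.n_folds):
            tr = fold_index_map != k
            te = ~tr
            if len(np.unique(y[tr])) < 2:
                raise ValueError(
                    f"fold {k} training partition is single-class; use stratified folds"
                )
            seed_jk = (cfg.seed * 1009 + j * 101 + k) % (2**31)
            model = _fit_one(name, X[tr], y[tr], cfg, seed_jk)
            fold_models[name].append(model)
            meta[te, j] = model.predict_proba(X[te])[:, 1]
    return fold_models, meta, fold_index_map


def fit_meta(training_meta_table: np.ndarray, cfg: StackConfig = StackConfig()):
    """Train the fuse model on the out-of-fold meta table."""
    Xm, ym = training_meta_table[:, :-1], training_meta_table[:, -1]
    if len(np.unique(ym)) < 2 and all(
        np.allclose(Xm[:, c], Xm[0, c]) for c in range(Xm.shape[1])
    ):
        raise ValueError("degenerate meta table: constant columns and single class")
    if len(np.unique(ym)) < 2:
        raise ValueError("meta table is single-class")
    meta = make_meta_learner(cfg, (cfg.seed * 1013 + 7) % (2**31))
    meta.fit(Xm, ym)
    return meta


def fit_stack(table: FeatureTable, cfg: StackConfig = StackConfig()) -> StackedModel:
    """End-to-end: OOF base training then meta training."""
    fold_models, meta_table, fold_map = fit_base_oof(table, cfg)
    meta_model = fit_meta(meta_table, cfg)
    return StackedModel(
        fold_models=fold_models,
        meta_model=meta_model,
        fold_index_map=fold_map,
        feature_names=list(table.feature_names),
        training_meta_table=meta_table,
        config=cfg,
    )


def predict(model: StackedModel, table: FeatureTable) -> np.ndarray:
    """Positive-class probability per row.

    Each base learner's n_folds fold-models predict every row; their
    probabilities are averaged per learner, and the resulting triple goes to
    the meta model.
    """
    if list(table.feature_names) != list(model.feature_names):
        raise ValueError(
            f"feature mismatch: model has {model.feature_names}, "
            f"table has {table.feature_names}"
        )
    X = table.X
    meta_X = np.empty((X.shape[0], len(BASE_LEARNER_NAMES)))
    for j, name in enumerate(BASE_LEARNER_NAMES):
        preds = np.stack(
            [m.predict_proba(X)[:, 1] for m in model.fold_models[name]], axis=0
        )
        meta_X[:, j] = preds.mean(axis=0)
    return model.meta_model.predict_proba(meta_X)[:, 1]


def classify(probabilities: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Hard labels: 1 iff probability >= threshold."""
    return (np.asarray(probabilities) >= threshold).astype(np.int64)


def save_model(model: StackedModel, directory) -> None:
    """Serialize a fitted stack: per-fold learner artifacts + JSON manifest."""
    import json
    import pickle
    from pathlib import Path

    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    for name, models in model.fold_models.items():
        for k, m in enumerate(models):
            with open(d / f"base_{name}_fold{k}.pkl", "wb") as fh:
                pickle.dump(m, fh)
    with open(d / "meta_model.pkl", "wb") as fh:
        pickle.dump(model.meta_model, fh)
    np.save(d / "fold_index_map.npy", model.fold_index_map)
    np.save(d / "training_meta_table.npy", model.training_meta_table)
    manifest = {
        "feature_names": model.feature_names,
        "n_folds": model.config.n_folds,
        "seed": model.config.seed,
        "base_learners": list(BASE_LEARNER_NAMES),
    }
    (d / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))


def load_model(directory) -> StackedModel:
    """Load a stack saved by :func:`save_model`."""
    import json
    import pickle
    from pathlib import Path

    d = Path(directory)
    manifest = json.loads((d / "manifest.json").read_text())
    cfg = StackConfig(n_folds=manifest["n_folds"], seed=manifest["seed"])
    fold_models: dict[str, list] = {}
    for name in manifest["base_learners"]:
        fold_models[name] = []
        for k in range(cfg.n_folds):
            with open(d / f"base_{name}_fold{k}.pkl", "rb") as fh:
                fold_models[name].append(pickle.load(fh))
    with open(d / "meta_model.pkl", "rb") as fh:
        meta_model = pickle.load(fh)
    return StackedModel(
        fold_models=fold_models,
        meta_model=meta_model,
        fold_index_map=np.load(d / "fold_index_map.npy"),
        feature_names=manifest["feature_names"],
        training_meta_table=np.load(d / "training_meta_table.npy"),
        config=cfg,
    )
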
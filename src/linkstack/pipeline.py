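"""End-to-end experiment orchestration.

One run: build a balanced train/test split, compute the 12 similarity
matrices, extract features, select features by random-forest RFE on the
training rows only, train the stacking ensemble on the selected features,
and evaluate on the test rows.

The ``feature_graph`` policy decides which graph the learned features come
from.  The default, ``"full"``, scores every labeled pair on the full
observed network (the task is then missing-link detection on the observed
graph; the train/test split partitions the labeled pairs, not the graph).
``"holdout"`` computes features on the training graph with the test
positives removed — the stricter forecasting task, in which the walk-based
indices for held-out edges no longer see the edge itself.  Similarity-only
baselines always score from the training graph.

Ablations (stack without feature selection, each base learner alone, with
and without the selected features) and the similarity baselines are
evaluated on the same split.  Runs r = 0..n_runs-1 use seed master_seed + r
and are aggregated as mean +/- sd per metric.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

from . import __version__ as _pkg_version
from .dataset import SplitConfig, build_balanced_dataset, extract_features
from .evalx import (
    MetricsReport,
    RunAggregate,
    aggregate_runs,
    evaluate_predictions,
    similarity_baseline,
)
from .graphio import Network, SyntheticSpec, generate_synthetic, read_edge_list
from .rfe import ForestConfig, RfeResult, run_rfe
from .sellp import BASE_LEARNER_NAMES, StackConfig, fit_stack, make_base_learner, predict
from .simindex import INDEX_NAMES, IndexParams, compute_all_indices

logger = logging.getLogger(__name__)

__all__ = ["ExperimentConfig", "ExperimentReport", "run_experiment", "run_rfe_only"]

STACK_METHOD = "RF-RFE-SELLP"


@dataclass
class ExperimentConfig:
    """Everything needed to reproduce one experiment."""

    edge_list: str | None = None
    synthetic: SyntheticSpec | None = None
    train_fraction: float = 0.9
    n_runs: int = 10
    index_params: IndexParams = field(default_factory=IndexParams)
    rfe_k_folds: int = 5
    rfe_n_repeats: int = 20
    forest_trees: int = 100
    stack: StackConfig = field(default_factory=StackConfig)
    threshold: float = 0.5
    feature_graph: str = "full"  # full | holdout
    baselines: tuple[str, ...] = ("CN", "MFI", "SRW")
    include_original_features: bool = True
    freeze_selection: bool = False
    master_seed: int = 0
    output_dir: str | None = None

    def resolve_network(self) -> Network:
        if self.edge_list is not None:
            return read_edge_list(self.edge_list)
        if self.synthetic is not None:
            return generate_synthetic(self.synthetic)
        raise ValueError("config names neither an edge list nor a synthetic spec")

    def provenance(self) -> dict:
        d = asdict(self)
        d["package_version"] = _pkg_version
        return d


@dataclass
class ExperimentReport:
    """Per-run metrics for every method, RFE traces, and aggregates."""

    method_runs: dict[str, list[MetricsReport]]
    aggregates: dict[str, RunAggregate]
    rfe_results: list[RfeResult]
    provenance: dict
    stage_log: list[tuple[str, float]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "methods": {
                name: {
                    "runs": [r.to_dict() for r in runs],
                    "aggregate": self.aggregates[name].to_dict(),
                }
                for name, runs in sorted(self.method_runs.items())
            },
            "rfe": [r.to_dict() for r in self.rfe_results],
            "provenance": self.provenance,
        }

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    def summary_frame(self):
        import pandas as pd

        rows = []
        for name, agg in sorted(self.aggregates.items()):
            row = {"method": name}
            for m in ("auc", "accuracy", "precision", "recall", "f1"):
                row[m] = agg.mean[m]
                row[m + "_sd"] = agg.sd[m]
            rows.append(row)
        return pd.DataFrame(rows).set_index("method")


def _run_seed(master_seed: int, r: int) -> int:
    return (master_seed + r) % (2**31)


def _single_run(net: Network, cfg: ExperimentConfig, run_seed: int,
                frozen_selection: list[str] | None = None):
    """One full train/evaluate cycle; returns (per-method reports, RfeResult)."""
    if cfg.feature_graph not in ("full", "holdout"):
        raise ValueError("feature_graph must be 'full' or 'holdout'")
    split_cfg = SplitConfig(cfg.train_fraction, True, run_seed, 1)
    train, test, training_graph = build_balanced_dataset(net, split_cfg)
    baseline_sims = compute_all_indices(training_graph, cfg.index_params)
    if cfg.feature_graph == "full":
        feature_sims = compute_all_indices(net, cfg.index_params)
    else:
        feature_sims = baseline_sims
    train_tab = extract_features(train, feature_sims)
    test_tab = extract_features(test, feature_sims)

    if frozen_selection is None:
        rfe_res = run_rfe(
            train_tab,
            k_folds=cfg.rfe_k_folds,
            n_repeats=cfg.rfe_n_repeats,
            forest_config=ForestConfig(cfg.forest_trees, run_seed),
        )
        selected = rfe_res.selected_features
    else:
        rfe_res = None
        selected = frozen_selection

    train_sel = train_tab.select(selected)
    test_sel = test_tab.select(selected)
    stack_cfg = replace(cfg.stack, seed=run_seed)

    reports: dict[str, MetricsReport] = {}

    def _eval(scores) -> MetricsReport:
        return evaluate_predictions(test.labels, scores, cfg.threshold)

    # stacking ensemble, with and without feature selection
    model_sel = fit_stack(train_sel, stack_cfg)
    reports[STACK_METHOD] = _eval(predict(model_sel, test_sel))
    if cfg.include_original_features:
        model_full = fit_stack(train_tab, stack_cfg)
        reports["SELLP"] = _eval(predict(model_full, test_tab))

    # each base learner alone
    for j, name in enumerate(BASE_LEARNER_NAMES):
        seed_j = (run_seed * 1021 + j) % (2**31)
        est = make_base_learner(name, stack_cfg, seed_j)
        est.fit(train_sel.X, train_sel.y)
        reports[f"RF-RFE-{name}"] = _eval(est.predict_proba(test_sel.X)[:, 1])
        if cfg.include_original_features:
            est = make_base_learner(name, stack_cfg, seed_j)
            est.fit(train_tab.X, train_tab.y)
            reports[name] = _eval(est.predict_proba(test_tab.X)[:, 1])

    # similarity-only baselines on the same split, always from the training graph
    sims_by_name = dict(zip(INDEX_NAMES, baseline_sims))
    for bname in cfg.baselines:
        reports[bname] = similarity_baseline(sims_by_name[bname], test)

    return reports, rfe_res


def run_experiment(cfg: ExperimentConfig, net: Network | None = None) -> ExperimentReport:
    """The full protocol: n_runs independent splits, aggregated per method."""
    if net is None:
        net = cfg.resolve_network()
    method_runs: dict[str, list[MetricsReport]] = {}
    rfe_results: list[RfeResult] = []
    stage_log: list[tuple[str, float]] = []
    frozen: list[str] | None = None
    for r in range(cfg.n_runs):
        t0 = time.perf_counter()
        run_seed = _run_seed(cfg.master_seed, r)
        reports, rfe_res = _single_run(net, cfg, run_seed, frozen_selection=frozen)
        if rfe_res is not None:
            rfe_results.append(rfe_res)
            if cfg.freeze_selection:
                frozen = rfe_res.selected_features
        for name, rep in reports.items():
            method_runs.setdefault(name, []).append(rep)
        dt = time.perf_counter() - t0
        stage_log.append((f"run_{r}", dt))
        logger.info("run %d/%d done in %.1fs", r + 1, cfg.n_runs, dt)
    aggregates = {name: aggregate_runs(runs) for name, runs in method_runs.items()}
    report = ExperimentReport(
        method_runs=method_runs,
        aggregates=aggregates,
        rfe_results=rfe_results,
        provenance=cfg.provenance(),
        stage_log=stage_log,
    )
    if cfg.output_dir is not None:
        out = Path(cfg.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        report.to_json(out / "experiment_report.json")
        report.summary_frame().to_csv(out / "summary.csv")
    return report


def run_rfe_only(cfg: ExperimentConfig, net: Network | None = None) -> RfeResult:
    """Feature selection alone: CVS curve and selected subset, no stacking."""
    if net is None:
        net = cfg.resolve_network()
    run_seed = _run_seed(cfg.master_seed, 0)
    split_cfg = SplitConfig(cfg.train_fraction, True, run_seed, 1)
    train, _, training_graph = build_balanced_dataset(net, split_cfg)
    graph = net if cfg.feature_graph == "full" else training_graph
    train_tab = extract_features(train, compute_all_indices(graph, cfg.index_params))
    return run_rfe(
        train_tab,
        k_folds=cfg.rfe_k_folds,
        n_repeats=cfg.rfe_n_repeats,
        forest_config=ForestConfig(cfg.forest_trees, run_seed),
    )
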
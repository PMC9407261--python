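"""Model/Results front end over the experiment pipeline.

`LinkPredictionModel` is constructed from a network (edge list file,
existing :class:`~linkstack.graphio.Network`, or synthetic recipe) plus the
experiment settings; ``fit()`` executes the full protocol — balanced splits,
similarity features, RFE selection, stacking — and returns a
`LinkPredictionResults` carrying per-method metrics with uncertainties, the
feature-selection trace, and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd

from .evalx import compare_methods
from .graphio import Network, SyntheticSpec, generate_synthetic, read_edge_list
from .pipeline import STACK_METHOD, ExperimentConfig, ExperimentReport, run_experiment

__all__ = ["LinkPredictionModel", "LinkPredictionResults"]


class LinkPredictionModel:
    """Unfitted link-prediction experiment bound to one network."""

    def __init__(self, network: Network, config: ExperimentConfig | None = None):
        self.network = network
        self.config = config if config is not None else ExperimentConfig()

    @classmethod
    def from_edge_list(cls, path: str | Path, **config_kwargs) -> "LinkPredictionModel":
        net = read_edge_list(path)
        return cls(net, ExperimentConfig(edge_list=str(path), **config_kwargs))

    @classmethod
    def from_synthetic(cls, spec: SyntheticSpec, **config_kwargs) -> "LinkPredictionModel":
        net = generate_synthetic(spec)
        return cls(net, ExperimentConfig(synthetic=spec, **config_kwargs))

    def fit(self, n_runs: int | None = None, seed: int | None = None) -> "LinkPredictionResults":
        cfg = self.config
        if n_runs is not None:
            cfg = replace(cfg, n_runs=n_runs)
        if seed is not None:
            cfg = replace(cfg, master_seed=seed)
        report = run_experiment(cfg, net=self.network)
        return LinkPredictionResults(self, cfg, report)


class LinkPredictionResults:
    """Fitted results: per-method metric means/SDs, RFE trace, comparisons."""

    def __init__(self, model: LinkPredictionModel, config: ExperimentConfig,
                 report: ExperimentReport):
        self.model = model
        self.config = config
        self.report = report

    @property
    def aggregates(self):
        return self.report.aggregates

    @property
    def selected_features(self) -> list[str] | None:
        if not self.report.rfe_results:
            return None
        return self.report.rfe_results[-1].selected_features

    def metric_runs(self, method: str, metric: str = "auc") -> np.ndarray:
        return np.array(
            [getattr(r, metric) for r in self.report.method_runs[method]]
        )

    def compare(self, method_a: str, method_b: str, metric: str = "auc"):
        """Two-stage F-test / t-test between two methods' per-run metrics."""
        return compare_methods(
            self.metric_runs(method_a, metric), self.metric_runs(method_b, metric)
        )

    def summary_frame(self) -> pd.DataFrame:
        return self.report.summary_frame()

    def summary(self) -> str:
        """Human-readable results table (mean +/- sd per metric and method)."""
        df = self.summary_frame()
        lines = [
            "Link prediction experiment",
            "=" * 70,
            f"network: N={self.model.network.N}, M={self.model.network.M}",
            f"runs: {self.config.n_runs}   train fraction: {self.config.train_fraction}"
            f"   master seed: {self.config.master_seed}",
        ]
        if self.selected_features is not None:
            lines.append(f"selected features (last run): {', '.join(self.selected_features)}")
        lines.append("-" * 70)
        header = f"{'method':<18}" + "".join(
            f"{m:>10}" for m in ("auc", "accuracy", "precision", "recall", "f1")
        )
        lines.append(header)
        order = sorted(df.index, key=lambda m: (m != STACK_METHOD, m))
        for name in order:
            row = df.loc[name]
            lines.append(
                f"{name:<18}" + "".join(
                    f"{row[m]:>10.4f}" for m in ("auc", "accuracy", "precision", "recall", "f1")
                )
            )
        lines.append("=" * 70)
        return "\n".join(lines)
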
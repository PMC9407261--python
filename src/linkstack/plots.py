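"""Plot helpers: CVS curve of the RFE selection and per-method metric bars."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .pipeline import ExperimentReport
from .rfe import RfeResult

__all__ = ["plot_cvs_curve", "plot_metric_bars"]


def plot_cvs_curve(rfe_result: RfeResult, path: str | Path | None = None):
    """Cross-validation score against number of selected features."""
    sizes = sorted(rfe_result.cvs_by_size)
    scores = [rfe_result.cvs_by_size[s] for s in sizes]
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(sizes, scores, marker="o")
    best = len(rfe_result.selected_features)
    ax.axvline(best, color="grey", linestyle="--", linewidth=1)
    ax.set_xlabel("number of selected features")
    ax.set_ylabel("cross-validation score")
    ax.set_title("RFE subset scores (dashed: selected size)")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_metric_bars(report: ExperimentReport, metric: str = "auc",
                     path: str | Path | None = None):
    """Mean metric per method with run-SD error bars."""
    names = sorted(report.aggregates)
    means = [report.aggregates[n].mean[metric] for n in names]
    sds = [report.aggregates[n].sd[metric] for n in names]
    fig, ax = plt.subplots(figsize=(max(6, 0.8 * len(names)), 4))
    ax.bar(range(len(names)), means, yerr=sds, capsize=3)
    ax.set_xticks(range(len(names)))
    ax.set_xticklabels(names, rotation=45, ha="right")
    ax.set_ylabel(metric)
    ax.set_ylim(0, 1.05)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
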
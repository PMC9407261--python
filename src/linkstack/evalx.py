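"""Evaluation: confusion-based metrics, rank AUC, similarity baselines,
matching scores, run aggregation and the two-stage F-test / t-test protocol.

AUC uses the rank formulation AUC = (S0 - n0(n0+1)/2) / (n0 n1) where S0 is
the rank sum of the positives in the ascending-score list, with midranks for
ties — which makes it exactly the concordance probability
P(score_pos > score_neg) + 0.5 P(tie).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .dataset import LabeledPairSet
from .simindex import SimilarityMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "RunAggregate",
    "ComparisonResult",
    "confusion",
    "rank_auc",
    "metrics",
    "evaluate_predictions",
    "similarity_baseline",
    "matching_score",
    "delta_sigma",
    "aggregate_runs",
    "compare_methods",
]

METRIC_FIELDS = ("accuracy", "precision", "recall", "f1", "auc")


@dataclass
class ConfusionCounts:
    TP: int
    FP: int
    FN: int
    TN: int

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.FN + self.TN


@dataclass
class MetricsReport:
    accuracy: float
    precision: float
    recall: float
    f1: float
    auc: float
    counts: ConfusionCounts
    n0: int  # positives
    n1: int  # negatives

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "auc": self.auc,
            "TP": self.counts.TP,
            "FP": self.counts.FP,
            "FN": self.counts.FN,
            "TN": self.counts.TN,
        }


@dataclass
class RunAggregate:
    reports: list[MetricsReport]
    mean: dict[str, float]
    sd: dict[str, float]

    def to_dict(self) -> dict:
        return {"mean": self.mean, "sd": self.sd, "n_runs": len(self.reports)}


@dataclass
class ComparisonResult:
    f_test_p: float
    t_test_p: float
    t_test_variant: str  # equal_variance | welch
    ci95_mean_difference: tuple[float, float]
    mean_difference: float


def confusion(labels_true, labels_pred) -> ConfusionCounts:
    """Exact TP/FP/FN/TN counts for binary labels."""
    yt = np.asarray(labels_true)
    yp = np.asarray(labels_pred)
    if yt.shape != yp.shape:
        raise ValueError("label vectors have different lengths")
    if not (np.isin(yt, (0, 1)).all() and np.isin(yp, (0, 1)).all()):
        raise ValueError("labels must be binary 0/1")
    tp = int(np.sum((yt == 1) & (yp == 1)))
    fp = int(np.sum((yt == 0) & (yp == 1)))
    fn = int(np.sum((yt == 1) & (yp == 0)))
    tn = int(np.sum((yt == 0) & (yp == 0)))
    return ConfusionCounts(tp, fp, fn, tn)


def rank_auc(scores, labels_true) -> float:
    """Rank-sum AUC with midranks for tied scores."""
    y = np.asarray(labels_true)
    s = np.asarray(scores, dtype=float)
    n0 = int(np.sum(y == 1))
    n1 = int(np.sum(y == 0))
    if n0 == 0 or n1 == 0:
        raise ValueError("AUC undefined: need both classes present")
    ranks = stats.rankdata(s, method="average")
    s0 = float(ranks[y == 1].sum())
    return (s0 - n0 * (n0 + 1) / 2.0) / (n0 * n1)


def _safe_div(num: float, den: float, name: str) -> float:
    if den == 0:
        logger.warning("%s has zero denominator; reporting 0", name)
        return 0.0
    return num / den


def metrics(counts: ConfusionCounts, scores, labels_true) -> MetricsReport:
    """Accuracy/Precision/Recall/F1 from the counts, AUC from the scores."""
    y = np.asarray(labels_true)
    if counts.total != len(y):
        raise ValueError("confusion counts inconsistent with label vector")
    acc = _safe_div(counts.TP + counts.TN, counts.total, "accuracy")
    prec = _safe_div(counts.TP, counts.TP + counts.FP, "precision")
    rec = _safe_div(counts.TP, counts.TP + counts.FN, "recall")
    f1 = _safe_div(2 * prec * rec, prec + rec, "f1")
    auc = rank_auc(scores, y)
    return MetricsReport(
        accuracy=acc,
        precision=prec,
        recall=rec,
        f1=f1,
        auc=auc,
        counts=counts,
        n0=int(np.sum(y == 1)),
        n1=int(np.sum(y == 0)),
    )


def evaluate_predictions(labels_true, scores, threshold: float = 0.5) -> MetricsReport:
    """Convenience: threshold scores, count, and compute all metrics."""
    pred = (np.asarray(scores) >= threshold).astype(int)
    return metrics(confusion(labels_true, pred), scores, labels_true)


def similarity_baseline(sim: SimilarityMatrix, test: LabeledPairSet) -> MetricsReport:
    """Score test pairs straight from one similarity matrix.

    AUC is threshold-free and is the primary comparison.  For the
    threshold-based metrics the scores are cut at the median of the evaluated
    pool (balanced pools then get balanced predictions); strictly-greater
    beats the median, ties fall to the negative side.
    """
    scores = np.array([sim.values[i, j] for i, j in test.pairs])
    thr = float(np.median(scores))
    pred = (scores > thr).astype(int)
    return metrics(confusion(test.labels, pred), scores, test.labels)


def matching_score(
    sim: SimilarityMatrix,
    observed_edges: set[tuple[int, int]],
    candidate_pool: list[tuple[int, int]],
) -> float:
    """Fraction of observed edges recovered in the top-|E| ranked candidates.

    Candidates are ranked by score descending; ties are broken by the fixed
    sorted pair order (stable sort), so the cut is deterministic.
    """
    observed = {(min(i, j), max(i, j)) for i, j in observed_edges}
    pool = sorted({(min(i, j), max(i, j)) for i, j in candidate_pool})
    if not observed <= set(pool):
        raise ValueError("observed_edges must be a subset of candidate_pool")
    if not observed:
        raise ValueError("observed_edges is empty")
    scores = np.array([sim.values[i, j] for i, j in pool])
    order = np.argsort(-scores, kind="stable")
    top = {pool[k] for k in order[: len(observed)]}
    return len(observed & top) / len(observed)


def delta_sigma(
    sim_a: SimilarityMatrix,
    sim_b: SimilarityMatrix,
    observed: set[tuple[int, int]],
    pool: list[tuple[int, int]],
) -> float:
    """Difference of matching scores sigma_a - sigma_b on the same pool."""
    return matching_score(sim_a, observed, pool) - matching_score(sim_b, observed, pool)


def aggregate_runs(reports: list[MetricsReport]) -> RunAggregate:
    """Per-metric mean and (population) standard deviation across runs."""
    if not reports:
        raise ValueError("no reports to aggregate")
    mean = {}
    sd = {}
    for f in METRIC_FIELDS:
        vals = np.array([getattr(r, f) for r in reports], dtype=float)
        mean[f] = float(vals.mean())
        sd[f] = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
    return RunAggregate(reports, mean, sd)


def compare_methods(sample_a, sample_b, alpha: float = 0.05) -> ComparisonResult:
    """Two-stage comparison of per-run metric samples.

    First an F-test of variance equality (two-sided); if its p-value is at
    least ``alpha`` the means are compared with the equal-variance two-sample
    t-test, otherwise with Welch's unequal-variance variant.  The 95% CI of
    the mean difference (a - b) uses the same variant's standard error and
    degrees of freedom.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 values per sample")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    diff = float(a.mean() - b.mean())
    if va == 0 and vb == 0:
        if np.isclose(diff, 0):
            return ComparisonResult(1.0, 1.0, "equal_variance", (diff, diff), diff)
        return ComparisonResult(1.0, 0.0, "equal_variance", (diff, diff), diff)
    # two-sided F-test on the variance ratio
    f_stat = va / vb if vb > 0 else np.inf
    dfa, dfb = len(a) - 1, len(b) - 1
    cdf = stats.f.cdf(f_stat, dfa, dfb)
    f_p = float(2 * min(cdf, 1 - cdf))
    f_p = min(f_p, 1.0)
    equal_var = f_p >= alpha
    tres = stats.ttest_ind(a, b, equal_var=equal_var)
    t_p = float(tres.pvalue)
    if equal_var:
        sp2 = (dfa * va + dfb * vb) / (dfa + dfb)
        se = np.sqrt(sp2 * (1 / len(a) + 1 / len(b)))
        df = dfa + dfb
    else:
        se = np.sqrt(va / len(a) + vb / len(b))
        df = (va / len(a) + vb / len(b)) ** 2 / (
            (va / len(a)) ** 2 / dfa + (vb / len(b)) ** 2 / dfb
        )
    tcrit = stats.t.ppf(1 - alpha / 2, df)
    ci = (diff - tcrit * se, diff + tcrit * se)
    return ComparisonResult(
        f_test_p=f_p,
        t_test_p=t_p,
        t_test_variant="equal_variance" if equal_var else "welch",
        ci95_mean_difference=(float(ci[0]), float(ci[1])),
        mean_difference=diff,
    )
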
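"""Ground-truth assembly and ranking metrics.

Known-indication drug instances are the positives; because no curated
negative drug–disease pairs exist, negatives are drawn uniformly without
replacement from a tissue-matched candidate pool, an equal number per
replicate, with independent seeded draws (10 by default).  AUROC, AUPR, F1
and accuracy are computed per replicate and aggregated as mean ± sample
standard deviation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score

logger = logging.getLogger("drugresc")

METRICS = ("auroc", "aupr", "f1", "accuracy")


@dataclass
class GroundTruth:
    """One balanced positives/negatives replicate."""

    positives: set[str]
    negatives: set[str]
    sampling_seed: int
    replicate_index: int = 1

    def __post_init__(self) -> None:
        if self.positives & self.negatives:
            raise ValueError("positives and negatives overlap")
        if len(self.negatives) != len(self.positives):
            raise ValueError("ground truth must be balanced")

    @property
    def instances(self) -> list[str]:
        return sorted(self.positives) + sorted(self.negatives)


@dataclass
class MetricReport:
    """Per-replicate metrics plus mean/sd aggregates."""

    per_replicate: pd.DataFrame
    mean: dict[str, float] = field(default_factory=dict)
    sd: dict[str, float] = field(default_factory=dict)
    single_replicate: bool = False

    def summary(self) -> str:
        lines = [f"{len(self.per_replicate)} replicate(s)"]
        for m in METRICS:
            lines.append(f"  {m:<9} {self.mean[m]:.3f} +/- {self.sd[m]:.3f}")
        return "\n".join(lines)


def sample_negatives(
    positives: set[str],
    pool: set[str],
    seed: int,
    replicate_index: int = 1,
) -> GroundTruth:
    """Draw |positives| negatives uniformly without replacement from pool \\ positives."""
    candidates = sorted(pool - set(positives))
    if len(candidates) < len(positives):
        raise ValueError(
            f"pool has only {len(candidates)} non-positive instances; "
            f"{len(positives)} needed"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(candidates, size=len(positives), replace=False)
    return GroundTruth(set(positives), set(chosen), seed, replicate_index)


def build_ground_truths(
    positives: set[str], pool: set[str], n: int = 10, master_seed: int = 0
) -> list[GroundTruth]:
    """n independent balanced replicates with seeds master_seed+1..master_seed+n."""
    return [
        sample_negatives(positives, pool, seed=master_seed + i, replicate_index=i)
        for i in range(1, n + 1)
    ]


def _scores_and_labels(scores: dict[str, float], truth: GroundTruth) -> tuple[np.ndarray, np.ndarray]:
    instances = truth.instances
    missing = [i for i in instances if i not in scores]
    if missing:
        raise ValueError(f"no score for instances: {missing[:5]}")
    s = np.array([scores[i] for i in instances], dtype=float)
    y = np.array([1 if i in truth.positives else 0 for i in instances])
    return s, y


def auroc_from_labels(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUROC of a score vector against binary labels (tied pairs count 0.5)."""
    return float(roc_auc_score(labels, scores))


def aupr_from_labels(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under precision-recall, precision summed over recall increments
    with tied scores grouped."""
    return float(average_precision_score(labels, scores))


def auroc(scores: dict[str, float], truth: GroundTruth) -> float:
    """Probability a random positive outranks a random negative (ties 0.5)."""
    s, y = _scores_and_labels(scores, truth)
    return auroc_from_labels(s, y)


def aupr(scores: dict[str, float], truth: GroundTruth) -> float:
    """Area under precision-recall: precision summed over recall increments."""
    s, y = _scores_and_labels(scores, truth)
    return aupr_from_labels(s, y)


def binarize(scores: dict[str, float], truth: GroundTruth) -> dict[str, int]:
    """Predict positive for the top-m instances, m = |positives| (ties by id)."""
    instances = truth.instances
    order = sorted(instances, key=lambda i: (-scores[i], i))
    m = len(truth.positives)
    top = set(order[:m])
    return {i: int(i in top) for i in instances}


def _confusion(pred: dict[str, int], truth: GroundTruth) -> tuple[int, int, int, int]:
    tp = sum(1 for i in truth.positives if pred[i] == 1)
    fn = len(truth.positives) - tp
    fp = sum(1 for i in truth.negatives if pred[i] == 1)
    tn = len(truth.negatives) - fp
    return tp, fp, fn, tn


def f1(pred: dict[str, int], truth: GroundTruth) -> float:
    """F1 = 2TP / (2TP + FP + FN), the harmonic mean of precision and recall."""
    tp, fp, fn, _ = _confusion(pred, truth)
    denom = 2 * tp + fp + fn
    return 2 * tp / denom if denom else 0.0


def accuracy(pred: dict[str, int], truth: GroundTruth) -> float:
    tp, fp, fn, tn = _confusion(pred, truth)
    return (tp + tn) / (tp + fp + fn + tn)


def evaluate_replicate(scores: dict[str, float], truth: GroundTruth) -> dict[str, float]:
    pred = binarize(scores, truth)
    return {
        "replicate": truth.replicate_index,
        "auroc": auroc(scores, truth),
        "aupr": aupr(scores, truth),
        "f1": f1(pred, truth),
        "accuracy": accuracy(pred, truth),
    }


def aggregate(reports: list[dict[str, float]]) -> MetricReport:
    """Mean and sample sd per metric; a single replicate reports sd = 0."""
    if not reports:
        raise ValueError("no replicates to aggregate")
    table = pd.DataFrame(reports)
    single = len(reports) == 1
    if single:
        logger.warning("single replicate: standard deviation reported as 0")
    mean = {m: float(table[m].mean()) for m in METRICS}
    sd = {m: 0.0 if single else float(table[m].std(ddof=1)) for m in METRICS}
    return MetricReport(per_replicate=table, mean=mean, sd=sd, single_replicate=single)


def evaluate_scores(
    scores: dict[str, float],
    positives: set[str],
    pool: set[str],
    n_samplings: int = 10,
    master_seed: int = 0,
) -> MetricReport:
    """End-to-end: build seeded replicates, score each, aggregate."""
    truths = build_ground_truths(positives, pool, n=n_samplings, master_seed=master_seed)
    return aggregate([evaluate_replicate(scores, t) for t in truths])
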
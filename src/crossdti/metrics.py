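"""Classification metrics and the virtual-screening score."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score


@dataclass
class MetricReport:
    auroc: float | None
    auprc: float | None
    acc: float
    n: int


def compute_metrics(labels, scores, threshold: float = 0.5) -> MetricReport:
    """AUROC (rank / Mann-Whitney with half-credit ties), AUPRC
    (precision-recall step integration), and accuracy at ``threshold``.

    With a single class present the ranking metrics are undefined and reported
    as None; accuracy is still computed.
    """
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if labels.shape != scores.shape or labels.size == 0:
        raise ValueError("labels and scores must be equal-length, non-empty")
    acc = float(((scores >= threshold).astype(int) == labels).mean())
    if len(np.unique(labels)) < 2:
        return MetricReport(auroc=None, auprc=None, acc=acc, n=labels.size)
    return MetricReport(auroc=float(roc_auc_score(labels, scores)),
                        auprc=float(average_precision_score(labels, scores)),
                        acc=acc, n=labels.size)


def screening_score(y_c: float, y_r: float) -> float:
    """Rank score for virtual screening: y_c**2 * y_r.

    Squaring the binding probability emphasizes the classifier's confidence
    before weighting by the predicted affinity.
    """
    y_c = np.asarray(y_c, dtype=float)
    if np.any((y_c < 0) | (y_c > 1)):
        raise ValueError("y_c must lie in [0, 1]")
    return y_c ** 2 * np.asarray(y_r, dtype=float)


def auroc_pairwise(labels, scores) -> float:
    """O(n^2) concordant-pair AUROC used as an independent oracle in tests."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes required")
    wins = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return (wins + 0.5 * ties) / (len(pos) * len(neg))
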
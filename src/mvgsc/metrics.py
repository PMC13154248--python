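"""Clustering agreement metrics.

Six measures comparing a predicted partition Q against ground truth P:
adjusted Rand index (ARI), normalized mutual information (NMI, sqrt
normalization by default), pair-counting F-score and precision, optimal-
assignment ("Hungarian") accuracy, and purity. F-score and precision here are
*pair-counting* quantities -- a true positive is a pair of cells of the same
true type placed in the same predicted cluster -- not per-class macro
averages, which would give different numbers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.optimize import linear_sum_assignment

from .data_io import LabelVector, ValidationError

NMINorm = Literal["sqrt", "mean", "max"]


@dataclass
class MetricReport:
    ari: float
    nmi: float
    f_score: float
    acc: float
    purity: float
    precision: float
    pair_counts: dict

    def as_dict(self) -> dict:
        return {
            "ari": self.ari,
            "nmi": self.nmi,
            "f_score": self.f_score,
            "acc": self.acc,
            "purity": self.purity,
            "precision": self.precision,
            "pair_counts": dict(self.pair_counts),
        }


def _codes(labels) -> np.ndarray:
    if isinstance(labels, LabelVector):
        return labels.as_codes()
    arr = np.asarray(labels)
    _, codes = np.unique(arr, return_inverse=True)
    return codes


def _contingency(truth, pred) -> np.ndarray:
    t = _codes(truth)
    q = _codes(pred)
    if len(t) != len(q):
        raise ValidationError(f"label length mismatch: {len(t)} vs {len(q)}")
    if len(t) == 0:
        raise ValidationError("empty labelings")
    C = np.zeros((t.max() + 1, q.max() + 1), dtype=np.int64)
    np.add.at(C, (t, q), 1)
    return C


def _comb2(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=np.int64)
    return x * (x - 1) // 2


def pair_confusion(truth, pred) -> dict:
    """TP/FP/FN/TN over all unordered cell pairs.

    TP: same true type, same predicted cluster. FP: different type, same
    cluster. FN: same type, different cluster. TN: different in both.
    """
    C = _contingency(truth, pred)
    n = int(C.sum())
    tp = int(_comb2(C).sum())
    same_truth = int(_comb2(C.sum(axis=1)).sum())
    same_pred = int(_comb2(C.sum(axis=0)).sum())
    fn = same_truth - tp
    fp = same_pred - tp
    tn = n * (n - 1) // 2 - tp - fp - fn
    return {"TP": tp, "TN": tn, "FP": fp, "FN": fn}


def ari(truth, pred) -> float:
    """Adjusted Rand index via the contingency-table expected-index form."""
    C = _contingency(truth, pred)
    n = int(C.sum())
    index = float(_comb2(C).sum())
    sum_a = float(_comb2(C.sum(axis=1)).sum())
    sum_b = float(_comb2(C.sum(axis=0)).sum())
    total = float(_comb2(np.array([n]))[0])
    expected = sum_a * sum_b / total if total > 0 else 0.0
    max_index = (sum_a + sum_b) / 2.0
    if max_index == expected:
        # both partitions trivial (all-singletons or single-cluster): identical
        return 1.0
    return (index - expected) / (max_index - expected)


def nmi(truth, pred, norm: NMINorm = "sqrt") -> float:
    """Mutual information of the two partitions, normalized by their entropies."""
    C = _contingency(truth, pred).astype(float)
    n = C.sum()
    P = C / n
    pi = P.sum(axis=1)
    pj = P.sum(axis=0)
    nz = P > 0
    mi = float(np.sum(P[nz] * np.log(P[nz] / np.outer(pi, pj)[nz])))
    hp = float(-np.sum(pi[pi > 0] * np.log(pi[pi > 0])))
    hq = float(-np.sum(pj[pj > 0] * np.log(pj[pj > 0])))
    if hp == 0.0 and hq == 0.0:
        return 1.0  # both single-cluster: identical partitions
    if norm == "sqrt":
        denom = np.sqrt(hp * hq)
    elif norm == "mean":
        denom = (hp + hq) / 2.0
    elif norm == "max":
        denom = max(hp, hq)
    else:
        raise ValueError(f"unknown NMI normalization {norm!r}")
    if denom == 0.0:
        return 0.0
    return max(0.0, mi) / denom


def precision(truth, pred) -> float:
    """Pair-counting precision TP / (TP + FP); 1 when no pair is co-clustered."""
    pc = pair_confusion(truth, pred)
    denom = pc["TP"] + pc["FP"]
    return pc["TP"] / denom if denom > 0 else 1.0


def recall(truth, pred) -> float:
    """Pair-counting recall TP / (TP + FN); 1 when truth has no co-typed pair."""
    pc = pair_confusion(truth, pred)
    denom = pc["TP"] + pc["FN"]
    return pc["TP"] / denom if denom > 0 else 1.0


def f_score(truth, pred, beta: float = 1.0) -> float:
    """Pair-counting F_beta = (1 + beta^2) P R / (beta^2 P + R); 0 if P = R = 0."""
    p = precision(truth, pred)
    r = recall(truth, pred)
    if p == 0.0 and r == 0.0:
        return 0.0
    return (1.0 + beta**2) * p * r / (beta**2 * p + r)


def acc(truth, pred) -> float:
    """Clustering accuracy under the optimal cluster-to-class assignment."""
    C = _contingency(truth, pred)
    k = max(C.shape)
    padded = np.zeros((k, k), dtype=np.int64)
    padded[: C.shape[0], : C.shape[1]] = C
    rows, cols = linear_sum_assignment(-padded)
    return float(padded[rows, cols].sum()) / float(C.sum())


def purity(truth, pred) -> float:
    """Fraction of cells in the majority true class of their predicted cluster."""
    C = _contingency(truth, pred)
    return float(C.max(axis=0).sum()) / float(C.sum())


def evaluate(truth, pred, nmi_norm: NMINorm = "sqrt") -> MetricReport:
    """All six metrics plus the raw pair counts."""
    return MetricReport(
        ari=ari(truth, pred),
        nmi=nmi(truth, pred, norm=nmi_norm),
        f_score=f_score(truth, pred),
        acc=acc(truth, pred),
        purity=purity(truth, pred),
        precision=precision(truth, pred),
        pair_counts=pair_confusion(truth, pred),
    )
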
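"""Per-view sparse KNN similarity graphs with adaptive-neighbor weights.

Each kernel view induces a squared distance d2_ij = K_ii + K_jj - 2 K_ij (the
metric of the kernel's feature space). For every cell the k nearest other
cells receive weights proportional to the margin between the (k+1)-th
distance and their own:

    S_ij = (d_{i,k+1} - d_ij) / (k d_{i,k+1} - sum_{h<=k} d_ih)

so each row lies on the probability simplex with at most k nonzeros, the
nearest neighbor carries the largest weight, and the weights are invariant to
a per-row rescaling of the distances. The per-row normalizer also fixes the
regularizer alpha_i = (k d_{i,k+1} - sum_{h<=k} d_ih) / 2 reused by the
attribute-stage row updates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional

import numpy as np

from .data_io import ValidationError
from .views import ViewSet

DistanceSpace = Literal["kernel_feature", "kernel_as_features"]
Weighting = Literal["adaptive", "binary", "heat"]


@dataclass
class SimilarityGraphSet:
    """Per-view row-stochastic KNN graphs plus the quantities reused later.

    supports[v][i] holds the k neighbor indices of cell i in view v (sorted by
    distance, ties broken by cell index); alphas[v][i] the adaptive-neighbor
    regularizer of that row; distances[v] the full squared-distance matrix.
    """

    graphs: list[np.ndarray]
    k: int
    distance_space: DistanceSpace = "kernel_feature"
    supports: Optional[list[np.ndarray]] = None
    alphas: Optional[list[np.ndarray]] = None
    distances: Optional[list[np.ndarray]] = None

    @property
    def n_views(self) -> int:
        return len(self.graphs)

    @property
    def n_cells(self) -> int:
        return self.graphs[0].shape[0]


def pairwise_distances(view: np.ndarray, mode: DistanceSpace = "kernel_feature") -> np.ndarray:
    """Squared distances induced by a kernel view.

    ``kernel_feature``: d2_ij = K_ii + K_jj - 2 K_ij (clipped at 0).
    ``kernel_as_features``: squared L2 distance between rows of K itself.
    """
    K = np.asarray(view, dtype=float)
    if K.ndim != 2 or K.shape[0] != K.shape[1]:
        raise ValidationError("kernel view must be square")
    if np.max(np.abs(K - K.T)) > 1e-8:
        raise ValidationError("kernel view must be symmetric")
    if mode == "kernel_feature":
        diag = np.diag(K)
        d2 = diag[:, None] + diag[None, :] - 2.0 * K
    elif mode == "kernel_as_features":
        sq = np.sum(K * K, axis=1)
        d2 = sq[:, None] + sq[None, :] - 2.0 * (K @ K.T)
    else:
        raise ValueError(f"unknown distance mode {mode!r}")
    np.maximum(d2, 0.0, out=d2)
    np.fill_diagonal(d2, 0.0)
    return (d2 + d2.T) / 2.0


def _neighbor_order(d2: np.ndarray) -> np.ndarray:
    """Per-row ordering of other cells by (distance, index), self excluded."""
    n = d2.shape[0]
    d = d2.copy()
    np.fill_diagonal(d, np.inf)  # self never a neighbor
    return np.argsort(d, axis=1, kind="stable")


def knn_weights_from_distances(
    d_sorted: np.ndarray, k: int
) -> tuple[np.ndarray, np.ndarray]:
    """Adaptive weights and alpha for one row given its k+1 smallest distances.

    ``d_sorted`` holds d_{i,1} <= ... <= d_{i,k+1}. Returns (weights over the
    first k neighbors, alpha). Degenerate rows (all k+1 distances equal) get
    uniform 1/k weights and alpha = 0.
    """
    dk1 = d_sorted[k]
    denom = k * dk1 - float(np.sum(d_sorted[:k]))
    if denom <= 1e-15:
        return np.full(k, 1.0 / k), 0.0
    w = (dk1 - d_sorted[:k]) / denom
    return w, denom / 2.0


def knn_similarity(
    view: np.ndarray,
    k: int,
    mode: DistanceSpace = "kernel_feature",
    weighting: Weighting = "adaptive",
) -> np.ndarray:
    """Row-stochastic KNN similarity graph of one kernel view."""
    S, _, _, _ = _knn_full(pairwise_distances(view, mode), k, weighting)
    return S


def _knn_full(
    d2: np.ndarray, k: int, weighting: Weighting = "adaptive"
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """(S, supports (n,k), alphas (n,), d2) for a distance matrix."""
    n = d2.shape[0]
    if not 1 <= k <= n - 2:
        raise ValidationError(f"k must satisfy 1 <= k <= n-2 (n={n}, k={k})")
    order = _neighbor_order(d2)
    supports = order[:, :k]
    S = np.zeros_like(d2)
    alphas = np.zeros(n)
    rows = np.arange(n)
    d_sorted = np.take_along_axis(d2, order[:, : k + 1], axis=1)
    if weighting == "adaptive":
        for i in range(n):
            w, alphas[i] = knn_weights_from_distances(d_sorted[i], k)
            S[i, supports[i]] = w
    elif weighting == "binary":
        S[rows[:, None], supports] = 1.0 / k
    elif weighting == "heat":
        scale = np.maximum(np.median(d_sorted[:, :k], axis=1), 1e-12)
        w = np.exp(-d_sorted[:, :k] / scale[:, None])
        w /= np.sum(w, axis=1, keepdims=True)
        S[rows[:, None], supports] = w
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    return S, supports, alphas, d2


def build_similarity_set(
    views: ViewSet,
    k: int = 15,
    mode: DistanceSpace = "kernel_feature",
    weighting: Weighting = "adaptive",
) -> SimilarityGraphSet:
    """One KNN graph per kernel view, same k throughout."""
    graphs, supports, alphas, dists = [], [], [], []
    for K in views.kernels:
        S, sup, alp, d2 = _knn_full(pairwise_distances(K, mode), k, weighting)
        graphs.append(S)
        supports.append(sup)
        alphas.append(alp)
        dists.append(d2)
    return SimilarityGraphSet(
        graphs, k, distance_space=mode, supports=supports, alphas=alphas, distances=dists
    )
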
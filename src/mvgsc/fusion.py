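"""Graph fusion and normalized-Laplacian spectral clustering.

The attribute graph U and structure graph A are combined (elementwise mean by
default), symmetrized, and degree-normalized into T = D^{-1/2} W D^{-1/2}
with a small eps added to the degrees to guard empty rows. Clustering uses
the eigenvectors of the c smallest eigenvalues of L = I - T (equivalently the
c largest of T), row-normalized, followed by seeded k-means.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from sklearn.cluster import KMeans

from .data_io import ValidationError

FusionRule = Literal["mean", "sum", "hadamard"]
_EPS = 1e-10


@dataclass
class FusedGraph:
    W: np.ndarray
    T: np.ndarray
    D: np.ndarray
    eps: float = _EPS

    @property
    def degenerate(self) -> bool:
        """True when the fused affinity carries no edges at all."""
        return not np.any(self.W > 0)


@dataclass
class SpectralOutput:
    L: np.ndarray
    eigvals: np.ndarray
    F: np.ndarray
    labels: np.ndarray
    kmeans_seed: int
    kmeans_restarts: int


def fuse(U: np.ndarray, A: np.ndarray, rule: FusionRule = "mean") -> FusedGraph:
    """Symmetrized combination of U and A plus its normalized matrix T."""
    U = np.asarray(U, dtype=float)
    A = np.asarray(A, dtype=float)
    if U.shape != A.shape or U.ndim != 2 or U.shape[0] != U.shape[1]:
        raise ValidationError(f"shape mismatch: {U.shape} vs {A.shape}")
    if rule == "mean":
        M = (U + A) / 2.0
    elif rule == "sum":
        M = U + A
    elif rule == "hadamard":
        M = U * A
    else:
        raise ValueError(f"unknown fusion rule {rule!r}")
    W = (M + M.T) / 2.0
    np.fill_diagonal(W, 0.0)
    D = W.sum(axis=1) + _EPS
    dinv = 1.0 / np.sqrt(D)
    T = dinv[:, None] * W * dinv[None, :]
    T = (T + T.T) / 2.0
    return FusedGraph(W=W, T=T, D=D)


def normalized_laplacian(fg: FusedGraph) -> np.ndarray:
    """L = I - T (symmetric, eigenvalues in [0, 2] up to eps perturbation)."""
    return np.eye(fg.T.shape[0]) - fg.T


def spectral_embedding(L: np.ndarray, c: int) -> tuple[np.ndarray, np.ndarray]:
    """Row-normalized eigenvectors of the c smallest eigenvalues of L.

    Columns are ordered by ascending eigenvalue with the largest-magnitude
    entry of each column made positive; rows that are identically zero before
    normalization are set to the first canonical basis direction.
    Returns (F, all eigenvalues ascending).
    """
    if c < 2:
        raise ValidationError("need at least 2 clusters")
    L = (L + L.T) / 2.0
    vals, vecs = np.linalg.eigh(L)
    F = vecs[:, :c].copy()
    for j in range(F.shape[1]):
        lead = np.argmax(np.abs(F[:, j]))
        if F[lead, j] < 0:
            F[:, j] = -F[:, j]
    norms = np.linalg.norm(F, axis=1)
    zero = norms <= 0
    if np.any(zero):
        F[zero] = 0.0
        F[zero, 0] = 1.0
        norms[zero] = 1.0
    F = F / norms[:, None]
    return F, vals


def kmeans_assign(
    F: np.ndarray, c: int, seed: int = 0, restarts: int = 20
) -> np.ndarray:
    """Best-of-restarts k-means labels of the embedding rows (deterministic)."""
    if c > F.shape[0]:
        raise ValidationError("more clusters than points")
    if restarts < 1:
        raise ValidationError("need at least one restart")
    km = KMeans(
        n_clusters=c, n_init=restarts, max_iter=300, random_state=int(seed) % (2**31)
    )
    return km.fit_predict(F)


def spectral_cluster_graph(
    G: np.ndarray, c: int, seed: int = 0, restarts: int = 20
) -> SpectralOutput:
    """Normalized-cut spectral clustering of one affinity graph."""
    fg = fuse(G, G, rule="mean")  # symmetrize + normalize; mean(G, G) = G
    L = normalized_laplacian(fg)
    F, vals = spectral_embedding(L, c)
    labels = kmeans_assign(F, c, seed=seed, restarts=restarts)
    return SpectralOutput(
        L=L, eigvals=vals, F=F, labels=labels, kmeans_seed=seed, kmeans_restarts=restarts
    )
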
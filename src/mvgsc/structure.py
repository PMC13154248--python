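"""Stage 2: cross-view consistency ("structure") graph learning.

The Hadamard product H = S^1 . S^2 . ... . S^m keeps an edge only where every
view agrees it exists; nonzero rows are renormalized to the simplex. The
intrinsic structure graph A is then learned by alternating minimization of

    ||A - H||_F^2 + gamma1 ||A||_F^2 + gamma2 * sum_ij ||f2_i - f2_j||^2 A_ij

over simplex rows of A (zero diagonal) and the orthonormal embedding F2 of
the c smallest Laplacian eigenvectors of A. gamma2 follows the
component-matching schedule: doubled while A has fewer connected components
than c, halved while it has more, stopping as soon as the count equals c.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse
from scipy.sparse.csgraph import connected_components

from ._simplex import project_simplex
from .data_io import ValidationError
from .similarity import SimilarityGraphSet


@dataclass
class StructureState:
    H: np.ndarray
    A: np.ndarray
    F2: np.ndarray
    gamma1: float
    gamma2: float
    n_components: int
    n_gamma_adaptations: int = 0
    converged: bool = False
    objective_trace: list = field(default_factory=list)
    gamma2_trace: list = field(default_factory=list)
    zero_rows: np.ndarray = None  # cells whose H row vanished entirely


def count_components(G: np.ndarray, threshold: float = 1e-10) -> int:
    """Connected components of the graph with edges (|G + G'|/2) > threshold."""
    if threshold < 0:
        raise ValidationError("threshold must be nonnegative")
    W = (G + G.T) / 2.0
    adj = scipy.sparse.csr_matrix(W > threshold)
    n, _ = connected_components(adj, directed=False)
    return int(n)


def hadamard_structure(S: SimilarityGraphSet | list[np.ndarray]) -> np.ndarray:
    """Elementwise product of the per-view graphs, rows renormalized.

    All-zero rows (no edge survives in every view) are left at zero and
    reported via a warning; `learn_structure` rejects inputs where more than
    half the rows vanish.
    """
    graphs = S.graphs if isinstance(S, SimilarityGraphSet) else list(S)
    if len(graphs) == 0:
        raise ValidationError("need at least one graph")
    H = graphs[0].copy()
    for G in graphs[1:]:
        H *= G
    sums = H.sum(axis=1)
    nz = sums > 0
    H[nz] /= sums[nz, None]
    if np.any(~nz):
        warnings.warn(
            f"{int(np.sum(~nz))} cells have no edge shared by all views; "
            "consider a larger k",
            stacklevel=2,
        )
    return H


def _embedding(A: np.ndarray, c: int) -> tuple[np.ndarray, np.ndarray]:
    from .attribute import solve_embedding  # same eigen-solve and sign rule

    return solve_embedding(A, c)


def structure_objective(A: np.ndarray, H: np.ndarray, F2: np.ndarray,
                        gamma1: float, gamma2: float) -> float:
    sq = np.sum(F2 * F2, axis=1)
    Q = sq[:, None] + sq[None, :] - 2.0 * (F2 @ F2.T)
    np.maximum(Q, 0.0, out=Q)
    np.fill_diagonal(Q, 0.0)
    return (
        float(np.sum((A - H) ** 2))
        + gamma1 * float(np.sum(A * A))
        + gamma2 * float(np.sum(Q * A))
    )


def learn_structure(
    H: np.ndarray,
    c: int,
    gamma1: float = 1.0,
    gamma2_init: float = 1.0,
    max_iter: int = 50,
    component_threshold: float = 1e-10,
) -> StructureState:
    """Alternate F2 / A updates under the gamma2 component-matching schedule."""
    H = np.asarray(H, dtype=float)
    n = H.shape[0]
    if c < 2 or c > n:
        raise ValidationError(f"need 2 <= c <= n, got c={c}, n={n}")
    zero_rows = np.flatnonzero(H.sum(axis=1) <= 0)
    if len(zero_rows) > n // 2:
        raise ValidationError(
            f"{len(zero_rows)} of {n} cells have empty consistency rows; "
            "increase the neighbor count k"
        )
    A = H.copy()
    gamma2 = float(gamma2_init)
    state = StructureState(
        H=H, A=A, F2=np.zeros((n, c)), gamma1=float(gamma1), gamma2=gamma2,
        n_components=count_components(A, component_threshold),
        zero_rows=zero_rows,
    )
    offdiag = ~np.eye(n, dtype=bool)
    for _ in range(max_iter):
        F2, _ = _embedding(state.A, c)
        state.F2 = F2
        sq = np.sum(F2 * F2, axis=1)
        Q = sq[:, None] + sq[None, :] - 2.0 * (F2 @ F2.T)
        np.maximum(Q, 0.0, out=Q)
        cand = (H - (state.gamma2 / 2.0) * Q) / (1.0 + state.gamma1)
        A = np.zeros_like(H)
        for i in range(n):
            idx = np.flatnonzero(offdiag[i])
            A[i, idx] = project_simplex(cand[i, idx])
        state.A = A
        state.objective_trace.append(
            structure_objective(A, H, F2, state.gamma1, state.gamma2)
        )
        state.gamma2_trace.append(state.gamma2)
        state.n_components = count_components(A, component_threshold)
        if state.n_components == c:
            state.converged = True
            break
        if state.n_components < c:
            state.gamma2 *= 2.0
        else:
            state.gamma2 /= 2.0
        state.n_gamma_adaptations += 1
    state.F2, _ = _embedding(state.A, c)
    return state
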
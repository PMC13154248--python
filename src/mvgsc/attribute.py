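"""Stage 1: self-weighted consensus ("attribute") graph learning.

Alternating minimization of

    J(S, U, F1) = sum_v sum_ij d^v_ij S^v_ij + sum_{v,i} alpha_i^v ||s^v_i||^2
                  + sum_v ||S^v - U||_F
                  + lambda * sum_ij ||f1_i - f1_j||^2 U_ij

over row-stochastic per-view graphs S^v, the consensus graph U (rows on the
simplex, zero diagonal, support restricted to the initial KNN neighborhoods)
and an n-by-c orthonormal spectral embedding F1 of U. The unsquared consensus
term is handled by iterative self-weighting: each weighted least-squares pass
uses w_v = 1/(2 ||U - S^v||_F) evaluated at the current iterate, which is a
majorize-minimize step, so the objective is non-increasing while lambda is
held fixed. lambda is adapted between iterations (doubled when U has fewer
connected components than c, halved when it has more) to steer U toward
exactly c components.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from ._simplex import project_simplex
from .data_io import ValidationError
from .similarity import SimilarityGraphSet
from .structure import count_components

_NORM_FLOOR = 1e-12
_MAX_LAMBDA_ADAPTATIONS = 30


class NumericError(ArithmeticError):
    pass


@dataclass
class AttributeState:
    """Mutable state of the attribute stage."""

    S: SimilarityGraphSet
    w: np.ndarray                 # normalized (sum-1) view weights, reported
    w_raw: np.ndarray             # self-weights 1/(2||U - S^v||), used in updates
    U: np.ndarray
    F1: np.ndarray
    c: int
    lambda_rank: float = 1.0
    objective_trace: list = field(default_factory=list)
    lambda_trace: list = field(default_factory=list)  # lambda in force per trace entry
    n_components: int = 0
    n_lambda_adaptations: int = 0
    U_support: Optional[np.ndarray] = None  # boolean off-diagonal support mask


def solve_embedding(U: np.ndarray, c: int) -> tuple[np.ndarray, np.ndarray]:
    """Eigenvectors of the c smallest Laplacian eigenvalues of (U + U')/2.

    Returns (F, eigenvalues ascending). Deterministic sign: the
    largest-magnitude entry of each column is made positive.
    """
    W = (U + U.T) / 2.0
    L = np.diag(W.sum(axis=1)) - W
    vals, vecs = np.linalg.eigh(L)
    F = vecs[:, :c].copy()
    for j in range(F.shape[1]):
        lead = np.argmax(np.abs(F[:, j]))
        if F[lead, j] < 0:
            F[:, j] = -F[:, j]
    return F, vals[:c]


def _pairwise_sq_rows(F: np.ndarray) -> np.ndarray:
    sq = np.sum(F * F, axis=1)
    P = sq[:, None] + sq[None, :] - 2.0 * (F @ F.T)
    np.maximum(P, 0.0, out=P)
    np.fill_diagonal(P, 0.0)
    return P


def init_attribute(S: SimilarityGraphSet, c: int) -> AttributeState:
    """Uniform weights, U = mean of the per-view graphs, one embedding solve."""
    n = S.n_cells
    if c < 2:
        raise ValidationError("need at least 2 clusters")
    if c > n:
        raise ValidationError("more clusters than cells")
    m = S.n_views
    U = sum(S.graphs) / m
    mask = np.zeros((n, n), dtype=bool)
    if S.supports is not None:
        rows = np.arange(n)
        for sup in S.supports:
            mask[rows[:, None], sup] = True
    else:
        mask = U > 0
    np.fill_diagonal(mask, False)
    F1, _ = solve_embedding(U, c)
    w = np.full(m, 1.0 / m)
    return AttributeState(
        S=S, w=w, w_raw=w.copy(), U=U, F1=F1, c=c, lambda_rank=1.0, U_support=mask
    )


def update_weights(state: AttributeState) -> np.ndarray:
    """Self-weights w_v = 1/(2 ||U - S^v||_F), floored; report normalized."""
    raw = np.array(
        [
            1.0 / (2.0 * max(np.linalg.norm(state.U - Sv), _NORM_FLOOR))
            for Sv in state.S.graphs
        ]
    )
    state.w_raw = raw
    state.w = raw / raw.sum()
    return state.w


def update_view_graphs(
    state: AttributeState, D_views: Optional[list[np.ndarray]] = None
) -> SimilarityGraphSet:
    """Row-wise refit of each S^v toward U on its fixed KNN support.

    Row i of view v minimizes  d^v_i . s + alpha_i ||s||^2 + w_v ||s - u_i||^2
    over the simplex restricted to the k initial neighbors; closed form is the
    simplex projection of (w_v u_i - d^v_i / 2) / (alpha_i + w_v).
    """
    S = state.S
    if D_views is None:
        D_views = S.distances
    if D_views is None or S.supports is None or S.alphas is None:
        raise ValidationError("similarity set lacks distances/supports/alphas")
    n = S.n_cells
    for v, (Sv, d2, sup, alp) in enumerate(
        zip(S.graphs, D_views, S.supports, S.alphas)
    ):
        wv = state.w_raw[v]
        new = np.zeros_like(Sv)
        u_sup = np.take_along_axis(state.U, sup, axis=1)
        d_sup = np.take_along_axis(d2, sup, axis=1)
        denom = alp[:, None] + wv
        cand = (wv * u_sup - d_sup / 2.0) / np.maximum(denom, _NORM_FLOOR)
        proj = project_simplex(cand)
        rows = np.arange(n)
        new[rows[:, None], sup] = proj
        S.graphs[v] = new
    return S


def update_unified(state: AttributeState) -> np.ndarray:
    """Row-wise consensus update of U on its support.

    Row i minimizes  sum_v w_v ||u - s^v_i||^2 + lambda * p_i . u  over the
    simplex (p_ij = ||f1_i - f1_j||^2): simplex projection of
    (sum_v w_v s^v_i - (lambda/2) p_i) / sum_v w_v.
    """
    P = _pairwise_sq_rows(state.F1)
    wsum = state.w_raw.sum()
    M = sum(wv * Sv for wv, Sv in zip(state.w_raw, state.S.graphs))
    cand = (M - (state.lambda_rank / 2.0) * P) / max(wsum, _NORM_FLOOR)
    n = cand.shape[0]
    U = np.zeros_like(cand)
    for i in range(n):
        idx = np.flatnonzero(state.U_support[i])
        U[i, idx] = project_simplex(cand[i, idx])
    state.U = U
    return U


def attribute_objective(state: AttributeState, D_views: Optional[list] = None) -> float:
    """The traced objective J(S, U, F1) at the current state."""
    S = state.S
    if D_views is None:
        D_views = S.distances
    P = _pairwise_sq_rows(state.F1)
    J = 0.0
    for v, Sv in enumerate(S.graphs):
        J += float(np.sum(D_views[v] * Sv))
        J += float(np.sum(S.alphas[v] * np.sum(Sv * Sv, axis=1)))
        J += float(np.linalg.norm(Sv - state.U))
    J += state.lambda_rank * float(np.sum(P * state.U))
    return J


def run_attribute_stage(
    S0: SimilarityGraphSet,
    c: int,
    D_views: Optional[list[np.ndarray]] = None,
    max_iter: int = 30,
    tol: float = 1e-6,
    lambda_init: float = 1.0,
    component_threshold: float = 1e-10,
) -> AttributeState:
    """Run the full alternating loop with lambda adaptation.

    Stops when the relative objective change falls below ``tol`` while lambda
    was not adapted in that iteration, or at ``max_iter``.
    """
    state = init_attribute(S0, c)
    state.lambda_rank = float(lambda_init)
    if D_views is None:
        D_views = S0.distances
    prev = None
    for _ in range(max_iter):
        state.F1, _ = solve_embedding(state.U, c)
        update_weights(state)
        update_view_graphs(state, D_views)
        update_weights(state)
        update_unified(state)
        obj = attribute_objective(state, D_views)
        if not np.isfinite(obj):
            raise NumericError(f"attribute objective diverged: {obj!r}")
        state.objective_trace.append(obj)
        state.lambda_trace.append(state.lambda_rank)

        state.n_components = count_components(state.U, component_threshold)
        lam_changed = False
        if state.n_lambda_adaptations < _MAX_LAMBDA_ADAPTATIONS:
            if state.n_components < c:
                state.lambda_rank *= 2.0
                state.n_lambda_adaptations += 1
                lam_changed = True
            elif state.n_components > c:
                state.lambda_rank /= 2.0
                state.n_lambda_adaptations += 1
                lam_changed = True
        if (
            prev is not None
            and not lam_changed
            and abs(prev - obj) <= tol * max(abs(prev), _NORM_FLOOR)
        ):
            break
        prev = obj
    state.F1, _ = solve_embedding(state.U, c)
    return state
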
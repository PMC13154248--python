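"""End-to-end orchestration: views -> graphs -> two learning stages -> fusion
-> spectral clustering, plus ablation and single-view baseline variants.

Variants
--------
full          the whole two-stage pipeline
no_structure  spectral clustering of the attribute graph U alone
no_attribute  spectral clustering of the structure graph A alone, where A is
              learned from the Hadamard graph of the *initial* KNN graphs
sc_view1/2/3  spectral clustering of a single view's KNN graph
sc_plain      spectral clustering of the Gaussian-kernel KNN graph of raw X
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass, field, asdict
from typing import Literal, Optional

import numpy as np

from .attribute import AttributeState, run_attribute_stage
from .data_io import ExpressionMatrix, LabelVector, ValidationError
from .fusion import (
    FusedGraph,
    fuse,
    kmeans_assign,
    normalized_laplacian,
    spectral_cluster_graph,
    spectral_embedding,
)
from .metrics import MetricReport, evaluate
from .similarity import build_similarity_set
from .structure import StructureState, hadamard_structure, learn_structure
from .views import build_views, gaussian_kernel

Variant = Literal[
    "full", "no_structure", "no_attribute", "sc_view1", "sc_view2", "sc_view3", "sc_plain"
]


@dataclass
class RunConfig:
    """All tunables of one run; defaults follow the method's stated settings
    (polynomial degree d=2, Gaussian bandwidth sigma=10, gamma1=gamma2=1)."""

    # kernels
    poly_degree: int = 2
    poly_gamma: float = 1.0
    poly_coef0: float = 1.0
    gauss_sigma: float = 10.0
    gauss_denominator: str = "two_sigma_sq"
    # KNN graphs
    knn_k: int = 15
    knn_weighting: str = "adaptive"
    knn_distance_space: str = "kernel_feature"
    # attribute stage
    attr_max_iter: int = 30
    attr_tol: float = 1e-6
    attr_lambda_init: float = 1.0
    # structure stage
    struct_gamma1: float = 1.0
    struct_gamma2_init: float = 1.0
    struct_max_iter: int = 50
    struct_component_threshold: float = 1e-10
    # fusion & spectral
    fusion_rule: str = "mean"
    kmeans_restarts: int = 20
    # preprocessing (off by default: the method is defined on the raw matrix)
    preprocess_log_scale: bool = False
    variant: Variant = "full"
    seed: int = 0

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass
class ClusteringResult:
    labels: np.ndarray
    cell_ids: Optional[list] = None
    F: Optional[np.ndarray] = None
    U: Optional[np.ndarray] = None
    A: Optional[np.ndarray] = None
    w: Optional[np.ndarray] = None
    attribute_trace: Optional[list] = None
    structure_trace: Optional[list] = None
    attribute_state: Optional[AttributeState] = None
    structure_state: Optional[StructureState] = None
    metrics: Optional[MetricReport] = None
    config: Optional[dict] = None
    timings: dict = field(default_factory=dict)
    degenerate: bool = False


def _preprocess(X: ExpressionMatrix, cfg: RunConfig) -> ExpressionMatrix:
    if not cfg.preprocess_log_scale:
        return X
    vals = X.values
    totals = vals.sum(axis=1)
    totals[totals == 0] = 1.0
    scaled = vals / totals[:, None] * float(np.median(totals))
    return ExpressionMatrix(
        np.log1p(scaled), X.cell_ids, X.gene_ids, X.orientation_declared
    )


def run_mvgsc(
    X: ExpressionMatrix,
    c: int,
    cfg: Optional[RunConfig] = None,
    truth: Optional[LabelVector] = None,
) -> ClusteringResult:
    """Run the configured variant end to end; deterministic given cfg.seed."""
    cfg = cfg or RunConfig()
    if cfg.variant != "full":
        return run_variant(X, c, cfg, truth=truth)
    t0 = time.perf_counter()
    X = _preprocess(X, cfg)
    views = build_views(
        X,
        poly_degree=cfg.poly_degree,
        poly_gamma=cfg.poly_gamma,
        poly_coef0=cfg.poly_coef0,
        gauss_sigma=cfg.gauss_sigma,
        gauss_denominator=cfg.gauss_denominator,
    )
    t1 = time.perf_counter()
    S = build_similarity_set(
        views, k=cfg.knn_k, mode=cfg.knn_distance_space, weighting=cfg.knn_weighting
    )
    t2 = time.perf_counter()
    attr = run_attribute_stage(
        S,
        c,
        max_iter=cfg.attr_max_iter,
        tol=cfg.attr_tol,
        lambda_init=cfg.attr_lambda_init,
    )
    t3 = time.perf_counter()
    H = hadamard_structure(attr.S)
    struct = learn_structure(
        H,
        c,
        gamma1=cfg.struct_gamma1,
        gamma2_init=cfg.struct_gamma2_init,
        max_iter=cfg.struct_max_iter,
        component_threshold=cfg.struct_component_threshold,
    )
    t4 = time.perf_counter()
    fg = fuse(attr.U, struct.A, rule=cfg.fusion_rule)
    if fg.degenerate:
        warnings.warn("fused graph has no edges; labels are arbitrary", stacklevel=2)
    L = normalized_laplacian(fg)
    F, _ = spectral_embedding(L, c)
    labels = kmeans_assign(F, c, seed=cfg.seed, restarts=cfg.kmeans_restarts)
    t5 = time.perf_counter()
    result = ClusteringResult(
        labels=labels,
        cell_ids=list(X.cell_ids),
        F=F,
        U=attr.U,
        A=struct.A,
        w=attr.w,
        attribute_trace=list(attr.objective_trace),
        structure_trace=list(struct.objective_trace),
        attribute_state=attr,
        structure_state=struct,
        config=cfg.as_dict(),
        degenerate=fg.degenerate,
        timings={
            "views": t1 - t0,
            "similarity": t2 - t1,
            "attribute": t3 - t2,
            "structure": t4 - t3,
            "fusion_spectral": t5 - t4,
        },
    )
    if truth is not None:
        if len(truth) != len(labels):
            raise ValidationError("truth labels do not match the matrix")
        result.metrics = evaluate(truth, labels)
    return result


def run_variant(
    X: ExpressionMatrix,
    c: int,
    cfg: Optional[RunConfig] = None,
    truth: Optional[LabelVector] = None,
) -> ClusteringResult:
    """Run an ablation or single-view baseline (see module docstring)."""
    cfg = cfg or RunConfig()
    variant = cfg.variant
    if variant == "full":
        return run_mvgsc(X, c, cfg, truth=truth)
    X = _preprocess(X, cfg)

    if variant == "sc_plain":
        K = gaussian_kernel(X, sigma=cfg.gauss_sigma, denominator=cfg.gauss_denominator)
        from .similarity import knn_similarity

        G = knn_similarity(K, cfg.knn_k, mode=cfg.knn_distance_space,
                           weighting=cfg.knn_weighting)
        out = spectral_cluster_graph(G, c, seed=cfg.seed, restarts=cfg.kmeans_restarts)
        return _finish(out.labels, X, cfg, truth, F=out.F)

    views = build_views(
        X,
        poly_degree=cfg.poly_degree,
        poly_gamma=cfg.poly_gamma,
        poly_coef0=cfg.poly_coef0,
        gauss_sigma=cfg.gauss_sigma,
        gauss_denominator=cfg.gauss_denominator,
    )
    S = build_similarity_set(
        views, k=cfg.knn_k, mode=cfg.knn_distance_space, weighting=cfg.knn_weighting
    )

    if variant in ("sc_view1", "sc_view2", "sc_view3"):
        v = int(variant[-1]) - 1
        out = spectral_cluster_graph(
            S.graphs[v], c, seed=cfg.seed, restarts=cfg.kmeans_restarts
        )
        return _finish(out.labels, X, cfg, truth, F=out.F)

    if variant == "no_structure":
        attr = run_attribute_stage(
            S, c, max_iter=cfg.attr_max_iter, tol=cfg.attr_tol,
            lambda_init=cfg.attr_lambda_init,
        )
        out = spectral_cluster_graph(
            attr.U, c, seed=cfg.seed, restarts=cfg.kmeans_restarts
        )
        res = _finish(out.labels, X, cfg, truth, F=out.F)
        res.U = attr.U
        res.w = attr.w
        res.attribute_trace = list(attr.objective_trace)
        return res

    if variant == "no_attribute":
        H = hadamard_structure(S)
        struct = learn_structure(
            H, c, gamma1=cfg.struct_gamma1, gamma2_init=cfg.struct_gamma2_init,
            max_iter=cfg.struct_max_iter,
            component_threshold=cfg.struct_component_threshold,
        )
        out = spectral_cluster_graph(
            struct.A, c, seed=cfg.seed, restarts=cfg.kmeans_restarts
        )
        res = _finish(out.labels, X, cfg, truth, F=out.F)
        res.A = struct.A
        res.structure_trace = list(struct.objective_trace)
        return res

    raise ValueError(f"unknown variant {variant!r}")


def _finish(labels, X, cfg, truth, F=None) -> ClusteringResult:
    res = ClusteringResult(
        labels=labels, cell_ids=list(X.cell_ids), F=F, config=cfg.as_dict()
    )
    if truth is not None:
        if len(truth) != len(labels):
            raise ValidationError("truth labels do not match the matrix")
        res.metrics = evaluate(truth, labels)
    return res
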
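"""Synthetic clustered scRNA-seq-like data.

The generator plants ``c`` cell populations whose mean expression profiles sit
at a controlled distance from each other. ``separation`` is measured in units
of the within-cluster spread -- the rms distance of a cell to its population
centroid -- so ``separation = s`` means the population centers are ``s``
cluster radii apart, independent of the number of genes. Nonnegativity,
sparsity and dropout (independent Bernoulli zero-masking) emulate the gross
statistical shape of single-cell expression; no batch effects or
mean-dropout coupling are modeled.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np

from .data_io import ExpressionMatrix, LabelVector, ValidationError

CountMode = Literal["gaussian_nonneg", "negative_binomial"]


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic dataset.

    separation:
        Distance between cluster mean profiles in units of the within-cluster
        spread (rms point-to-centroid distance). 0 means the planted labels
        carry no signal; >= ~4 is clearly separable; 8 is well separated.
        In ``negative_binomial`` mode the same number is interpreted as the L2
        distance between log-mean profiles (see module docstring of methods).
    dropout_rate:
        Probability that any entry is independently zeroed after sampling.
    """

    n_cells: int
    n_genes: int
    n_clusters: int
    cluster_sizes: Optional[Sequence[int]] = None
    separation: float = 8.0
    dropout_rate: float = 0.3
    count_mode: CountMode = "gaussian_nonneg"
    nb_dispersion: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 2 or self.n_genes < 1 or self.n_clusters < 1:
            raise ValidationError("need n_cells >= 2, n_genes >= 1, n_clusters >= 1")
        if self.n_clusters > self.n_cells:
            raise ValidationError("more clusters than cells")
        if not 0.0 <= self.dropout_rate <= 1.0:
            raise ValidationError("dropout_rate must be in [0, 1]")
        if self.separation < 0:
            raise ValidationError("separation must be nonnegative")
        if self.nb_dispersion <= 0:
            raise ValidationError("nb_dispersion must be positive")
        if self.cluster_sizes is not None:
            sizes = list(self.cluster_sizes)
            if len(sizes) != self.n_clusters:
                raise ValidationError("cluster_sizes length must equal n_clusters")
            if any(s < 1 for s in sizes):
                raise ValidationError("every cluster needs at least one cell")
            if sum(sizes) != self.n_cells:
                raise ValidationError("cluster_sizes must sum to n_cells")

    def resolved_sizes(self) -> list[int]:
        if self.cluster_sizes is not None:
            return list(self.cluster_sizes)
        base = self.n_cells // self.n_clusters
        sizes = [base] * self.n_clusters
        for i in range(self.n_cells - base * self.n_clusters):
            sizes[i] += 1
        return sizes


# within-cluster noise sd per gene (gaussian mode) and baseline mean, fixed
_SIGMA = 1.0
_BASELINE = 1.0
_NB_LOG_BASE_MEAN = np.log(2.0)


def _cluster_directions(rng: np.random.Generator, n_genes: int, c: int) -> np.ndarray:
    """c mutually orthonormal random directions in gene space (rows)."""
    g = rng.standard_normal((n_genes, max(c, 1)))
    q, _ = np.linalg.qr(g)
    return q[:, :c].T


def generate(spec: SyntheticSpec) -> tuple[ExpressionMatrix, LabelVector]:
    """Draw one dataset; bit-identical for identical spec (incl. seed)."""
    rng = np.random.default_rng(spec.seed)
    sizes = spec.resolved_sizes()
    labels = np.repeat(np.arange(spec.n_clusters), sizes)

    dirs = _cluster_directions(rng, spec.n_genes, spec.n_clusters)
    # orthonormal directions: placing centers at r*u_g gives pairwise distance
    # r*sqrt(2); within-cluster spread is sigma*sqrt(n_genes)
    radius = spec.separation * _SIGMA * np.sqrt(spec.n_genes) / np.sqrt(2.0)

    if spec.count_mode == "gaussian_nonneg":
        means = _BASELINE + radius * dirs  # (c, n_genes)
        X = means[labels] + _SIGMA * rng.standard_normal((spec.n_cells, spec.n_genes))
        X = np.clip(X, 0.0, None)
    elif spec.count_mode == "negative_binomial":
        # log-mean profiles at pairwise L2 distance `separation`
        log_means = _NB_LOG_BASE_MEAN + (spec.separation / np.sqrt(2.0)) * dirs
        mu = np.exp(np.clip(log_means[labels], -30.0, 12.0))
        # NB(mean mu, dispersion r): p = r / (r + mu)
        r = spec.nb_dispersion
        X = rng.negative_binomial(r, r / (r + mu)).astype(float)
    else:  # pragma: no cover
        raise ValidationError(f"unknown count_mode {spec.count_mode!r}")

    if spec.dropout_rate > 0:
        keep = rng.random((spec.n_cells, spec.n_genes)) >= spec.dropout_rate
        X = X * keep

    cell_ids = [f"cell{i:04d}" for i in range(spec.n_cells)]
    gene_ids = [f"gene{j:05d}" for j in range(spec.n_genes)]
    em = ExpressionMatrix(X, cell_ids, gene_ids)
    lv = LabelVector([f"type{g}" for g in labels])
    return em, lv
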
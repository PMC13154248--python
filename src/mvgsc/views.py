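"""Kernel views of the expression matrix.

Three cell-by-cell kernels give three representations ("views") of the same
cells: an inhomogeneous polynomial kernel (nonlinear, inner-product based), a
Gaussian kernel (distance based, smooths noise), and a linear kernel. Fixed
view order: [polynomial, gaussian, linear].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .data_io import ExpressionMatrix, ValidationError

VIEW_NAMES = ("polynomial", "gaussian", "linear")


class NumericError(ArithmeticError):
    """A kernel evaluation overflowed; rescale the input."""


@dataclass
class ViewSet:
    """The kernel matrices V^(1..m) plus the parameters that produced them."""

    kernels: list[np.ndarray]
    view_names: list[str]
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, K in zip(self.view_names, self.kernels):
            if not np.all(np.isfinite(K)):
                raise NumericError(f"{name} kernel has non-finite entries")
            if np.max(np.abs(K - K.T)) > 1e-10:
                raise ValidationError(f"{name} kernel is not symmetric")

    @property
    def n_views(self) -> int:
        return len(self.kernels)


def _rows(X) -> np.ndarray:
    if isinstance(X, ExpressionMatrix):
        return X.values
    return np.asarray(X, dtype=float)


def polynomial_kernel(
    X, gamma: float = 1.0, degree: int = 2, coef0: float = 1.0
) -> np.ndarray:
    """K_ij = (gamma * <x_i, x_j> + coef0) ** degree."""
    if gamma <= 0:
        raise ValidationError("gamma must be positive")
    if degree < 1:
        raise ValidationError("degree must be >= 1")
    A = _rows(X)
    with np.errstate(over="raise"):
        try:
            K = (gamma * (A @ A.T) + coef0) ** degree
        except FloatingPointError as exc:
            raise NumericError(
                "polynomial kernel overflowed; scale the expression matrix down"
            ) from exc
    if not np.all(np.isfinite(K)):
        raise NumericError(
            "polynomial kernel overflowed; scale the expression matrix down"
        )
    return (K + K.T) / 2.0


def gaussian_kernel(
    X, sigma: float = 10.0, denominator: Literal["two_sigma_sq", "sigma_sq"] = "two_sigma_sq"
) -> np.ndarray:
    """K_ij = exp(-||x_i - x_j||^2 / (2 sigma^2)); unit diagonal."""
    if sigma <= 0:
        raise ValidationError("sigma must be positive")
    A = _rows(X)
    sq = np.sum(A * A, axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (A @ A.T)
    np.maximum(d2, 0.0, out=d2)
    denom = 2.0 * sigma**2 if denominator == "two_sigma_sq" else sigma**2
    K = np.exp(-d2 / denom)
    K = (K + K.T) / 2.0
    np.fill_diagonal(K, 1.0)
    return K


def linear_kernel(X) -> np.ndarray:
    """K_ij = <x_i, x_j>."""
    A = _rows(X)
    K = A @ A.T
    return (K + K.T) / 2.0


def build_views(
    X,
    poly_degree: int = 2,
    poly_gamma: float = 1.0,
    poly_coef0: float = 1.0,
    gauss_sigma: float = 10.0,
    gauss_denominator: Literal["two_sigma_sq", "sigma_sq"] = "two_sigma_sq",
) -> ViewSet:
    """Build the fixed [polynomial, gaussian, linear] view set."""
    kernels = [
        polynomial_kernel(X, gamma=poly_gamma, degree=poly_degree, coef0=poly_coef0),
        gaussian_kernel(X, sigma=gauss_sigma, denominator=gauss_denominator),
        linear_kernel(X),
    ]
    params = {
        "poly_gamma": poly_gamma,
        "poly_degree": poly_degree,
        "poly_coef0": poly_coef0,
        "gauss_sigma": gauss_sigma,
        "gauss_denominator": gauss_denominator,
    }
    return ViewSet(kernels, list(VIEW_NAMES), params)
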
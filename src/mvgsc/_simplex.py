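"""Euclidean projection onto the probability simplex (Duchi et al. 2008)."""

from __future__ import annotations

import numpy as np


def project_simplex(v: np.ndarray) -> np.ndarray:
    """Project ``v`` onto {x : x >= 0, sum(x) = 1}.

    Works on a 1-D vector or row-wise on a 2-D array.
    """
    v = np.asarray(v, dtype=float)
    if v.ndim == 1:
        return _project_rows(v[None, :])[0]
    return _project_rows(v)


def _project_rows(V: np.ndarray) -> np.ndarray:
    n = V.shape[1]
    if n == 0:
        raise ValueError("cannot project an empty vector onto the simplex")
    # sort descending, find the largest rho with u_rho - tau > 0
    U = np.sort(V, axis=1)[:, ::-1]
    css = np.cumsum(U, axis=1) - 1.0
    idx = np.arange(1, n + 1)
    cond = U - css / idx > 0
    rho = n - 1 - np.argmax(cond[:, ::-1], axis=1)  # last True per row
    tau = css[np.arange(V.shape[0]), rho] / (rho + 1)
    return np.maximum(V - tau[:, None], 0.0)
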
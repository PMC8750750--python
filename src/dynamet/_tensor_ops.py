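"""Small dense third-order tensor utilities shared by the factorization solvers.

All routines use the "natural" row-major unfolding: mode-``n`` unfolding moves
axis ``n`` first and flattens the remaining axes in their original order, so
``unfold(X, 0)[i, j*K + k] == X[i, j, k]``.
"""

from __future__ import annotations

import numpy as np


def unfold(X: np.ndarray, mode: int) -> np.ndarray:
    """Mode-``mode`` matricization of a third-order array."""
    return np.moveaxis(X, mode, 0).reshape(X.shape[mode], -1)


def khatri_rao(U: np.ndarray, V: np.ndarray) -> np.ndarray:
    """Column-wise Khatri-Rao product; row ``(i*V.shape[0] + j)`` is ``U[i]*V[j]``."""
    if U.shape[1] != V.shape[1]:
        raise ValueError("khatri_rao: column counts differ")
    return (U[:, None, :] * V[None, :, :]).reshape(-1, U.shape[1])


def cp_tensor(weights: np.ndarray, A: np.ndarray, B: np.ndarray, C: np.ndarray) -> np.ndarray:
    """Dense tensor of the Kruskal operator  sum_r w_r a_r o b_r o c_r."""
    weights = np.asarray(weights, dtype=float)
    if not (A.shape[1] == B.shape[1] == C.shape[1] == weights.shape[0]):
        raise ValueError(
            f"component count mismatch: weights {weights.shape[0]}, "
            f"A {A.shape[1]}, B {B.shape[1]}, C {C.shape[1]}"
        )
    return np.einsum("r,ir,jr,kr->ijk", weights, A, B, C, optimize=True)


def masked_sqnorm(X: np.ndarray, mask: np.ndarray | None = None) -> float:
    """Squared Frobenius norm, restricted to ``mask == 1`` entries if given."""
    if mask is None:
        return float(np.sum(X * X))
    return float(np.sum((X * X)[mask.astype(bool)]))
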
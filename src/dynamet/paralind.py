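"""Paralind(S, R, R): CP with linearly dependent subject-mode components.

When the true subject-mode components of a CP model are collinear (rank
deficiency, |C12| ~ 1), the unrestricted model is unstable and hard to
interpret. Paralind makes the dependency explicit: the effective subjects
factor is  A_eff = A H  with a basis A (I x S, S < R) and a binary
dependency matrix H (S x R) recording which components share a basis
vector. Example: Paralind(2,3,3) with components 1 and 2 equal in the
subjects mode has  H = [[1, 1, 0], [0, 0, 1]].

Fitting minimizes  || W * (X - [[lambda; A H, B, C]]) ||^2  by alternating
updates: A via a reduced least-squares problem (H fixed), B via the
orthogonal-Procrustes solution (orthogonality in the metabolites mode makes
the restricted model unique), C via row-wise non-negative least squares
(time mode), with the same EM treatment of missing entries and multi-start
strategy as the CP fitter. Only A_eff = A H is identified; A and H
individually are not (any invertible mixing of A's columns that preserves
A H is equivalent).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._tensor_ops import cp_tensor, khatri_rao, masked_sqnorm, unfold
from .cp import (
    FitOptions,
    _hosvd_init,
    _init_factors,
    _ls_update,
    _nnls_update,
    _procrustes_update,
    fit_percent,
)

__all__ = ["ParalindDecomposition", "dependency_matrix", "fit_paralind"]


@dataclass
class ParalindDecomposition:
    """Basis factor A (I x S), dependency matrix H (S x R), unit-norm B, C
    and weights lambda; the effective subjects factor is ``A @ H``."""

    weights: np.ndarray
    A: np.ndarray
    H: np.ndarray
    B: np.ndarray
    C: np.ndarray
    fit: float | None = None
    objective: float | None = None
    objective_history: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        for name in ("A", "H", "B", "C"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        S, R = self.H.shape
        if self.A.shape[1] != S:
            raise ValueError("A column count must equal H row count")
        if not (self.B.shape[1] == self.C.shape[1] == self.weights.size == R):
            raise ValueError("B, C, weights must agree with H on R")

    @property
    def n_components(self) -> int:
        return self.H.shape[1]

    @property
    def n_basis(self) -> int:
        return self.H.shape[0]

    @property
    def effective_A(self) -> np.ndarray:
        return self.A @ self.H

    def reconstruct(self) -> np.ndarray:
        return cp_tensor(self.weights, self.effective_A, self.B, self.C)

    def save(self, directory, **kwargs) -> None:
        from pathlib import Path

        from .cp import CPDecomposition

        extra = kwargs.pop("extra_manifest", {}) or {}
        extra.update({"model": "paralind", "n_basis": self.n_basis,
                      "H": self.H.astype(int).tolist()})
        CPDecomposition(
            weights=self.weights, A=self.effective_A, B=self.B, C=self.C,
            fit=self.fit, objective=self.objective,
        ).save(directory, extra_manifest=extra, **kwargs)
        np.savetxt(Path(directory) / "dependency_matrix.tsv",
                   self.H.astype(int), fmt="%d", delimiter="\t")


def dependency_matrix(S: int, R: int, groups) -> np.ndarray:
    """Build H from a grouping pattern: ``groups[r]`` (1-based, in 1..S) is
    the basis vector component ``r+1`` uses. Every basis must be used."""
    groups = list(groups)
    if S > R:
        raise ValueError("S must be <= R")
    if len(groups) != R:
        raise ValueError(f"groups must have length R = {R}")
    if sorted(set(groups)) != list(range(1, S + 1)):
        raise ValueError(
            f"groups must cover every basis index 1..{S} (got {groups})"
        )
    H = np.zeros((S, R))
    for r, s in enumerate(groups):
        H[s - 1, r] = 1.0
    return H


def _normalize_paralind(A, H, B, C, nonneg_modes):
    """Unit-norm A columns and C columns, magnitudes into lambda.

    H is binary (each component uses exactly one basis column), so scaling a
    basis column of A scales the corresponding effective columns uniformly;
    B comes out of the Procrustes update with orthonormal columns already.
    Sign convention matches the CP fitter: metabolites columns flipped to a
    non-negative sum, compensated in the basis column when all components
    sharing it flip consistently, otherwise in H.
    """
    A, H, B, C = (np.asarray(F, float).copy() for F in (A, H, B, C))
    S, R = H.shape
    a_norms = np.linalg.norm(A, axis=0)
    nz = a_norms > 0
    A[:, nz] /= a_norms[nz]
    c_norms = np.linalg.norm(C, axis=0)
    nzc = c_norms > 0
    C[:, nzc] /= c_norms[nzc]
    b_norms = np.linalg.norm(B, axis=0)
    nzb = b_norms > 0
    B[:, nzb] /= b_norms[nzb]
    basis_of = np.argmax(H != 0, axis=0)
    weights = (
        a_norms[basis_of] * np.abs(H[basis_of, np.arange(R)])
        * b_norms * c_norms
    )
    H[H != 0] = np.sign(H[H != 0])
    if 1 not in nonneg_modes:
        for r in range(R):
            if B[:, r].sum() < 0:
                B[:, r] *= -1
                H[basis_of[r], r] *= -1
    order = np.argsort(-np.abs(weights), kind="stable")
    return weights[order], A, H[:, order], B[:, order], C[:, order]


def fit_paralind(
    X: np.ndarray,
    S: int,
    R: int,
    H: np.ndarray,
    opts: FitOptions | None = None,
    mask: np.ndarray | None = None,
) -> ParalindDecomposition:
    """Best-of-multistart Paralind(S, R, R) fit.

    When ``opts`` is omitted, the conventional constraint set for this model
    is used: orthogonality in the metabolites mode (which makes the
    restricted model unique) and non-negativity in the time mode. An explicit
    ``opts`` is honoured verbatim (its ``n_components`` is ignored in favour
    of ``R``). Deterministic given ``opts.seed``.
    """
    if opts is None:
        opts = FitOptions(n_components=R, orth_modes=(1,), nonneg_modes=(2,))
    X = np.asarray(X, dtype=float)
    if X.ndim != 3:
        raise ValueError("X must be a third-order array")
    H = np.asarray(H, dtype=float)
    if H.shape != (S, R):
        raise ValueError(f"H must be {S} x {R}")
    if S > R:
        raise ValueError("S must be <= R")
    if np.any(~H.any(axis=1)):
        raise ValueError("every basis (row of H) must be used by a component")
    Wb = None
    if mask is not None:
        Wb = np.asarray(mask).astype(bool)
        if Wb.shape != X.shape:
            raise ValueError("mask shape must match X")
    check = X if Wb is None else X[Wb]
    if not np.isfinite(check).all():
        raise ValueError("non-finite entries in X at observed positions")

    nonneg = set(opts.nonneg_modes)
    orth = set(opts.orth_modes)
    base_sq = masked_sqnorm(X, mask)
    streams = np.random.SeedSequence(opts.seed).spawn(opts.n_starts)
    best = None
    for s_idx, stream in enumerate(streams):
        if s_idx == 0:
            _, B0, C0 = _hosvd_init(X, R, nonneg, orth, Wb)
            Xw = X if Wb is None else np.where(Wb, X, 0.0)
            A0 = np.linalg.svd(unfold(Xw, 0), full_matrices=False)[0][:, :S]
        else:
            rng = np.random.default_rng(stream)
            _, B0, C0 = _init_factors(X.shape, R, nonneg, orth, rng)
            A0 = rng.standard_normal((X.shape[0], S))
        factors = [A0, B0, C0]
        hist = []
        prev = np.inf
        for _ in range(opts.max_iters):
            A0, B0, C0 = factors
            A_eff = A0 @ H
            if Wb is not None:
                X_hat = cp_tensor(np.ones(R), A_eff, B0, C0)
                X_work = np.where(Wb, X, X_hat)
            else:
                X_work = X
            # A update: X_(0) ~ A (H M0^T) with M0 the KR of the other modes
            M0 = khatri_rao(B0, C0)                   # (J*K) x R
            Z = M0 @ H.T                              # (J*K) x S
            A0 = _ls_update(Z, unfold(X_work, 0))
            A_eff = A0 @ H
            # B update (orthogonal or plain LS)
            M1 = khatri_rao(A_eff, C0)
            X1 = unfold(X_work, 1)
            if 1 in orth:
                B0 = _procrustes_update(M1, X1, B0)
            elif 1 in nonneg:
                B0 = _nnls_update(M1, X1)
            else:
                B0 = _ls_update(M1, X1)
            # C update (non-negative or plain LS)
            M2 = khatri_rao(A_eff, B0)
            X2 = unfold(X_work, 2)
            if 2 in nonneg:
                C0 = _nnls_update(M2, X2)
            else:
                C0 = _ls_update(M2, X2)
            factors = [A0, B0, C0]
            X_hat = cp_tensor(np.ones(R), A0 @ H, B0, C0)
            obj = masked_sqnorm(X - X_hat, mask)
            hist.append(obj)
            denom = max(base_sq, np.finfo(float).tiny)
            if prev - obj <= opts.tol * denom and np.isfinite(obj):
                break
            prev = obj
        if hist and np.isfinite(hist[-1]) and (best is None or hist[-1] < best[0]):
            best = (hist[-1], factors, np.asarray(hist))
    if best is None:
        raise RuntimeError("all Paralind starts diverged")

    obj, (A0, B0, C0), hist = best
    weights, A_n, H_n, B_n, C_n = _normalize_paralind(A0, H, B0, C0, nonneg)
    model = ParalindDecomposition(
        weights=weights, A=A_n, H=H_n, B=B_n, C=C_n,
        objective=obj, objective_history=hist,
    )
    model.fit = fit_percent(X, model.reconstruct(), mask)
    return model
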
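"""CANDECOMP/PARAFAC (CP) factorization with constraints and missing data.

An R-component CP model writes a subjects x metabolites x time tensor as a
sum of rank-one terms,

    X  ~  sum_r  lambda_r  a_r o b_r o c_r,

with unit-norm factor columns and the magnitudes absorbed by the weight
vector lambda. The model is fitted by minimizing the (optionally masked)
least-squares objective  || W * (X - X_hat) ||^2  with alternating
least-squares sweeps; missing entries are handled by expectation-maximization
imputation (each sweep fills them with the current model's prediction, which
minimizes the identical masked objective at convergence). Constraints follow
common metabolomics practice for this design: non-negativity in the time
mode (concentration profiles), optionally orthogonality in a mode via the
orthogonal-Procrustes subproblem. Multiple random initializations guard
against local minima; the start with the lowest final objective wins.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import nnls

from ._tensor_ops import cp_tensor, khatri_rao, masked_sqnorm, unfold

__all__ = ["CPDecomposition", "FitOptions", "fit_cp", "fit_percent", "reconstruct"]


@dataclass
class CPDecomposition:
    """Weights ``lambda`` and unit-norm factor matrices A (subjects),
    B (metabolites), C (time), ordered by descending ``|lambda|``."""

    weights: np.ndarray
    A: np.ndarray
    B: np.ndarray
    C: np.ndarray
    fit: float | None = None                 # explained fit (%) on the training data
    objective: float | None = None           # final (masked) squared residual
    objective_history: np.ndarray | None = None   # per-iteration, winning start

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        for name in ("A", "B", "C"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        R = self.weights.size
        if not (self.A.shape[1] == self.B.shape[1] == self.C.shape[1] == R):
            raise ValueError("factor matrices and weights disagree on R")

    @property
    def n_components(self) -> int:
        return self.weights.size

    @property
    def factors(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return self.A, self.B, self.C

    def reconstruct(self) -> np.ndarray:
        return cp_tensor(self.weights, self.A, self.B, self.C)

    def save(self, directory, subject_labels=None, metabolite_labels=None,
             time_labels=None, extra_manifest: dict | None = None) -> None:
        """Write factors as labelled TSV tables plus a JSON manifest."""
        import json
        from pathlib import Path

        import pandas as pd

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        cols = [f"comp{r + 1}" for r in range(self.n_components)]
        for name, M, labels in (
            ("subjects", self.A, subject_labels),
            ("metabolites", self.B, metabolite_labels),
            ("time", self.C, time_labels),
        ):
            idx = labels if labels is not None else range(1, M.shape[0] + 1)
            pd.DataFrame(M, index=list(idx), columns=cols).to_csv(
                directory / f"factor_{name}.tsv", sep="\t"
            )
        np.savetxt(directory / "weights.tsv", self.weights[None], delimiter="\t")
        manifest = {
            "model": "cp",
            "n_components": self.n_components,
            "fit_percent": self.fit,
            "objective": self.objective,
        }
        manifest.update(extra_manifest or {})
        (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))


@dataclass
class FitOptions:
    """Optimization settings shared by the CP and Paralind fitters.

    ``nonneg_modes`` / ``orth_modes`` index modes 0 (subjects), 1
    (metabolites), 2 (time). Defaults: non-negative time mode, 20 random
    starts, stop when the relative objective change drops below ``tol``.
    """

    n_components: int = 2
    n_starts: int = 20
    max_iters: int = 10_000
    tol: float = 1e-10
    nonneg_modes: tuple[int, ...] = (2,)
    orth_modes: tuple[int, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")
        if self.n_starts < 1:
            raise ValueError("n_starts must be >= 1")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")
        if set(self.nonneg_modes) & set(self.orth_modes):
            raise ValueError("a mode cannot be both non-negative and orthogonal")


def reconstruct(model: CPDecomposition) -> np.ndarray:
    """Dense tensor of a fitted model (module-level convenience)."""
    return model.reconstruct()


def fit_percent(X: np.ndarray, X_hat: np.ndarray,
                mask: np.ndarray | None = None) -> float:
    """Explained fit  100 * (1 - ||X - X_hat||^2 / ||X||^2), optionally masked."""
    X = np.asarray(X, float)
    X_hat = np.asarray(X_hat, float)
    if X.shape != X_hat.shape:
        raise ValueError("X and X_hat must have the same shape")
    denom = masked_sqnorm(X, mask)
    if denom == 0:
        raise ValueError("||X|| is zero; fit undefined")
    return 100.0 * (1.0 - masked_sqnorm(X - X_hat, mask) / denom)


# --------------------------------------------------------------------------
# ALS machinery (shared with the Paralind fitter)
# --------------------------------------------------------------------------

def _nnls_update(M: np.ndarray, Xn: np.ndarray) -> np.ndarray:
    """Row-wise non-negative least squares:  min ||Xn_i - M u_i||, u_i >= 0.

    Fast path: solve the unconstrained problem for all rows at once; a row
    whose unconstrained optimum is already non-negative is the NNLS optimum
    (feasible global optimum of the relaxation). Only violating rows go
    through the active-set solver.
    """
    out = _ls_update(M, Xn)
    bad = np.where((out < 0).any(axis=1))[0]
    for i in bad:
        out[i], _ = nnls(M, Xn[i])
    np.maximum(out, 0.0, out=out)   # clip float dust on the fast path
    return out


def _ls_update(M: np.ndarray, Xn: np.ndarray) -> np.ndarray:
    """Unconstrained update via the normal equations (pinv fallback)."""
    G = M.T @ M
    RHS = Xn @ M
    try:
        return np.linalg.solve(G, RHS.T).T
    except np.linalg.LinAlgError:
        return RHS @ np.linalg.pinv(G)


def _procrustes_update(M: np.ndarray, Xn: np.ndarray,
                       previous: np.ndarray) -> np.ndarray:
    """Orthogonality-constrained update: the orthogonal-Procrustes solution
    of  min ||Xn - U M^T||  s.t.  U^T U = I.  A zero cross-product matrix
    leaves the subproblem undetermined; keep the previous iterate then."""
    P = Xn @ M
    if not np.any(P):
        return previous
    U, _, Vt = np.linalg.svd(P, full_matrices=False)
    return U @ Vt


def _hosvd_init(X, R, nonneg_modes, orth_modes, mask):
    """Deterministic start: leading left singular vectors of each unfolding
    (missing entries zero-filled), a standard high-quality CP initialization."""
    Xw = X if mask is None else np.where(mask.astype(bool), X, 0.0)
    factors = []
    for n in range(3):
        U = np.linalg.svd(unfold(Xw, n), full_matrices=False)[0]
        F = U[:, :R]
        if F.shape[1] < R:      # mode shorter than R: pad deterministically
            F = np.hstack([F, np.ones((F.shape[0], R - F.shape[1]))])
        if n in nonneg_modes:
            F = np.abs(F)
        if n in orth_modes:
            F, _ = np.linalg.qr(F)
        factors.append(F)
    return factors


def _init_factors(shape, R, nonneg_modes, orth_modes, rng):
    factors = []
    for n, dim in enumerate(shape):
        F = rng.standard_normal((dim, R))
        if n in nonneg_modes:
            F = np.abs(F)
        if n in orth_modes:
            F, _ = np.linalg.qr(F)
        factors.append(F)
    return factors


def _als(X, R, factors, mask, nonneg_modes, orth_modes, max_iters, tol):
    """One constrained-ALS trajectory; returns (factors, history).

    With a mask, missing entries are EM-imputed from the current model before
    every sweep, so each sweep decreases the masked objective.
    """
    Wb = None if mask is None else mask.astype(bool)
    base_sq = masked_sqnorm(X, mask)
    X_work = X if Wb is None else np.where(Wb, X, 0.0)
    history = []
    prev = np.inf
    for _ in range(max_iters):
        X_hat = cp_tensor(np.ones(R), *factors)
        if Wb is not None:
            X_work = np.where(Wb, X, X_hat)
        for n in range(3):
            others = [factors[m] for m in range(3) if m != n]
            M = khatri_rao(*others)          # (prod other dims) x R
            Xn = unfold(X_work, n)
            if n in orth_modes:
                factors[n] = _procrustes_update(M, Xn, factors[n])
            elif n in nonneg_modes:
                factors[n] = _nnls_update(M, Xn)
            else:
                factors[n] = _ls_update(M, Xn)
        X_hat = cp_tensor(np.ones(R), *factors)
        obj = masked_sqnorm(X - X_hat, mask)
        history.append(obj)
        denom = max(base_sq, np.finfo(float).tiny)
        if prev - obj <= tol * denom and np.isfinite(obj):
            break
        prev = obj
    return factors, np.asarray(history)


def _normalize(factors, nonneg_modes):
    """Unit-norm columns, magnitudes into lambda, fixed sign convention.

    Signs: lambda >= 0 always (norms are non-negative); each metabolites
    column is flipped to have a non-negative sum, compensated in the
    subjects column, so similarity scores are comparable across runs.
    Constrained non-negative columns are never flipped.
    """
    A, B, C = (np.asarray(F, float).copy() for F in factors)
    R = A.shape[1]
    weights = np.ones(R)
    for F in (A, B, C):
        norms = np.linalg.norm(F, axis=0)
        nz = norms > 0
        F[:, nz] /= norms[nz]
        weights *= norms
    for r in range(R):
        if 1 not in nonneg_modes and B[:, r].sum() < 0:
            B[:, r] *= -1
            A[:, r] *= -1
    order = np.argsort(-np.abs(weights), kind="stable")
    return weights[order], A[:, order], B[:, order], C[:, order]


def fit_cp(X: np.ndarray, opts: FitOptions,
           mask: np.ndarray | None = None) -> CPDecomposition:
    """Best-of-``n_starts`` constrained CP fit of a third-order tensor.

    The first start is the deterministic HOSVD initialization; the remaining
    ``n_starts - 1`` use i.i.d. random factors. Deterministic given
    ``opts.seed``: per-start RNG streams are spawned from it, and ties
    between starts resolve to the earliest start. Raises if the input
    contains non-finite observed entries or if every start diverges.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 3:
        raise ValueError("X must be a third-order array")
    Wb = None
    if mask is not None:
        Wb = np.asarray(mask)
        if Wb.shape != X.shape:
            raise ValueError("mask shape must match X")
    check = X if Wb is None else X[Wb.astype(bool)]
    if not np.isfinite(check).all():
        raise ValueError("non-finite entries in X at observed positions")

    R = opts.n_components
    streams = np.random.SeedSequence(opts.seed).spawn(opts.n_starts)
    best_obj, best_factors, best_hist = np.inf, None, None
    for s, stream in enumerate(streams):
        if s == 0:
            init = _hosvd_init(X, R, opts.nonneg_modes, opts.orth_modes, Wb)
        else:
            rng = np.random.default_rng(stream)
            init = _init_factors(X.shape, R, opts.nonneg_modes, opts.orth_modes, rng)
        factors, hist = _als(
            X, R, init, mask, set(opts.nonneg_modes), set(opts.orth_modes),
            opts.max_iters, opts.tol,
        )
        if hist.size and np.isfinite(hist[-1]) and hist[-1] < best_obj:
            best_obj, best_factors, best_hist = hist[-1], factors, hist
    if best_factors is None:
        raise RuntimeError("all CP starts diverged")

    weights, A, B, C = _normalize(best_factors, set(opts.nonneg_modes))
    model = CPDecomposition(
        weights=weights, A=A, B=B, C=C,
        objective=best_obj, objective_history=best_hist,
    )
    model.fit = fit_percent(X, model.reconstruct(), mask)
    return model
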
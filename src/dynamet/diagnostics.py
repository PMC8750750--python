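"""Model-selection diagnostics for CP/Paralind fits.

Implemented metrics:

* **explained fit** — percentage of the (preprocessed) data's squared norm
  captured by the model (see :func:`dynamet.cp.fit_percent`);
* **core consistency (CC)** — how superdiagonal the least-squares Tucker
  core computed from the fixed CP factors is; ~100 for an appropriate number
  of components, collapsing (possibly below zero) when overfactored;
* **Tucker's congruence coefficient (TC)** — the product over modes of the
  cosine similarities of two components; an off-diagonal value near -1 flags
  a two-factor degeneracy;
* **subject-mode similarity C12** — cosine similarity of the first two
  subject-mode components; |C12| ~ 1 reveals rank deficiency in that mode
  and motivates a Paralind model;
* **tensor completion score (TCS)** — relative reconstruction error on
  deliberately held-out entries, the cross-validation test error used to
  compare candidate models, with a paired t-test across replicates sharing
  their missing patterns.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._tensor_ops import cp_tensor
from .cp import CPDecomposition, FitOptions, fit_cp, fit_percent
from .paralind import ParalindDecomposition, dependency_matrix, fit_paralind
from .preprocess import preprocess
from .synthetic_data import add_noise, make_missing_mask

__all__ = [
    "DiagnosticsReport",
    "ModelSpec",
    "core_consistency",
    "congruence_matrix",
    "max_congruence",
    "cosine_similarity",
    "tcs",
    "crossval_compare",
]

# Signed-TC threshold below which we flag a two-factor degeneracy ("close to
# -1"). The flag is advisory; the raw TC value is always reported alongside.
DEGENERACY_TC_THRESHOLD = -0.85


def cosine_similarity(u: np.ndarray, v: np.ndarray) -> float:
    """Cosine of the angle between two nonzero vectors, in [-1, 1]."""
    u = np.asarray(u, float).ravel()
    v = np.asarray(v, float).ravel()
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("cosine similarity undefined for a zero vector")
    return float(np.clip(u @ v / (nu * nv), -1.0, 1.0))


def congruence_matrix(model) -> np.ndarray:
    """R x R matrix of Tucker congruence coefficients between components.

    Entry (i, j) is the product over the three modes of the cosine
    similarities of components i and j; symmetric with unit diagonal.
    ``model`` is any object exposing CP-style factors (Paralind models
    contribute their effective subjects factor).
    """
    A = model.effective_A if hasattr(model, "effective_A") else model.A
    TC = np.ones((A.shape[1],) * 2)
    for F in (A, model.B, model.C):
        norms = np.linalg.norm(F, axis=0)
        if np.any(norms == 0):
            raise ValueError("zero-norm factor column; congruence undefined")
        Fn = F / norms
        TC *= Fn.T @ Fn
    return TC


def max_congruence(model) -> tuple[float, tuple[int, int]]:
    """The signed off-diagonal TC of largest magnitude and its (i, j) index."""
    TC = congruence_matrix(model)
    R = TC.shape[0]
    if R < 2:
        return 0.0, (0, 0)
    off = np.abs(TC)
    np.fill_diagonal(off, -np.inf)
    i, j = np.unravel_index(np.argmax(off), off.shape)
    return float(TC[i, j]), (int(i), int(j))


def core_consistency(X: np.ndarray, model: CPDecomposition) -> float:
    """Core consistency of a fitted CP model, as a percentage (<= 100).

    The least-squares Tucker core G (R x R x R) is solved for the fixed CP
    factors, with the weights folded into the subjects factor so that the
    ideal core is the superdiagonal array of ones T. Then

        CC = 100 * (1 - sum((G - T)^2) / R),

    the denominator being sum(T^2) = R. 100 means the CP structure fully
    explains the interactions; large negative values mean the factors
    interact far beyond a trilinear model (too many components).
    """
    X = np.asarray(X, float)
    R = model.n_components
    A = model.A * model.weights[None, :]
    mats = []
    for F in (A, model.B, model.C):
        if np.linalg.matrix_rank(F) < R:
            raise ValueError(
                "rank-deficient factor matrix: Tucker core solve is ill-posed"
            )
        mats.append(np.linalg.pinv(F))
    G = np.einsum("pi,qj,rk,ijk->pqr", mats[0], mats[1], mats[2], X,
                  optimize=True)
    T = np.zeros((R, R, R))
    T[np.arange(R), np.arange(R), np.arange(R)] = 1.0
    return float(100.0 * (1.0 - np.sum((G - T) ** 2) / R))


def tcs(X_noise: np.ndarray, X_hat: np.ndarray, W: np.ndarray) -> float:
    """Tensor completion score: relative error restricted to missing entries.

    TCS = ||(1-W) * (X_hat - X_noise)|| / ||(1-W) * X_noise||. Requires at
    least one missing entry and a nonzero denominator; lower is better.
    """
    X_noise = np.asarray(X_noise, float)
    X_hat = np.asarray(X_hat, float)
    W = np.asarray(W)
    if W.shape != X_noise.shape or X_hat.shape != X_noise.shape:
        raise ValueError("shape mismatch")
    missing = ~W.astype(bool)
    if not missing.any():
        raise ValueError("TCS undefined: no missing entries")
    denom = np.linalg.norm(X_noise[missing])
    if denom == 0:
        raise ValueError("TCS undefined: held-out entries all zero")
    return float(np.linalg.norm((X_hat - X_noise)[missing]) / denom)


# --------------------------------------------------------------------------
# candidate models and the cross-validation comparison
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelSpec:
    """A candidate model for the selection/cross-validation machinery.

    ``kind`` is "cp" or "paralind"; Paralind additionally needs the basis
    count ``S`` and the 1-based component grouping pattern (defaults to all
    components sharing one basis).
    """

    kind: str
    R: int
    S: int | None = None
    groups: tuple[int, ...] | None = None
    n_starts: int = 20
    max_iters: int = 10_000
    tol: float = 1e-10

    def __post_init__(self) -> None:
        if self.kind not in ("cp", "paralind"):
            raise ValueError("kind must be 'cp' or 'paralind'")
        if self.kind == "paralind":
            S = self.S if self.S is not None else 1
            groups = self.groups if self.groups is not None else (1,) * self.R
            object.__setattr__(self, "S", S)
            object.__setattr__(self, "groups", tuple(groups))

    @property
    def label(self) -> str:
        if self.kind == "cp":
            return f"CP(R={self.R})"
        return f"Paralind({self.S},{self.R},{self.R})"

    def fit(self, X: np.ndarray, seed: int, mask: np.ndarray | None = None):
        if self.kind == "cp":
            opts = FitOptions(
                n_components=self.R, n_starts=self.n_starts,
                max_iters=self.max_iters, tol=self.tol, seed=seed,
            )
            return fit_cp(X, opts, mask=mask)
        opts = FitOptions(
            n_components=self.R, n_starts=self.n_starts,
            max_iters=self.max_iters, tol=self.tol, seed=seed,
            orth_modes=(1,), nonneg_modes=(2,),
        )
        H = dependency_matrix(self.S, self.R, self.groups)
        return fit_paralind(X, self.S, self.R, H, opts, mask=mask)


@dataclass
class DiagnosticsReport:
    """Bundle of model-selection metrics for one fitted model / comparison."""

    fit: float | None = None
    core_consistency: float | None = None
    tc: float | None = None
    tc_index: tuple[int, int] | None = None
    degenerate: bool | None = None
    c12: float | None = None
    tcs_values: dict[str, list[float]] = field(default_factory=dict)
    paired_p: float | None = None

    def to_dict(self) -> dict:
        return {
            "fit_percent": self.fit,
            "core_consistency": self.core_consistency,
            "tc": self.tc,
            "tc_index": list(self.tc_index) if self.tc_index else None,
            "degenerate": self.degenerate,
            "c12": self.c12,
            "tcs_values": self.tcs_values,
            "paired_t_p_value": self.paired_p,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def tcs_table(self) -> pd.DataFrame:
        rows = [
            {"replicate": i + 1, "model": label, "TCS": v}
            for label, values in self.tcs_values.items()
            for i, v in enumerate(values)
        ]
        return pd.DataFrame(rows, columns=["replicate", "model", "TCS"])


def crossval_compare(
    X: np.ndarray,
    model_specs: Sequence[ModelSpec],
    eta: float = 0.3,
    missing_fraction: float = 0.2,
    n_reps: int = 20,
    seed: int = 0,
) -> DiagnosticsReport:
    """Missing-data cross-validation comparison of candidate models.

    Each replicate adds Gaussian noise at relative level ``eta`` to the raw
    cohort tensor ``X``, hides ``missing_fraction`` of the entries (the same
    pattern for every model, so the scores are paired), preprocesses the
    masked noisy data (statistics from observed entries only), fits every
    candidate on the preprocessed scale with the mask, back-transforms the
    reconstruction to the original scale, and scores it at the hidden
    entries with the TCS against the noisy data. The paired two-sided t-test
    compares the first two candidates across replicates.

    Deterministic given ``seed``. A replicate aborted by a fit failure is
    logged as a warning; fewer than ``n_reps`` completions raise.
    """
    if len(model_specs) < 2:
        raise ValueError("need at least two model specs to compare")
    if eta < 0:
        raise ValueError("eta must be >= 0")
    X = np.asarray(X, float)
    labels: list[str] = []
    for m in model_specs:           # disambiguate duplicate candidate labels
        label = m.label
        while label in labels:
            label += "'"
        labels.append(label)
    scores: dict[str, list[float]] = {label: [] for label in labels}
    rep_seqs = np.random.SeedSequence(seed).spawn(n_reps)
    completed = 0
    for rep, rseq in enumerate(rep_seqs):
        noise_seq, mask_seq, fit_seq = rseq.spawn(3)
        X_noise = add_noise(X, eta, np.random.default_rng(noise_seq))
        W = make_missing_mask(X.shape, missing_fraction,
                              np.random.default_rng(mask_seq))
        fit_seed = int(fit_seq.generate_state(1)[0] % (2**31))
        try:
            X_pp, state = preprocess(X_noise, mask=W)
            rep_scores = {}
            for label, m in zip(labels, model_specs):
                model = m.fit(X_pp, seed=fit_seed, mask=W)
                X_hat = state.invert(model.reconstruct())
                rep_scores[label] = tcs(X_noise, X_hat, W)
        except Exception as exc:  # noqa: BLE001 - skip failed replicate
            warnings.warn(f"cross-validation replicate {rep + 1} failed: {exc}",
                          stacklevel=2)
            continue
        for label, value in rep_scores.items():
            scores[label].append(value)
        completed += 1
    if completed < n_reps:
        raise RuntimeError(
            f"only {completed}/{n_reps} cross-validation replicates completed"
        )
    first, second = labels[0], labels[1]
    diffs = np.asarray(scores[first]) - np.asarray(scores[second])
    if np.allclose(diffs, 0):
        p = 1.0
    else:
        p = float(stats.ttest_rel(scores[first], scores[second]).pvalue)
    return DiagnosticsReport(tcs_values={k: list(v) for k, v in scores.items()},
                             paired_p=p)
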
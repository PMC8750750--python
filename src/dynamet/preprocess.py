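"""Two-step tensor preprocessing: center across subjects, scale within metabolites.

Centering removes, for every (metabolite, time) pair, the mean over subjects,
so the factorizations model between-subject variation rather than the grand
temporal profile. Scaling divides every metabolite's horizontal slice by its
root-mean-square value so that metabolites measured on different concentration
ranges contribute comparably. Because scaling multiplies whole slices by
constants, it leaves the subject-mode means at zero — one pass suffices.

All statistics honour an optional observation mask: means and RMS values are
computed over observed entries only, while the affine transform itself is
applied to every entry (so held-out entries end up on the same scale as the
fitted model's reconstruction).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PreprocessState",
    "center_across_subjects",
    "scale_within_metabolites",
    "preprocess",
]


@dataclass
class PreprocessState:
    """Offsets (J x K subject-mode means) and scales (per-metabolite RMS)."""

    offsets: np.ndarray
    scales: np.ndarray

    def __post_init__(self) -> None:
        self.offsets = np.asarray(self.offsets, dtype=float)
        self.scales = np.asarray(self.scales, dtype=float)
        if np.any(self.scales <= 0):
            raise ValueError("scales must be strictly positive")

    def apply(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, float) - self.offsets[None]) / self.scales[None, :, None]

    def invert(self, X_pp: np.ndarray) -> np.ndarray:
        return np.asarray(X_pp, float) * self.scales[None, :, None] + self.offsets[None]

    def save(self, offsets_path, scales_path) -> None:
        np.savetxt(offsets_path, self.offsets, delimiter="\t")
        np.savetxt(scales_path, self.scales[None], delimiter="\t")

    @staticmethod
    def load(offsets_path, scales_path) -> "PreprocessState":
        return PreprocessState(
            offsets=np.loadtxt(offsets_path, delimiter="\t", ndmin=2),
            scales=np.loadtxt(scales_path, delimiter="\t", ndmin=2).ravel(),
        )


def _as_bool_mask(X: np.ndarray, mask: np.ndarray | None) -> np.ndarray:
    if mask is None:
        return np.ones(X.shape, dtype=bool)
    mask = np.asarray(mask)
    if mask.shape != X.shape:
        raise ValueError("mask shape must match tensor shape")
    return mask.astype(bool)


def center_across_subjects(
    X: np.ndarray, mask: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Subtract, per (metabolite, time) fiber, the mean over observed subjects.

    Returns the centered tensor (all entries shifted, statistics from observed
    entries only) and the J x K offset table. A fiber with no observed subject
    has no defined mean and raises.
    """
    X = np.asarray(X, dtype=float)
    W = _as_bool_mask(X, mask)
    counts = W.sum(axis=0)
    if np.any(counts == 0):
        j, k = np.argwhere(counts == 0)[0]
        raise ValueError(f"fiber (metabolite {j}, time {k}) is fully missing")
    offsets = np.where(W, X, 0.0).sum(axis=0) / counts
    return X - offsets[None], offsets


def scale_within_metabolites(
    X: np.ndarray, mask: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Divide each metabolite slice by its RMS over observed entries.

    Returns the scaled tensor and the length-J scale vector. A slice whose
    observed entries are all zero cannot be scaled and raises.
    """
    X = np.asarray(X, dtype=float)
    W = _as_bool_mask(X, mask)
    counts = W.sum(axis=(0, 2))
    if np.any(counts == 0):
        raise ValueError(
            f"metabolite slice {int(np.flatnonzero(counts == 0)[0])} is fully missing"
        )
    sumsq = np.where(W, X * X, 0.0).sum(axis=(0, 2))
    scales = np.sqrt(sumsq / counts)
    # a slice that is zero up to rounding noise of the original data carries
    # no information to scale; compare against the tensor-wide RMS
    tiny = 1e-12 * np.sqrt(sumsq.sum() / counts.sum())
    if np.any(scales <= tiny):
        j = int(np.flatnonzero(scales <= tiny)[0])
        raise ValueError(f"metabolite slice {j} has zero RMS; cannot scale")
    return X / scales[None, :, None], scales


def preprocess(
    X: np.ndarray, mask: np.ndarray | None = None
) -> tuple[np.ndarray, PreprocessState]:
    """Center across subjects, then scale within metabolites.

    The returned :class:`PreprocessState` reproduces the transform on new
    data (``apply``) and undoes it (``invert``).
    """
    Xc, offsets = center_across_subjects(X, mask)
    Xs, scales = scale_within_metabolites(Xc, mask)
    return Xs, PreprocessState(offsets=offsets, scales=scales)
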
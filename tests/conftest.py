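"""Shared fixtures: reference cohorts and small planted-factor tensors."""

from __future__ import annotations

import numpy as np
import pytest

import dynamet as dm


def linear_cohort_config(beta: float, seed: int) -> dm.CohortConfig:
    """Two groups of 10: normal vs. 50% knock-down of the A(7,6) rate."""
    return dm.CohortConfig(
        groups=(
            dm.GroupSpec("normal", 10, dm.VariationSpec(beta=beta)),
            dm.GroupSpec(
                "abnormal_A(7,6)", 10,
                dm.VariationSpec(beta=beta, induced=(("A(7,6)", 0.5),)),
            ),
        ),
        time_grid=dm.linear_time_grid(),
        seed=seed,
    )


@pytest.fixture(scope="session")
def linear_system() -> dm.LinearSystemSpec:
    return dm.default_linear_system()


@pytest.fixture(scope="session")
def b001_cohort(linear_system) -> dm.MetabolomicsTensor:
    """One beta=0.01 one-induced-source cohort (seed 1)."""
    return dm.generate_cohort(linear_cohort_config(0.01, seed=1), linear_system)


@pytest.fixture(scope="session")
def b001_preprocessed(b001_cohort) -> np.ndarray:
    X_pp, _ = dm.preprocess(b001_cohort.values)
    return X_pp


def planted_cp(shape=(8, 6, 5), R=2, seed=0, nonneg_time=True):
    """A noiseless tensor with known well-separated CP factors."""
    rng = np.random.default_rng(seed)
    A = rng.standard_normal((shape[0], R))
    B = rng.standard_normal((shape[1], R))
    C = np.abs(rng.standard_normal((shape[2], R))) if nonneg_time \
        else rng.standard_normal((shape[2], R))
    # orthogonalize a touch so components are well separated
    A = np.linalg.qr(A)[0] + 0.1 * rng.standard_normal((shape[0], R))
    weights = np.array([3.0, 2.0, 1.5, 1.2][:R])
    X = np.einsum("r,ir,jr,kr->ijk", weights, A, B, C)
    return X, (weights, A, B, C)


@pytest.fixture()
def planted_rank2():
    return planted_cp()
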
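"""Fit/CC/TC/C12/TCS metrics and the cross-validation comparison."""

import numpy as np
import pytest

import dynamet as dm
from dynamet.cp import CPDecomposition, FitOptions
from dynamet.diagnostics import ModelSpec

from conftest import planted_cp


def random_model(seed, R=3, dims=(6, 5, 4)):
    rng = np.random.default_rng(seed)
    return CPDecomposition(
        rng.normal(size=R),
        *(rng.normal(size=(n, R)) for n in dims),
    )


class TestCosine:
    def test_identities(self):
        u = np.array([1.0, 2.0, -0.5])
        assert dm.cosine_similarity(u, u) == pytest.approx(1.0)
        assert dm.cosine_similarity(u, -u) == pytest.approx(-1.0)

    def test_hand_value(self):
        assert dm.cosine_similarity([1, 0], [1, 1]) == pytest.approx(1 / np.sqrt(2))

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            dm.cosine_similarity([0, 0], [1, 0])


class TestCongruence:
    def test_duplicate_component_gives_unit_offdiagonal(self):
        rng = np.random.default_rng(0)
        a, b, c = (rng.normal(size=(n, 1)) for n in (4, 3, 5))
        m = CPDecomposition(np.ones(2), np.hstack([a, a]), np.hstack([b, b]),
                            np.hstack([c, c]))
        TC = dm.congruence_matrix(m)
        assert TC[0, 1] == pytest.approx(1.0)

    def test_orthogonal_in_one_mode_gives_zero(self):
        rng = np.random.default_rng(1)
        A = np.array([[1.0, 0.0], [0.0, 1.0], [0.0, 0.0]])  # orthogonal columns
        B, C = (rng.normal(size=(n, 2)) for n in (3, 5))
        TC = dm.congruence_matrix(CPDecomposition(np.ones(2), A, B, C))
        assert TC[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_matches_triple_product_oracle(self):
        m = random_model(2)
        TC = dm.congruence_matrix(m)
        R = m.n_components
        for i in range(R):
            for j in range(R):
                expected = 1.0
                for F in (m.A, m.B, m.C):
                    expected *= (F[:, i] @ F[:, j]) / (
                        np.linalg.norm(F[:, i]) * np.linalg.norm(F[:, j]))
                assert TC[i, j] == pytest.approx(expected, abs=1e-12)
        np.testing.assert_allclose(TC, TC.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(TC), 1.0, atol=1e-12)

    def test_max_congruence_reports_extreme_pair(self):
        m = random_model(3)
        tc, (i, j) = dm.max_congruence(m)
        TC = dm.congruence_matrix(m)
        off = np.abs(TC.copy())
        np.fill_diagonal(off, -np.inf)
        assert abs(tc) == pytest.approx(off.max())
        assert abs(TC[i, j]) == pytest.approx(off.max())


class TestCoreConsistency:
    def test_one_component_fit_is_100(self):
        for seed in range(3):
            X = np.random.default_rng(seed).normal(size=(5, 4, 6))
            m = dm.fit_cp(X, FitOptions(n_components=1, n_starts=2, seed=0,
                                        nonneg_modes=()))
            assert dm.core_consistency(X, m) == pytest.approx(100.0, abs=1e-6)

    def test_exact_rank_two_fit_is_100(self, planted_rank2):
        X, _ = planted_rank2
        m = dm.fit_cp(X, FitOptions(n_components=2, n_starts=4, seed=0))
        assert dm.core_consistency(X, m) == pytest.approx(100.0, abs=1e-4)

    def test_rank_deficient_factors_rejected(self):
        X = np.random.default_rng(0).normal(size=(4, 4, 4))
        a = np.random.default_rng(1).normal(size=(4, 1))
        m = CPDecomposition(np.ones(2), np.hstack([a, a]),
                            np.random.default_rng(2).normal(size=(4, 2)),
                            np.random.default_rng(3).normal(size=(4, 2)))
        with pytest.raises(ValueError, match="ill-posed"):
            dm.core_consistency(X, m)

    def test_overfactored_model_collapses(self, b001_preprocessed):
        m = dm.fit_cp(b001_preprocessed,
                      FitOptions(n_components=3, n_starts=4, seed=0))
        assert dm.core_consistency(b001_preprocessed, m) < 50.0


class TestTCS:
    def test_identities_and_toy_value(self):
        X = np.random.default_rng(0).normal(size=(3, 2, 2))
        W = np.ones_like(X)
        W[0, 0, 0] = 0
        assert dm.tcs(X, X, W) == pytest.approx(0.0)
        assert dm.tcs(X, np.zeros_like(X), W) == pytest.approx(1.0)
        # 2x1x1 fiber, missing entry has value 2, estimated as 1
        Xn = np.array([3.0, 2.0]).reshape(2, 1, 1)
        Xh = np.array([9.9, 1.0]).reshape(2, 1, 1)
        Wt = np.array([1, 0]).reshape(2, 1, 1)
        assert dm.tcs(Xn, Xh, Wt) == pytest.approx(0.5)

    def test_invariant_to_observed_entries(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(4, 3, 3))
        X_hat = rng.normal(size=(4, 3, 3))
        W = dm.make_missing_mask(X.shape, 0.3, rng)
        score = dm.tcs(X, X_hat, W)
        X_hat2 = X_hat + np.where(W.astype(bool), rng.normal(size=X.shape), 0.0)
        assert dm.tcs(X, X_hat2, W) == pytest.approx(score, rel=1e-12)

    def test_requires_missing_entries(self):
        X = np.ones((2, 2, 2))
        with pytest.raises(ValueError):
            dm.tcs(X, X, np.ones_like(X))


class TestCrossval:
    def test_identical_specs_give_p_one(self, planted_rank2):
        X, _ = planted_rank2
        spec = ModelSpec("cp", 2, n_starts=2, tol=1e-8)
        rep = dm.crossval_compare(X, [spec, spec], eta=0.1,
                                  missing_fraction=0.2, n_reps=3, seed=0)
        labels = list(rep.tcs_values)
        assert len(labels) == 2
        assert rep.tcs_values[labels[0]] == rep.tcs_values[labels[1]]
        assert rep.paired_p == pytest.approx(1.0)

    def test_seeded_determinism(self, planted_rank2):
        X, _ = planted_rank2
        specs = [ModelSpec("cp", 2, n_starts=2, tol=1e-8),
                 ModelSpec("paralind", 2, S=1, n_starts=2, tol=1e-8)]
        r1 = dm.crossval_compare(X, specs, eta=0.2, missing_fraction=0.2,
                                 n_reps=4, seed=5)
        r2 = dm.crossval_compare(X, specs, eta=0.2, missing_fraction=0.2,
                                 n_reps=4, seed=5)
        assert r1.tcs_values == r2.tcs_values
        assert r1.paired_p == r2.paired_p

    def test_true_model_beats_overfactored(self):
        X, _ = planted_cp(shape=(10, 8, 6), R=2, seed=7)
        specs = [ModelSpec("cp", 2, n_starts=2, tol=1e-8),
                 ModelSpec("cp", 4, n_starts=2, tol=1e-8)]
        rep = dm.crossval_compare(X, specs, eta=0.1, missing_fraction=0.2,
                                  n_reps=10, seed=3)
        true_s = np.array(rep.tcs_values["CP(R=2)"])
        over_s = np.array(rep.tcs_values["CP(R=4)"])
        assert (true_s <= over_s).sum() >= 7

    def test_report_serialization(self, planted_rank2, tmp_path):
        X, _ = planted_rank2
        specs = [ModelSpec("cp", 1, n_starts=2, tol=1e-8),
                 ModelSpec("cp", 2, n_starts=2, tol=1e-8)]
        rep = dm.crossval_compare(X, specs, eta=0.2, missing_fraction=0.2,
                                  n_reps=3, seed=1)
        rep.to_json(tmp_path / "report.json")
        import json

        loaded = json.loads((tmp_path / "report.json").read_text())
        assert set(loaded["tcs_values"]) == {"CP(R=1)", "CP(R=2)"}
        table = rep.tcs_table()
        assert len(table) == 6
        assert set(table.columns) == {"replicate", "model", "TCS"}
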
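"""Kinetic systems, variation operators, simulation and cohort assembly."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import dynamet as dm
from dynamet.synthetic_data import _MODEL_REGISTRY

from conftest import linear_cohort_config


def toy_two_metabolite_system() -> dm.KineticSystem:
    """Minimal nonlinear plug-in model: influx, conversion, first-order efflux."""

    def rhs(x, p):
        return np.array([
            p["vin"] - p["k1"] * x[0],
            p["k1"] * x[0] - p["kout"] * x[1] ** 2 / (1 + x[1]),
        ])

    return dm.KineticSystem(rhs=rhs, params={"vin": 1.0, "k1": 2.0, "kout": 3.0},
                            x0=np.array([0.5, 0.5]), metabolite_names=("X1", "X2"))


class TestLinearSystem:
    def test_printed_rate_matrix_entries(self, linear_system):
        A = linear_system.A
        assert A[1, 0] == pytest.approx(200.0)
        assert A[0, 1] == pytest.approx(300.0)
        assert linear_system.b[0] == pytest.approx(100.0)
        assert A[10, 10] == -1000.0

    def test_mass_conservation_and_tridiagonality(self, linear_system):
        A = linear_system.A
        np.testing.assert_allclose(A.sum(axis=0)[:10], 0.0, atol=1e-9)
        off = np.abs(np.subtract.outer(np.arange(11), np.arange(11))) > 1
        assert np.all(A[off] == 0)

    def test_degenerate_variant_matches_printed_diagonal(self):
        A = dm.degenerate_linear_system().A
        np.testing.assert_allclose(np.diag(A), 1e3 * np.r_[-1, [-2] * 10])
        np.testing.assert_allclose(np.diag(A, 1), 1e3)
        np.testing.assert_allclose(np.diag(A, -1), 1e3)

    def test_rejects_nonpositive_rates(self):
        spec = dm.default_linear_system()
        with pytest.raises(ValueError):
            dm.LinearSystemSpec(sub=-spec.sub, sup=spec.sup, b=spec.b, x0=spec.x0)


class TestPerturbation:
    def test_zero_beta_is_identity(self, linear_system):
        rng = np.random.default_rng(0)
        out = dm.perturb_parameters(linear_system, 0.0, rng)
        np.testing.assert_array_equal(out.A, linear_system.A)

    def test_negative_beta_rejected(self, linear_system):
        with pytest.raises(ValueError):
            dm.perturb_parameters(linear_system, -0.1, np.random.default_rng(0))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(beta=st.floats(1e-4, 0.3), seed=st.integers(0, 2**31 - 1))
    def test_relative_bound_and_mass_constraint(self, beta, seed):
        spec = dm.default_linear_system()
        out = dm.perturb_parameters(spec, beta, np.random.default_rng(seed))
        rel_sub = np.abs(out.sub / spec.sub - 1)
        rel_sup = np.abs(out.sup / spec.sup - 1)
        assert rel_sub.max() <= beta and rel_sup.max() <= beta
        np.testing.assert_allclose(out.A.sum(axis=0)[:10], 0.0, atol=1e-9)
        assert out.A[10, 10] == -1000.0

    def test_generic_system_perturbs_every_parameter(self):
        sys0 = toy_two_metabolite_system()
        out = dm.perturb_parameters(sys0, 0.1, np.random.default_rng(3))
        for k in sys0.params:
            assert out.params[k] != sys0.params[k]
            assert abs(out.params[k] / sys0.params[k] - 1) <= 0.1


class TestInducedVariation:
    def test_halving_a76(self, linear_system):
        out = dm.apply_induced_variation(linear_system, "A(7,6)", 0.5)
        assert out.A[6, 5] == pytest.approx(500.0)
        np.testing.assert_allclose(out.A.sum(axis=0)[:10], 0.0, atol=1e-9)

    def test_zero_alpha_is_identity(self, linear_system):
        out = dm.apply_induced_variation(linear_system, "A(7,6)", 0.0)
        np.testing.assert_array_equal(out.A, linear_system.A)

    @pytest.mark.parametrize("param", ["A(1,1)", "A(3,7)", "q", "A(99,98)"])
    def test_unknown_parameter_rejected(self, linear_system, param):
        with pytest.raises(KeyError):
            dm.apply_induced_variation(linear_system, param, 0.5)

    def test_generic_system_param(self):
        out = dm.apply_induced_variation(toy_two_metabolite_system(), "k1", 0.25)
        assert out.params["k1"] == pytest.approx(1.5)


class TestSimulation:
    def test_initial_state(self, linear_system):
        # smallest valid grid containing t=0
        traj = dm.simulate(linear_system, [0.0, 1e-9])
        np.testing.assert_allclose(traj[:, 0], np.ones(11))

    def test_matches_independent_stiff_integrator(self, linear_system):
        """Closed-form linear solution vs. an LSODA run through the plug-in path."""
        A, b = linear_system.A, linear_system.b
        generic = dm.KineticSystem(
            rhs=lambda x, p: A @ x + b, params={"dummy": 1.0},
            x0=linear_system.x0, metabolite_names=linear_system.metabolite_names,
        )
        grid = dm.linear_time_grid()
        closed = dm.simulate(linear_system, grid)
        numeric = dm.simulate(generic, grid)
        np.testing.assert_allclose(closed, numeric, rtol=1e-6)

    def test_long_time_reaches_steady_state(self, linear_system):
        x_ss = np.linalg.solve(linear_system.A, -linear_system.b)
        # ten times the slowest time constant of the rate matrix
        tau = 1.0 / np.abs(np.linalg.eigvals(linear_system.A).real).min()
        traj = dm.simulate(linear_system, [10.0 * tau])
        np.testing.assert_allclose(traj[:, 0], x_ss, rtol=1e-4)
        np.testing.assert_allclose(dm.steady_state(linear_system), x_ss, rtol=1e-12)

    def test_decreasing_times_rejected(self, linear_system):
        with pytest.raises(ValueError):
            dm.simulate(linear_system, [0.2, 0.1])


class TestTimeGrids:
    def test_linear_grid(self):
        grid = dm.linear_time_grid()
        assert grid[0] == pytest.approx(0.012)
        assert grid[-1] == pytest.approx(0.202)
        assert len(grid) == 20
        np.testing.assert_allclose(np.diff(grid), 0.01)

    def test_cholesterol_grid(self):
        grid = dm.cholesterol_time_grid()
        assert grid[0] == pytest.approx(0.0)
        assert len(grid) == 21
        assert np.all(np.diff(grid) > 0)
        # second picked point is the 25th of logspace(0, 6, 1000) - 1
        assert grid[1] == pytest.approx(10 ** (6 * 24 / 999) - 1)


class TestCohort:
    def test_shape_and_labels(self, b001_cohort):
        assert b001_cohort.shape == (20, 11, 20)
        assert b001_cohort.subject_groups[:10] == ("normal",) * 10
        assert b001_cohort.subject_groups[10:] == ("abnormal_A(7,6)",) * 10
        assert b001_cohort.metabolite_names[0] == "M1"

    def test_seeded_determinism(self, linear_system):
        cfg = linear_cohort_config(0.01, seed=7)
        t1 = dm.generate_cohort(cfg, linear_system)
        t2 = dm.generate_cohort(cfg, linear_system)
        np.testing.assert_array_equal(t1.values, t2.values)

    def test_beta_zero_gives_identical_subjects_within_group(self, linear_system):
        cfg = linear_cohort_config(0.0, seed=3)
        t = dm.generate_cohort(cfg, linear_system)
        for g in (slice(0, 10), slice(10, 20)):
            np.testing.assert_array_equal(t.values[g], np.broadcast_to(
                t.values[g][0], t.values[g].shape))
        assert not np.allclose(t.values[0], t.values[10])

    def test_appending_a_group_preserves_earlier_subjects(self, linear_system):
        base = linear_cohort_config(0.05, seed=11)
        extended = dm.CohortConfig(
            groups=base.groups + (dm.GroupSpec("extra", 3, dm.VariationSpec(0.05)),),
            time_grid=base.time_grid, seed=base.seed,
        )
        t_base = dm.generate_cohort(base, linear_system)
        t_ext = dm.generate_cohort(extended, linear_system)
        np.testing.assert_array_equal(t_ext.values[:20], t_base.values)

    def test_config_roundtrip_through_yaml(self, tmp_path, linear_system):
        cfg = linear_cohort_config(0.01, seed=5)
        path = tmp_path / "cohort.yaml"
        import yaml

        path.write_text(yaml.safe_dump(cfg.to_dict()))
        loaded = dm.CohortConfig.from_yaml(path)
        np.testing.assert_array_equal(
            dm.generate_cohort(loaded, linear_system).values,
            dm.generate_cohort(cfg, linear_system).values,
        )

    def test_tensor_io_roundtrip(self, tmp_path, b001_cohort):
        path = tmp_path / "tensor.h5"
        b001_cohort.save(path)
        loaded = dm.MetabolomicsTensor.load(path)
        np.testing.assert_array_equal(loaded.values, b001_cohort.values)
        assert loaded.subject_groups == b001_cohort.subject_groups
        df = b001_cohort.to_long_dataframe()
        assert len(df) == 20 * 11 * 20
        assert df["value"].iloc[0] == b001_cohort.values[0, 0, 0]

    def test_steady_state_initialization_flag(self):
        sys0 = toy_two_metabolite_system()
        cfg = dm.CohortConfig(
            groups=(dm.GroupSpec("mutant", 2, dm.VariationSpec(
                beta=0.0, induced=(("k1", 0.5),), init_from_steady_state=True)),),
            time_grid=np.array([0.01, 0.1, 1.0]), seed=0,
        )
        t = dm.generate_cohort(cfg, sys0)
        x_ss = dm.steady_state(sys0)
        # trajectories launch from the normal steady state, not x0
        assert np.allclose(t.values[0, :, 0], x_ss, rtol=1e-2)
        assert not np.allclose(x_ss, sys0.x0)


class TestNoiseAndMask:
    def test_zero_eta_returns_copy(self):
        X = np.random.default_rng(0).normal(size=(4, 3, 2))
        out = dm.add_noise(X, 0.0, np.random.default_rng(1))
        np.testing.assert_array_equal(out, X)
        assert out is not X

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(eta=st.floats(1e-6, 2.0), seed=st.integers(0, 2**31 - 1))
    def test_exact_relative_noise_norm(self, eta, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(5, 4, 3)) + 1.0
        out = dm.add_noise(X, eta, rng)
        ratio = np.linalg.norm(out - X) / np.linalg.norm(X)
        assert ratio == pytest.approx(eta, rel=1e-12)

    def test_zero_tensor_unchanged(self):
        out = dm.add_noise(np.zeros((2, 2, 2)), 0.5, np.random.default_rng(0))
        np.testing.assert_array_equal(out, 0.0)

    def test_mask_counts_and_determinism(self):
        W1 = dm.make_missing_mask((20, 11, 20), 0.2, np.random.default_rng(9))
        W2 = dm.make_missing_mask((20, 11, 20), 0.2, np.random.default_rng(9))
        assert (W1 == 0).sum() == 880
        np.testing.assert_array_equal(W1, W2)
        W0 = dm.make_missing_mask((3, 3, 3), 0.0, np.random.default_rng(0))
        assert W0.all()


class TestRegistry:
    def test_builtin_models(self):
        assert set(dm.available_kinetic_models()) >= {"linear", "linear_degenerate"}
        assert isinstance(dm.get_kinetic_model("linear"), dm.LinearSystemSpec)

    def test_register_and_run_plugin(self):
        dm.register_kinetic_model("toy2", toy_two_metabolite_system)
        try:
            sys0 = dm.get_kinetic_model("toy2")
            traj = dm.simulate(sys0, dm.cholesterol_time_grid()[1:6])
            assert traj.shape == (2, 5)
            assert np.isfinite(traj).all()
        finally:
            _MODEL_REGISTRY.pop("toy2", None)

    def test_unknown_model_errors(self):
        with pytest.raises(KeyError, match="linear"):
            dm.get_kinetic_model("glycolysis")
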
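import numpy as np
import pytest

import stmix as sx
from stmix.synthetic import _icar_draw, _rw1_draw, default_populations


class TestLattice:
    @pytest.mark.parametrize("rows,cols", [(2, 2), (3, 5), (1, 4), (8, 8)])
    def test_edge_count_formula(self, rows, cols):
        g = sx.make_lattice(rows, cols)
        assert g.I == rows * cols
        assert len(g.edges) == rows * (cols - 1) + cols * (rows - 1)

    def test_degree_distribution(self):
        g = sx.make_lattice(3, 4)
        deg = np.sort(g.n_neighbors)
        # 4 corners of degree 2, 6 border nodes of degree 3, 2 interior of 4
        assert np.array_equal(deg, [2] * 4 + [3] * 6 + [4] * 2)

    def test_single_cell_rejected(self):
        with pytest.raises(ValueError, match="isolated"):
            sx.make_lattice(1, 1)

    def test_connected(self):
        assert sx.make_lattice(4, 4).n_components() == 1


class TestFieldDraws:
    def test_icar_draws_are_centered(self):
        g = sx.make_lattice(4, 4)
        x = _icar_draw(g, 0.7, np.random.default_rng(3), size=5)
        assert x.shape == (16, 5)
        assert np.allclose(x.mean(axis=0), 0.0, atol=1e-10)

    def test_icar_scale_proportional_to_sd(self):
        g = sx.make_lattice(4, 4)
        a = _icar_draw(g, 1.0, np.random.default_rng(9), size=3)
        b = _icar_draw(g, 2.5, np.random.default_rng(9), size=3)
        assert np.allclose(b, 2.5 * a)

    def test_icar_draws_are_spatially_smooth(self):
        # neighbour differences should be smaller than random-pair ones
        g = sx.make_lattice(8, 8)
        rng = np.random.default_rng(11)
        x = _icar_draw(g, 1.0, rng, size=50)
        nbr = np.mean((x[g.edges[:, 0]] - x[g.edges[:, 1]]) ** 2)
        perm = rng.permutation(g.I)
        far = np.mean((x - x[perm]) ** 2)
        assert nbr < far

    def test_rw1_centered_and_persistent(self):
        x = _rw1_draw(40, 0.3, np.random.default_rng(5), size=20)
        assert np.allclose(x.mean(axis=0), 0.0, atol=1e-12)
        lag1 = np.mean(x[1:] * x[:-1])  # a random walk is autocorrelated
        assert lag1 > 0


class TestSampleTrueState:
    def test_zero_sd_gives_zero_effect(self, grid3x3):
        spec = sx.ModelSpec("Alt1", 2)
        sig = sx.SignalSettings(sd_u=0.0, sd_v=0.0, sd_gamma=0.0, sd_phi=0.0)
        st = sx.sample_true_state(spec, grid3x3, 4, sig, seed=1)
        for name in ("u", "v", "gamma", "phi"):
            assert not np.any(getattr(st, name))

    def test_wrong_coefficient_shape_rejected(self, grid3x3):
        spec = sx.ModelSpec("Alt1", 1)
        cov = sx.make_covariates(9, 4, 2, 1, 1, seed=0)
        sig = sx.SignalSettings(beta_s=np.zeros((1, 3)))
        with pytest.raises(ValueError, match="shape"):
            sx.sample_true_state(spec, grid3x3, 4, sig, seed=1, cov=cov)

    def test_three_component_logit_shapes(self, grid3x3):
        st = sx.sample_true_state(sx.ModelSpec("Alt2", 2), grid3x3, 4, seed=2)
        assert st.z.shape == (9, 2, 3)
        assert st.a.shape == (9, 2, 3)

    def test_fixed_rho_respected(self, grid3x3):
        sig = sx.SignalSettings(rho=[0.5, 2.0])
        st = sx.sample_true_state(sx.ModelSpec("Alt3b", 2), grid3x3, 4, sig, seed=3)
        assert np.allclose(st.rho, [0.5, 2.0])


class TestCountsGeneration:
    def test_populations_in_range_and_constant(self):
        pop = default_populations(50, 6, seed=4)
        assert pop.shape == (50, 6)
        assert np.all(pop >= 1e4) and np.all(pop <= 5e5)
        assert np.all(pop == pop[:, :1])

    def test_null_model_counts_track_expected(self, grid3x3):
        # all effects off: y ~ Poisson(e) so the empirical SIR is near 1
        spec = sx.ModelSpec("Alt1", 1)
        sig = sx.SignalSettings(sd_u=0, sd_v=0, sd_gamma=0, sd_phi=0, sd_z=0, sd_a=0)
        st = sx.sample_true_state(spec, grid3x3, 20, sig, seed=0)
        pop = default_populations(9, 20, seed=1)
        frame = sx.generate_counts(spec, st, pop, rates=(3e-4,), seed=2)
        sir = frame.y.sum() / frame.expected.sum()
        se = 1 / np.sqrt(frame.expected.sum())
        assert abs(sir - 1) < 4 * se

    def test_deterministic_under_seed(self, grid3x3):
        spec = sx.ModelSpec("Alt1", 1)
        st = sx.sample_true_state(spec, grid3x3, 4, seed=0)
        pop = default_populations(9, 4, seed=1)
        a = sx.generate_counts(spec, st, pop, seed=7)
        b = sx.generate_counts(spec, st, pop, seed=7)
        assert np.array_equal(a.y, b.y)

    def test_overflow_guard(self, grid3x3):
        spec = sx.ModelSpec("Alt1", 1)
        st = sx.sample_true_state(spec, grid3x3, 4, seed=0)
        st.alpha0[:] = 50.0
        pop = default_populations(9, 4, seed=1)
        with pytest.raises(FloatingPointError, match="overflow"):
            sx.generate_counts(spec, st, pop, seed=2)


class TestThresholding:
    def test_coding_rules(self):
        frame = sx.make_dataset(sx.ModelSpec("Alt1", 1), rows=2, cols=2, J=2, seed=0).frame
        frame = frame.copy()
        frame.y[...] = 0
        frame.y[0, 0, 0] = 3   # -> code 5
        frame.y[0, 1, 0] = 7   # -> code 10
        frame.y[1, 0, 0] = 12  # above every interval, untouched
        coded = sx.apply_thresholding(frame)
        assert coded.y[0, 0, 0] == 5 and coded.coded[0, 0, 0]
        assert coded.y[0, 1, 0] == 10 and coded.coded[0, 1, 0]
        assert coded.y[1, 0, 0] == 12 and not coded.coded[1, 0, 0]
        assert coded.y[1, 1, 0] == 0 and not coded.coded[1, 1, 0]

    def test_realistic_rates_produce_some_censoring(self):
        ds = sx.make_dataset(sx.ModelSpec("Alt1", 3), rows=6, cols=6, J=8, seed=5)
        frac = ds.frame_coded.coded.mean()
        assert 0.0 < frac < 0.9  # censoring present but not total


class TestMakeDataset:
    def test_deterministic_and_self_consistent(self):
        spec = sx.ModelSpec("Alt2", 2)
        a = sx.make_dataset(spec, rows=4, cols=3, J=5, seed=13)
        b = sx.make_dataset(spec, rows=4, cols=3, J=5, seed=13)
        assert np.array_equal(a.frame.y, b.frame.y)
        assert np.allclose(a.state.v, b.state.v)
        assert a.frame.counties == a.graph.counties
        assert a.cov.standardized

    def test_different_seeds_differ(self):
        spec = sx.ModelSpec("Alt1", 1)
        a = sx.make_dataset(spec, rows=4, cols=3, J=5, seed=1)
        b = sx.make_dataset(spec, rows=4, cols=3, J=5, seed=2)
        assert not np.array_equal(a.frame.y, b.frame.y)


class TestRecoveryHarness:
    def test_desk_scale_guard(self):
        with pytest.raises(ValueError, match="desk-scale"):
            sx.recovery_harness(
                sx.ModelSpec("Alt1", 1), sx.SignalSettings(),
                sx.McmcConfig(n_burnin=10, n_samples=10), rows=20, cols=20,
            )

    def test_single_replicate_scorecard(self):
        cfg = sx.McmcConfig(n_chains=2, n_burnin=60, n_samples=40, seed=0)
        out = sx.recovery_harness(
            sx.ModelSpec("Alt1", 1), sx.SignalSettings(), cfg,
            n_replicates=1, seed=3, rows=3, cols=3, J=4,
        )
        assert len(out) == 1
        row = out.iloc[0]
        assert -1 <= row["v_corr"] <= 1
        assert 0 <= row["p_spatial_mean"] <= 1
        assert np.isfinite(row["waic_Alt1"])
        assert isinstance(row["converged"], (bool, np.bool_))
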
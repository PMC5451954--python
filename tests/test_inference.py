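import dataclasses

import numpy as np
import pytest

import stmix as sx
from stmix.inference import gelman_rubin, initialize, rhat_table


def _tiny_fit(frame, graph, cov=None, variant="Alt1", K=1, seed=0, **kw):
    spec = sx.ModelSpec(variant, K)
    cfg = sx.McmcConfig(n_chains=2, n_burnin=60, n_samples=40, seed=seed, **kw)
    return sx.run_mcmc(frame, graph, cov, spec, cfg)


class TestInitialize:
    def test_intercept_at_log_sir_and_rest_zero(self, small_frame, grid3x3):
        spec = sx.ModelSpec("Alt1", 1)
        st = initialize(spec, small_frame, grid3x3)
        # expected counts conserve totals, so the log overall SIR is zero
        assert st.alpha0 == pytest.approx(0.0, abs=1e-12)
        for name in ("u", "v", "gamma", "phi", "z", "a"):
            assert not np.any(getattr(st, name))
        assert st.sigma["v"] == pytest.approx(spec.C("v") / 2)

    def test_alt3b_rho_starts_at_prior_mean(self):
        spec = sx.ModelSpec("Alt3b", 2)
        ds = sx.make_dataset(spec, rows=3, cols=2, J=3, seed=1)
        st = initialize(spec, sx.recompute_expected(ds.frame), ds.graph)
        assert np.allclose(st.rho, 2.0)

    def test_requires_expected(self, small_dataset):
        frame = small_dataset.frame.copy()
        frame.expected = None
        with pytest.raises(ValueError, match="expected"):
            initialize(sx.ModelSpec("Alt1", 1), frame, small_dataset.graph)

    def test_disease_count_mismatch(self, small_frame, grid3x3):
        with pytest.raises(ValueError, match="diseases"):
            initialize(sx.ModelSpec("F2PRED", 2), small_frame, grid3x3)


class TestRunMcmcContracts:
    def test_rejects_unimputed_codes(self, small_dataset):
        coded = sx.expected_counts(small_dataset.frame_coded)
        if not coded.coded.any():  # force at least one code
            coded.y[0, 0, 0] = 5
            coded.coded[0, 0, 0] = True
        with pytest.raises(ValueError, match="impute"):
            sx.run_mcmc(coded, small_dataset.graph)

    def test_rejects_unstandardized_covariates(self, small_frame, grid3x3, rng):
        cov = sx.CovariateSet(
            rng.normal(2, 3, (small_frame.I, 1)),
            np.zeros((small_frame.J, 0)),
            np.zeros((small_frame.I, small_frame.J, 0)),
        )
        with pytest.raises(ValueError, match="standardized"):
            sx.run_mcmc(small_frame, grid3x3, cov)

    def test_rejects_missing_expected(self, small_dataset):
        frame = small_dataset.frame.copy()
        frame.expected = None
        with pytest.raises(ValueError, match="expected"):
            sx.run_mcmc(frame, small_dataset.graph)


class TestDeterminismAndShapes:
    def test_bitwise_reproducible_under_seed(self, small_frame, grid3x3):
        a = _tiny_fit(small_frame, grid3x3, seed=5)
        b = _tiny_fit(small_frame, grid3x3, seed=5)
        c = _tiny_fit(small_frame, grid3x3, seed=6)
        for name in a.draws:
            assert np.array_equal(a.draws[name], b.draws[name]), name
        assert np.array_equal(a.loglik, b.loglik)
        assert not np.array_equal(a.draws["alpha0"], c.draws["alpha0"])

    def test_draw_shapes_and_shared_storage(self):
        spec = sx.ModelSpec("F2PRED", 2)
        ds = sx.make_dataset(spec, rows=3, cols=3, J=4, seed=2)
        frame = sx.recompute_expected(ds.frame)
        cfg = sx.McmcConfig(n_chains=2, n_burnin=50, n_samples=30, seed=0)
        fit = sx.run_mcmc(frame, ds.graph, ds.cov, spec, cfg)
        I, J, K = frame.I, frame.J, frame.K
        assert fit.draws["v"].shape == (2, 30, I)          # one shared field
        assert fit.draws["gamma"].shape == (2, 30, J)      # one shared walk
        assert fit.draws["u"].shape == (2, 30, I, K)
        assert fit.draws["phi"].shape == (2, 30, I, J, K)
        assert fit.loglik.shape == (2, 30, I, J, K)
        assert fit.y_rep.dtype.kind == "i"

    def test_alt1_bivariate_gamma_is_per_disease(self):
        spec = sx.ModelSpec("Alt1", 2)
        ds = sx.make_dataset(spec, rows=3, cols=2, J=4, seed=3)
        frame = sx.recompute_expected(ds.frame)
        cfg = sx.McmcConfig(n_chains=1, n_burnin=40, n_samples=20, seed=0)
        fit = sx.run_mcmc(frame, ds.graph, ds.cov, spec, cfg)
        assert fit.draws["gamma"].shape == (1, 20, frame.J, 2)

    def test_accept_rates_recorded(self, small_frame, grid3x3):
        fit = _tiny_fit(small_frame, grid3x3)
        assert fit.accept_rates
        for key, rate in fit.accept_rates.items():
            if np.isnan(rate):  # family never proposed (e.g. no covariates)
                continue
            assert 0.0 <= rate <= 1.0, key
        assert any(not np.isnan(r) for r in fit.accept_rates.values())

    def test_update_families_freezes_others(self, small_frame, grid3x3):
        fit = _tiny_fit(
            small_frame, grid3x3, update_families=("alpha0", "sigma")
        )
        assert not np.any(fit.draws["v"])  # never proposed, stays at init
        assert np.ptp(fit.stacked("alpha0")) > 0  # actually moved

    def test_randomized_sweep_order_smoke(self, small_frame, grid3x3):
        fit = _tiny_fit(small_frame, grid3x3, randomize_order=True)
        assert np.all(np.isfinite(fit.loglik))

    def test_thinning(self, small_frame, grid3x3):
        fit = _tiny_fit(small_frame, grid3x3, thin=4)
        assert fit.n_draws == 10  # 40 post-burn-in sweeps, keep every 4th


class TestPriorOnly:
    def test_prior_only_run_leaves_likelihood_blank(self, small_frame, grid3x3):
        fit = _tiny_fit(small_frame, grid3x3, prior_only=True)
        assert not np.any(fit.loglik)
        assert not np.any(fit.y_rep)

    def test_prior_only_sigmas_stay_inside_support(self, small_frame, grid3x3):
        fit = _tiny_fit(small_frame, grid3x3, prior_only=True)
        spec = fit.spec
        for fam in ("v", "gamma", "alpha0"):
            s = fit.stacked(f"sigma_{fam}")
            assert np.all(s > 0) and np.all(s < spec.C(fam))


def _manual_samples(draws_dict, n_chains, n_draws):
    return sx.PosteriorSamples(
        draws=draws_dict,
        loglik=np.zeros((n_chains, n_draws, 1, 1, 1)),
        y_rep=np.zeros((n_chains, n_draws, 1, 1, 1), dtype=int),
        accept_rates={},
        spec=sx.ModelSpec("Alt1", 1),
        config=sx.McmcConfig(n_burnin=1, n_samples=n_draws),
        counties=["a"],
        years=np.array([0]),
        diseases=["d1"],
    )


class TestGelmanRubin:
    def test_hand_computed_value(self):
        x = np.array([[[0.0], [2.0], [4.0]], [[10.0], [12.0], [14.0]]])
        s = _manual_samples({"x": x}, 2, 3)
        W = 4.0  # within-chain variance (ddof=1) in both chains
        Bn = np.var([2.0, 12.0], ddof=1)  # variance of chain means
        want = np.sqrt(((3 - 1) / 3 * W + Bn) / W)
        assert gelman_rubin(s, "x")[0] == pytest.approx(want)

    def test_identical_chains_hit_lower_limit(self):
        chain = np.random.default_rng(1).normal(size=(50, 2))
        s = _manual_samples({"x": np.stack([chain, chain])}, 2, 50)
        assert np.allclose(gelman_rubin(s, "x"), np.sqrt(49 / 50))

    def test_agrees_with_arviz_qualitatively(self):
        import arviz

        rng = np.random.default_rng(3)
        good = rng.normal(size=(2, 400, 1))
        bad = good.copy()
        bad[1] += 8.0  # chains exploring different regions
        for draws, lo, hi in ((good, None, 1.05), (bad, 1.5, None)):
            ours = float(gelman_rubin(_manual_samples({"x": draws}, 2, 400), "x")[0])
            theirs = float(
                arviz.rhat(
                    arviz.convert_to_dataset(draws[:, :, 0]), method="identity"
                )["x"].values
            )
            for val in (ours, theirs):
                if lo is not None:
                    assert val > lo
                if hi is not None:
                    assert val < hi

    def test_rhat_table_flags(self, small_frame, grid3x3):
        fit = _tiny_fit(small_frame, grid3x3)
        rt = rhat_table(fit)
        assert {"rhat_max", "converged"} <= set(rt.columns)
        assert np.all(np.isfinite(rt["rhat_max"]))


class TestPersistence:
    def test_save_load_round_trip(self, tmp_path, small_frame, grid3x3):
        fit = _tiny_fit(small_frame, grid3x3)
        fit.save(tmp_path / "post")
        back = sx.PosteriorSamples.load(tmp_path / "post")
        assert back.spec == fit.spec
        assert back.config == fit.config
        assert set(back.draws) == set(fit.draws)
        for name in fit.draws:
            assert np.allclose(back.draws[name], fit.draws[name]), name
        assert np.allclose(back.loglik, fit.loglik)
        assert np.array_equal(back.y_rep, fit.y_rep)
        assert back.counties == fit.counties
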
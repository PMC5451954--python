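import numpy as np
import pytest
from scipy import stats
from scipy.special import expit

import stmix as sx
from stmix.model_family import (
    alt3_scale,
    icar_full_conditional_kernel,
    icar_sum_of_squares,
    mixture_weights_three,
    mixture_weights_two,
    rw1_sum_of_squares,
)

from conftest import make_random_state


def oracle_log_risk(spec, state, cov, i, j, k):
    """Naive per-cell implementation of every variant, written from the
    model definitions with explicit scalar arithmetic (no broadcasting)."""
    m_s = (
        float(cov.x_spatial[i] @ state.beta_s[k])
        + state.u[i, k]
        + state.v[i]
    )
    f_t = float(cov.x_temporal[j] @ state.beta_t[k])
    if spec.time_varying_beta_st:
        f_st = float(cov.x_st[i, j] @ state.beta_st[j, k])
    else:
        f_st = float(cov.x_st[i, j] @ state.beta_st[k])

    if spec.variant == "Alt2":
        q = expit(state.z[i, k] + state.a[i, k])  # (3,)
        p = q / q.sum()
        m_t = f_t + state.gamma[j]
        m_st = f_st + state.phi[i, j, k]
        return state.alpha0[k] + p[0] * m_s + p[1] * m_t + p[2] * m_st

    if spec.gamma_per_disease:
        g = state.gamma[j, k]
    elif spec.variant == "Alt3a":
        g = state.rho[k] * state.gamma[j]
    elif spec.variant == "Alt3b":
        gj = state.gamma[j]
        g = np.sign(gj) * abs(gj) ** state.rho[k]
    else:
        g = state.gamma[j]
    p_s = expit(state.z[i, k] + state.a[i, k])
    m_st = f_st + f_t + g + state.phi[i, j, k]
    return state.alpha0[k] + p_s * m_s + (1 - p_s) * m_st


VARIANT_CASES = [
    ("F2PRED", 1), ("F2PRED", 2), ("Alt1", 1), ("Alt1", 2), ("Alt1", 3),
    ("Alt2", 1), ("Alt2", 2), ("Alt3a", 2), ("Alt3b", 3),
]


class TestLinearPredictorOracle:
    @pytest.mark.parametrize("variant,K", VARIANT_CASES)
    def test_matches_naive_cell_oracle(self, variant, K):
        spec = sx.ModelSpec(variant, K)
        graph = sx.make_lattice(3, 3)
        J = 4
        cov = sx.make_covariates(graph.I, J, 2, 1, 1, seed=5)
        state = make_random_state(spec, graph, J, seed=31, cov=cov)
        eta = sx.linear_predictor(spec, state, cov)
        rng = np.random.default_rng(0)
        for _ in range(25):
            i, j, k = rng.integers([graph.I, J, K])
            want = oracle_log_risk(spec, state, cov, i, j, k)
            assert eta[i, j, k] == pytest.approx(want, abs=1e-12)
            assert sx.log_relative_risk(spec, state, cov, i, j, k) == pytest.approx(
                want, abs=1e-12
            )

    def test_time_constant_st_coefficients(self):
        spec = sx.ModelSpec("F2PRED", 2, time_varying_beta_st=False)
        graph = sx.make_lattice(3, 2)
        cov = sx.make_covariates(graph.I, 3, 1, 1, 2, seed=2)
        state = make_random_state(spec, graph, 3, seed=8, cov=cov)
        assert state.beta_st.shape == (2, 2)  # (K, P_ST), no year axis
        eta = sx.linear_predictor(spec, state, cov)
        assert eta[1, 2, 0] == pytest.approx(
            oracle_log_risk(spec, state, cov, 1, 2, 0), abs=1e-12
        )

    def test_alt1_univariate_equals_f2pred(self):
        graph = sx.make_lattice(3, 3)
        cov = sx.make_covariates(graph.I, 5, 1, 1, 1, seed=4)
        state = make_random_state(sx.ModelSpec("F2PRED", 1), graph, 5, seed=6, cov=cov)
        eta_f = sx.linear_predictor(sx.ModelSpec("F2PRED", 1), state, cov)
        eta_a = sx.linear_predictor(sx.ModelSpec("Alt1", 1), state, cov)
        assert np.array_equal(eta_f, eta_a)


class TestMixtureWeights:
    def test_two_component_complements(self, rng):
        z, a = rng.normal(size=(6, 2)), rng.normal(size=(6, 2))
        p_s, p_st = mixture_weights_two(z, a)
        assert np.allclose(p_s + p_st, 1.0)
        assert np.all((p_s >= 0) & (p_s <= 1))

    def test_two_component_extreme_logits_saturate(self):
        p_s, p_st = mixture_weights_two(np.array([800.0, -800.0]), 0.0)
        assert p_s[0] == 1.0 and p_s[1] == 0.0
        assert np.all(np.isfinite([p_st[0], p_st[1]]))

    def test_three_component_normalization_and_order(self, rng):
        z, a = rng.normal(size=(5, 2, 3)), rng.normal(size=(5, 2, 3))
        p = mixture_weights_three(z, a)
        assert np.allclose(p.sum(axis=-1), 1.0)
        # raising one component's logit raises its share
        z2 = z.copy()
        z2[..., 1] += 3.0
        assert np.all(mixture_weights_three(z2, a)[..., 1] > p[..., 1])

    def test_three_component_degenerate_raises(self):
        with pytest.raises(ValueError, match="degenerate"):
            mixture_weights_three(np.full((1, 1, 3), -1e4), np.zeros((1, 1, 3)))

    def test_trailing_axis_checked(self):
        with pytest.raises(ValueError, match="trailing"):
            mixture_weights_three(np.zeros((4, 2)), np.zeros((4, 2)))


class TestAlt3Scale:
    def test_alt3a_is_linear(self):
        g = np.array([-0.5, 0.0, 1.2])
        assert np.allclose(alt3_scale("Alt3a", g, 2.0), 2.0 * g)

    def test_alt3b_identity_at_unit_exponent(self):
        g = np.array([-0.5, 0.0, 1.2])
        assert np.allclose(alt3_scale("Alt3b", g, 1.0), g)

    def test_alt3b_preserves_sign_and_zero(self):
        out = alt3_scale("Alt3b", np.array([-2.0, 0.0, 2.0]), 0.5)
        assert out[0] == pytest.approx(-np.sqrt(2))
        assert out[1] == 0.0
        assert out[2] == pytest.approx(np.sqrt(2))

    def test_alt3b_rejects_nonpositive_exponent(self):
        with pytest.raises(ValueError, match="rho"):
            alt3_scale("Alt3b", np.ones(2), 0.0)


class TestLogLikelihood:
    def test_matches_scipy_poisson_logpmf(self, small_frame, grid3x3):
        spec = sx.ModelSpec("Alt1", 1)
        cov = sx.CovariateSet.empty(small_frame.I, small_frame.J)
        state = make_random_state(spec, grid3x3, small_frame.J, seed=12)
        total, pointwise = sx.log_likelihood(small_frame, spec, state, cov)
        mu = small_frame.expected * np.exp(sx.linear_predictor(spec, state, cov))
        want = stats.poisson.logpmf(small_frame.y, mu)
        assert np.allclose(pointwise, want, atol=1e-10)
        assert total == pytest.approx(want.sum())

    def test_overflowing_mean_names_cell(self, small_frame, grid3x3):
        spec = sx.ModelSpec("Alt1", 1)
        cov = sx.CovariateSet.empty(small_frame.I, small_frame.J)
        state = make_random_state(spec, grid3x3, small_frame.J, seed=12)
        state.alpha0[:] = 1e4
        with pytest.raises(FloatingPointError, match="county"):
            sx.log_likelihood(small_frame, spec, state, cov)


class TestKernels:
    def test_icar_sum_of_squares_path_hand_value(self):
        g = sx.AdjacencyGraph(["a", "b", "c"], np.array([[0, 1], [1, 2]]))
        x = np.array([1.0, 4.0, 6.0])
        assert icar_sum_of_squares(g, x) == pytest.approx(9.0 + 4.0)

    def test_rw1_sum_of_squares_hand_value(self):
        x = np.array([0.0, 2.0, 3.0, 3.0])
        assert rw1_sum_of_squares(x) == pytest.approx(4.0 + 1.0 + 0.0)

    def test_icar_conditional_mean_is_neighbor_average(self):
        g = sx.make_lattice(2, 2)
        x = np.array([0.0, 1.0, 2.0, 5.0])
        # kernel is maximized (0) when x_i equals the neighbour mean
        x_at_mean = x.copy()
        x_at_mean[0] = (x[1] + x[2]) / 2
        assert icar_full_conditional_kernel(g, x_at_mean, 0, 1.0) == pytest.approx(0.0)
        assert icar_full_conditional_kernel(g, x, 0, 1.0) < 0


class TestLogPrior:
    def _setup(self, variant="Alt1", K=2):
        spec = sx.ModelSpec(variant, K)
        graph = sx.make_lattice(3, 3)
        state = make_random_state(spec, graph, 4, seed=19)
        return spec, graph, state

    def test_finite_inside_support(self):
        spec, graph, state = self._setup()
        assert np.isfinite(sx.log_prior(spec, state, graph))

    def test_sigma_outside_bound_gives_minus_inf(self):
        spec, graph, state = self._setup()
        state.sigma["v"] = np.asarray(spec.C("v") + 1.0)
        assert sx.log_prior(spec, state, graph) == -np.inf

    def test_negative_sigma_gives_minus_inf(self):
        spec, graph, state = self._setup()
        state.sigma["u"] = np.array([-0.1, 1.0])
        assert sx.log_prior(spec, state, graph) == -np.inf

    def test_alt3b_negative_rho_gives_minus_inf(self):
        spec, graph, state = self._setup("Alt3b", 2)
        state.rho = np.array([1.0, -0.5])
        assert sx.log_prior(spec, state, graph) == -np.inf

    def test_icar_invariant_to_constant_shift_in_v(self):
        spec, graph, state = self._setup()
        base = sx.log_prior(spec, state, graph)
        shifted = state.copy()
        shifted.v = state.v + 3.7  # improper kernel ignores the level
        assert sx.log_prior(spec, shifted, graph) == pytest.approx(base)

    def test_gamma_quadratic_in_differences(self):
        spec, graph, state = self._setup()
        base = sx.log_prior(spec, state, graph)
        shifted = state.copy()
        shifted.gamma = state.gamma + 1.1
        assert sx.log_prior(spec, shifted, graph) == pytest.approx(base)


class TestModelSpec:
    def test_unknown_variant(self):
        with pytest.raises(ValueError, match="variant"):
            sx.ModelSpec("Alt9", 1)

    def test_alt3_needs_multiple_diseases(self):
        with pytest.raises(ValueError, match="bivariate"):
            sx.ModelSpec("Alt3a", 1)

    def test_structure_queries(self):
        assert sx.ModelSpec("Alt2", 2).three_component
        assert not sx.ModelSpec("Alt1", 1).gamma_per_disease
        assert sx.ModelSpec("Alt1", 2).gamma_per_disease
        assert sx.ModelSpec("Alt3b", 2).has_rho
        assert sx.ModelSpec("F2PRED", 3).arity == "multivariate"

    def test_sd_bound_mapping(self):
        spec = sx.ModelSpec("Alt1", 1, sd_bound={"v": 2.0})
        assert spec.C("v") == 2.0
        assert spec.C("u") == 10.0  # default for unlisted families

    def test_yaml_round_trip(self, tmp_path):
        spec = sx.ModelSpec("Alt3a", 2, sd_bound=5.0, time_varying_beta_st=False)
        path = tmp_path / "spec.yaml"
        spec.to_yaml(path)
        assert sx.ModelSpec.from_yaml(path) == spec


class TestPropertyBased:
    from hypothesis import given, settings, strategies as st

    logits = st.floats(
        min_value=-1e6, max_value=1e6, allow_nan=False, allow_infinity=False
    )

    @given(st.lists(logits, min_size=1, max_size=20),
           st.lists(logits, min_size=1, max_size=20))
    @settings(max_examples=200, deadline=None)
    def test_two_component_weights_always_valid(self, z, a):
        n = min(len(z), len(a))
        p_s, p_st = mixture_weights_two(np.array(z[:n]), np.array(a[:n]))
        assert np.all((p_s >= 0) & (p_s <= 1))
        assert np.allclose(p_s + p_st, 1.0, atol=1e-12)

    @given(st.lists(st.tuples(logits, logits, logits), min_size=1, max_size=10))
    @settings(max_examples=200, deadline=None)
    def test_three_component_weights_always_valid(self, rows):
        z = np.array(rows)
        try:
            p = mixture_weights_three(z, np.zeros_like(z))
        except ValueError:
            # legal only when some row's logits all underflow the logistic
            assert np.any(np.all(z < -700, axis=-1))
            return
        assert np.all((p >= 0) & (p <= 1))
        assert np.allclose(p.sum(axis=-1), 1.0, atol=1e-12)
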
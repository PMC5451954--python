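import numpy as np
import pytest

import stmix as sx


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def grid3x3():
    return sx.make_lattice(3, 3)


@pytest.fixture
def small_frame():
    """3x3 lattice, 4 years, one disease, no censoring, e computed."""
    spec = sx.ModelSpec("Alt1", 1)
    ds = sx.make_dataset(spec, rows=3, cols=3, J=4, seed=9)
    return sx.recompute_expected(ds.frame)


@pytest.fixture
def small_dataset():
    spec = sx.ModelSpec("Alt1", 1)
    return sx.make_dataset(spec, rows=3, cols=3, J=4, seed=9)


def make_random_state(spec, graph, J, seed, cov=None):
    """Generative state with a bit of every effect, for oracle tests."""
    sig = sx.SignalSettings(
        beta_s=0.3 * np.ones((spec.K, cov.P[0] if cov else 0)),
        beta_t=-0.2 * np.ones((spec.K, cov.P[1] if cov else 0)),
        beta_st=0.1 * np.ones((spec.K, cov.P[2] if cov else 0)),
        sd_u=0.2, sd_v=0.4, sd_gamma=0.3, sd_phi=0.1, sd_z=0.5, sd_a=0.4,
    )
    return sx.sample_true_state(spec, graph, J, sig, seed=seed, cov=cov)
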
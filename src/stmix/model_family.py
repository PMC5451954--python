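"""Space-time mixture model family for small-area disease risk.

Counts follow a conditionally independent Poisson law,

    y_ijk ~ Poisson(mu_ijk),   mu_ijk = e_ijk * theta_ijk,

for county i, year j and disease k, with e_ijk the expected count and
theta_ijk the relative risk.  The log relative risk is a convex mixture of
component-specific linear predictors,

    log(theta_ijk) = alpha_0k + sum_h p_ikh * M_ijkh,
    sum_h p_ikh = 1,  p_ikh in [0, 1],

where the components h are spatial / spatio-temporal (two-component
variants) or spatial / temporal / spatio-temporal (the three-component
variant), and the area- and disease-specific weights p are themselves
modelled through spatially correlated (intrinsic CAR) and uncorrelated
logit fields.  Five variants are supported:

``F2PRED``
    two components; temporal random walk gamma_j shared across diseases,
    folded into the spatio-temporal component.
``Alt1``
    as F2PRED, but gamma is disease-specific (gamma_jk) in multi-disease
    fits; identical to F2PRED in the univariate case.
``Alt2``
    three components; the temporal block (temporal covariates plus the
    shared gamma_j) gets its own mixture weight p_ikT.
``Alt3a`` / ``Alt3b``
    as F2PRED, but the shared gamma_j is scaled per disease: rho_k*gamma_j
    (Alt3a, rho_k ~ Normal) or a sign-preserving power
    sign(gamma_j)*|gamma_j|^rho_k (Alt3b, rho_k ~ Gamma(2,1)).  Only
    meaningful with two or more diseases.

Multi-disease information sharing happens through the effects without a
disease subscript: the ICAR field v_i always, and gamma_j except in Alt1.
All random-effect standard deviations carry Uniform(0, C) priors.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml
from scipy.special import expit, gammaln

from .data_io import AdjacencyGraph, CovariateSet, StudyFrame

VARIANTS = ("F2PRED", "Alt1", "Alt2", "Alt3a", "Alt3b")
ARITY_NAMES = {1: "univariate", 2: "bivariate", 3: "multivariate"}

#: effect families whose scale parameters get Uniform(0, C) priors
SD_FAMILIES = ("alpha0", "beta", "u", "v", "gamma", "phi", "z", "a", "rho")


@dataclasses.dataclass(frozen=True)
class ModelSpec:
    """A model variant plus its arity and prior hyperparameters.

    Parameters
    ----------
    variant
        One of ``F2PRED, Alt1, Alt2, Alt3a, Alt3b``.
    n_diseases
        K in {1, 2, 3}; Alt3a/Alt3b require K >= 2.
    sd_bound
        Upper bound C of the Uniform(0, C) prior on every random-effect
        standard deviation; either a scalar or a mapping per effect family
        (keys from :data:`SD_FAMILIES`).
    time_varying_beta_st
        If True (default), spatio-temporal covariates get per-year
        coefficient vectors beta_jk; if False a single beta_k.
    """

    variant: str
    n_diseases: int = 1
    sd_bound: float | Mapping[str, float] = 10.0
    time_varying_beta_st: bool = True

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(
                f"unknown variant {self.variant!r}; choose from {VARIANTS}"
            )
        if self.n_diseases not in (1, 2, 3):
            raise ValueError("n_diseases must be 1, 2 or 3")
        if self.variant in ("Alt3a", "Alt3b") and self.n_diseases < 2:
            raise ValueError(
                f"{self.variant} is only defined for bivariate/multivariate fits"
            )

    # -- structure queries --------------------------------------------------

    @property
    def K(self) -> int:
        return self.n_diseases

    @property
    def arity(self) -> str:
        return ARITY_NAMES[self.n_diseases]

    @property
    def three_component(self) -> bool:
        return self.variant == "Alt2"

    @property
    def gamma_per_disease(self) -> bool:
        """Alt1 lets the temporal walk vary by disease (when K > 1)."""
        return self.variant == "Alt1" and self.n_diseases > 1

    @property
    def has_rho(self) -> bool:
        return self.variant in ("Alt3a", "Alt3b")

    def C(self, family: str) -> float:
        if isinstance(self.sd_bound, Mapping):
            return float(self.sd_bound.get(family, 10.0))
        return float(self.sd_bound)

    # -- (de)serialization --------------------------------------------------

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        if isinstance(self.sd_bound, Mapping):
            d["sd_bound"] = dict(self.sd_bound)
        Path(path).write_text(yaml.safe_dump(d))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ModelSpec":
        return cls(**yaml.safe_load(Path(path).read_text()))


@dataclasses.dataclass
class ParameterState:
    """One full point in a model's parameter space.

    Array shapes (I counties, J years, K diseases, P_* covariates):

    ==========  ==========================================================
    alpha0      (K,) intercepts
    beta_s      (K, P_S) spatial coefficients
    beta_t      (K, P_T) temporal coefficients
    beta_st     (J, K, P_ST) per-year, or (K, P_ST) time-constant
    u           (I, K) uncorrelated spatial effects
    v           (I,) ICAR spatial effect, shared across diseases
    gamma       (J,) shared or (J, K) disease-specific random walk
    phi         (I, J, K) uncorrelated space-time interactions
    z           (I, K) or (I, K, 3) CAR-correlated mixture logits
    a           same shape as z, uncorrelated mixture logits
    rho         (K,) temporal scaling (Alt3a/Alt3b only), else None
    sigma       dict family -> SD parameter(s); scalars for shared
                families (alpha0, beta, v, gamma), (K,) arrays for
                disease-specific families (u, phi, z, a, rho)
    ==========  ==========================================================
    """

    alpha0: np.ndarray
    beta_s: np.ndarray
    beta_t: np.ndarray
    beta_st: np.ndarray
    u: np.ndarray
    v: np.ndarray
    gamma: np.ndarray
    phi: np.ndarray
    z: np.ndarray
    a: np.ndarray
    sigma: dict
    rho: np.ndarray | None = None

    def copy(self) -> "ParameterState":
        return ParameterState(
            alpha0=self.alpha0.copy(), beta_s=self.beta_s.copy(),
            beta_t=self.beta_t.copy(), beta_st=self.beta_st.copy(),
            u=self.u.copy(), v=self.v.copy(), gamma=self.gamma.copy(),
            phi=self.phi.copy(), z=self.z.copy(), a=self.a.copy(),
            sigma={f: np.array(s, copy=True) for f, s in self.sigma.items()},
            rho=None if self.rho is None else self.rho.copy(),
        )


# ---------------------------------------------------------------------------
# Mixture weights
# ---------------------------------------------------------------------------


def mixture_weights_two(z, a):
    """Two-component weights: p_S = logistic(z + a), p_ST = 1 - p_S.

    Accepts scalars or arrays; the logistic saturates safely at extreme
    logits.
    """
    p_s = expit(np.asarray(z, dtype=float) + np.asarray(a, dtype=float))
    return p_s, 1.0 - p_s


def mixture_weights_three(z, a):
    """Three-component weights via normalized logistics.

    q_h = logistic(z_h + a_h); p_h = q_h / sum_h q_h, over the trailing
    axis of length 3 (order S, T, ST).  Raises if every q underflows to
    zero, which would leave the weights undefined.
    """
    logits = np.asarray(z, dtype=float) + np.asarray(a, dtype=float)
    if logits.shape[-1] != 3:
        raise ValueError("three-component weights need a trailing axis of 3")
    q = expit(logits)
    total = q.sum(axis=-1, keepdims=True)
    if np.any(total == 0):
        raise ValueError("degenerate mixture: all component logits underflow")
    return q / total


def mixture_weights(spec: ModelSpec, state: ParameterState) -> np.ndarray:
    """Weights for a full state: (I, K, 2) two-component or (I, K, 3)."""
    if spec.three_component:
        return mixture_weights_three(state.z, state.a)
    p_s, p_st = mixture_weights_two(state.z, state.a)
    return np.stack([p_s, p_st], axis=-1)


# ---------------------------------------------------------------------------
# Temporal scaling (Alt3)
# ---------------------------------------------------------------------------


def alt3_scale(variant: str, gamma, rho):
    """Disease-specific transform of the shared temporal walk.

    Alt3a: rho * gamma (scalar scaling).  Alt3b: sign-preserving power
    sign(gamma)*|gamma|^rho, which is the identity at rho = 1 and maps
    gamma = 0 to 0; the sign convention keeps the transform monotone for
    negative walk values, where a plain real power would be undefined.
    """
    gamma = np.asarray(gamma, dtype=float)
    rho = np.asarray(rho, dtype=float)
    if variant == "Alt3a":
        return rho * gamma
    if variant == "Alt3b":
        if np.any(rho <= 0):
            raise ValueError("Alt3b requires rho > 0")
        return np.sign(gamma) * np.abs(gamma) ** rho
    raise ValueError(f"no temporal scaling for variant {variant!r}")


# ---------------------------------------------------------------------------
# Linear predictor / relative risk
# ---------------------------------------------------------------------------


def _fixed_effects(spec, state, cov):
    """Covariate contributions: spatial (I,K), temporal (J,K), ST (I,J,K)."""
    f_s = cov.x_spatial @ state.beta_s.T  # (I, K)
    f_t = cov.x_temporal @ state.beta_t.T  # (J, K)
    if spec.time_varying_beta_st:
        f_st = np.einsum("ijp,jkp->ijk", cov.x_st, state.beta_st)
    else:
        f_st = np.einsum("ijp,kp->ijk", cov.x_st, state.beta_st)
    return f_s, f_t, f_st


def _gamma_effective(spec: ModelSpec, state: ParameterState) -> np.ndarray:
    """Temporal walk as it enters the predictor, shape (J, K)."""
    K = spec.K
    if spec.gamma_per_disease:
        return state.gamma
    g = state.gamma[:, None]
    if spec.variant == "Alt3a":
        return state.rho[None, :] * g
    if spec.variant == "Alt3b":
        return np.sign(g) * np.abs(g) ** state.rho[None, :]
    return np.broadcast_to(g, (g.shape[0], K))


def linear_predictor(
    spec: ModelSpec, state: ParameterState, cov: CovariateSet
) -> np.ndarray:
    """log relative risk eta_ijk = alpha_0k + sum_h p_ikh M_ijkh, (I,J,K)."""
    f_s, f_t, f_st = _fixed_effects(spec, state, cov)
    m_s = f_s + state.u + state.v[:, None]  # (I, K)
    g = _gamma_effective(spec, state)  # (J, K)
    if spec.three_component:
        m_t = f_t + state.gamma[:, None]  # (J, K)
        m_st = f_st + state.phi  # (I, J, K)
        p = mixture_weights_three(state.z, state.a)  # (I, K, 3)
        eta = (
            state.alpha0[None, None, :]
            + p[:, None, :, 0] * m_s[:, None, :]
            + p[:, None, :, 1] * m_t[None, :, :]
            + p[:, None, :, 2] * m_st
        )
    else:
        m_st = f_st + f_t[None, :, :] + g[None, :, :] + state.phi
        p_s, p_st = mixture_weights_two(state.z, state.a)  # (I, K)
        eta = (
            state.alpha0[None, None, :]
            + p_s[:, None, :] * m_s[:, None, :]
            + p_st[:, None, :] * m_st
        )
    return eta


def log_relative_risk(
    spec: ModelSpec,
    state: ParameterState,
    cov: CovariateSet,
    i: int,
    j: int,
    k: int,
) -> float:
    """log(theta_ijk) for a single cell (convenience over the full grid)."""
    eta = linear_predictor(spec, state, cov)
    return float(eta[i, j, k])


def log_likelihood(
    frame: StudyFrame,
    spec: ModelSpec,
    state: ParameterState,
    cov: CovariateSet,
) -> tuple[float, np.ndarray]:
    """Poisson log likelihood and its pointwise (I, J, K) matrix.

    mu = e * exp(eta); pointwise terms are y log mu - mu - log y!, the
    quantities accumulated for WAIC.
    """
    if frame.expected is None:
        raise ValueError("expected counts not computed")
    eta = linear_predictor(spec, state, cov)
    with np.errstate(over="ignore"):
        mu = frame.expected * np.exp(eta)
    if not np.all(np.isfinite(mu)):
        i, j, k = np.argwhere(~np.isfinite(mu))[0]
        raise FloatingPointError(
            f"non-finite Poisson mean at county {frame.counties[i]!r}, "
            f"year {frame.years[j]}, disease {frame.diseases[k]!r} "
            f"(eta = {eta[i, j, k]:.3g})"
        )
    y = frame.y
    with np.errstate(divide="ignore", invalid="ignore"):
        pointwise = np.where(
            y > 0, y * np.log(mu), 0.0
        ) - mu - gammaln(y + 1.0)
    return float(pointwise.sum()), pointwise


# ---------------------------------------------------------------------------
# Priors
# ---------------------------------------------------------------------------


def icar_sum_of_squares(graph: AdjacencyGraph, x: np.ndarray) -> np.ndarray:
    """Pairwise-difference sum sum_{i~l, i<l} (x_i - x_l)^2 along axis 0."""
    e = graph.edges
    d = x[e[:, 0]] - x[e[:, 1]]
    return (d * d).sum(axis=0)


def rw1_sum_of_squares(x: np.ndarray) -> np.ndarray:
    """First-difference sum sum_j (x_j - x_{j-1})^2 along axis 0."""
    d = np.diff(x, axis=0)
    return (d * d).sum(axis=0)


def _normal_term(x: np.ndarray, sigma, k_axis: int | None = None) -> float:
    """iid Normal(0, sigma^2) log density of all entries.

    ``sigma`` may be a scalar, or a (K,) array paired with the disease
    axis ``k_axis`` of ``x``.
    """
    sigma = np.asarray(sigma, dtype=float)
    if sigma.ndim == 0:
        return float(
            -x.size * (0.5 * np.log(2 * np.pi) + np.log(sigma))
            - (x * x).sum() / (2 * sigma**2)
        )
    other = tuple(i for i in range(x.ndim) if i != k_axis)
    ss = (x * x).sum(axis=other)
    n_per = x.size // sigma.size
    return float(
        np.sum(
            -n_per * (0.5 * np.log(2 * np.pi) + np.log(sigma))
            - ss / (2 * sigma**2)
        )
    )


def log_prior(
    spec: ModelSpec, state: ParameterState, graph: AdjacencyGraph
) -> float:
    """Joint log prior density of a state (improper parts up to a constant).

    Sums iid Normal terms (intercepts, coefficients, u, phi, a, Alt3a rho),
    intrinsic CAR pairwise-difference kernels for v and the correlated
    mixture logits z, the first-order random-walk kernel for gamma, the
    Gamma(2, 1) density for Alt3b's rho, and the flat Uniform(0, C) density
    for every SD parameter (-inf outside its support).  The ICAR and RW1
    kernels include their sigma-dependent normalizing exponent
    ``-rank * log(sigma)`` so that the scale parameters have well-defined
    conditionals; the remaining (state-independent) constants are dropped.
    """
    sg = state.sigma
    # support checks for the Uniform(0, C) scale priors
    for fam in SD_FAMILIES:
        if fam not in sg:
            continue
        s = np.atleast_1d(np.asarray(sg[fam], dtype=float))
        if np.any(s <= 0) or np.any(s >= spec.C(fam)):
            return -np.inf
    if spec.variant == "Alt3b" and np.any(state.rho <= 0):
        return -np.inf

    total = 0.0
    total += _normal_term(state.alpha0, sg["alpha0"])
    for b in (state.beta_s, state.beta_t, state.beta_st):
        if b.size:
            total += _normal_term(b, sg["beta"])
    total += _normal_term(state.u, sg["u"], k_axis=1)
    total += _normal_term(state.phi, sg["phi"], k_axis=2)
    total += _normal_term(state.a, sg["a"], k_axis=1)

    # intrinsic CAR for v (rank I - #components)
    rank_v = graph.I - graph.n_components()
    s_v = float(sg["v"])
    total += -rank_v * np.log(s_v) - icar_sum_of_squares(graph, state.v) / (
        2 * s_v**2
    )

    # CAR mixture logits, one field per disease (x components for Alt2)
    s_z = np.atleast_1d(np.asarray(sg["z"], dtype=float))
    z = state.z if state.z.ndim == 3 else state.z[:, :, None]
    for k in range(spec.K):
        ss_k = icar_sum_of_squares(graph, z[:, k, :]).sum()
        nfield = z.shape[2]
        total += -nfield * rank_v * np.log(s_z[k]) - ss_k / (2 * s_z[k] ** 2)

    # random walk for gamma
    J = state.gamma.shape[0]
    s_g = float(sg["gamma"])
    g = state.gamma if state.gamma.ndim == 2 else state.gamma[:, None]
    ncols = g.shape[1]
    total += -ncols * (J - 1) * np.log(s_g) - rw1_sum_of_squares(g).sum() / (
        2 * s_g**2
    )

    # temporal scaling parameters
    if spec.variant == "Alt3a":
        total += _normal_term(state.rho, sg["rho"], k_axis=0)
    elif spec.variant == "Alt3b":
        total += float(np.sum(np.log(state.rho) - state.rho))  # Gamma(2,1)

    # flat Uniform(0, C) contributions of the SDs themselves
    for fam in SD_FAMILIES:
        if fam in sg:
            s = np.atleast_1d(np.asarray(sg[fam], dtype=float))
            total += -s.size * np.log(spec.C(fam))
    return float(total)


def icar_full_conditional_kernel(
    graph: AdjacencyGraph, x: np.ndarray, i: int, sigma: float
) -> float:
    """Gaussian kernel of x_i | x_{-i} under the intrinsic CAR:
    Normal(mean = neighbour average, variance = sigma^2 / n_i)."""
    nbr_mean = float(graph.neighbor_sum(x)[i]) / graph.n_neighbors[i]
    return -graph.n_neighbors[i] * (x[i] - nbr_mean) ** 2 / (2 * sigma**2)
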
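"""Metropolis-within-Gibbs sampler for the space-time mixture models.

No conjugate Gibbs steps exist under the Poisson likelihood with
Uniform(0, C) priors on standard deviations, so every parameter is updated
by an adaptive Gaussian random-walk Metropolis step.  Updates are blocked
for speed: parameters whose likelihood footprints are disjoint axis-aligned
cell blocks (e.g. all u_ik, or all ICAR sites of one graph colour) are
proposed and accepted/rejected simultaneously, which keeps a full sweep to
a couple of dozen vectorized passes over the data cube.

Per-site proposal scales adapt toward a target acceptance rate during
burn-in only and are frozen afterwards, so the sampling phase is exact
Metropolis-Hastings.  Scale parameters are updated on the log scale with
the Jacobian correction, rejecting proposals outside (0, C).

The improper ICAR / random-walk fields are sampled unconstrained (the
posterior is proper: the intercepts carry proper Normal priors and the
mixture weights vary over areas); during burn-in the fields are recentred
each sweep with the offset pushed into an exactly compensating partner
(v -> u, z -> a, gamma -> phi) to keep the chain numerically anchored.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .data_io import AdjacencyGraph, CovariateSet, StudyFrame
from .model_family import (
    ModelSpec,
    ParameterState,
    linear_predictor,
)

_EFFECT_FAMILIES = (
    "alpha0", "beta_s", "beta_t", "beta_st", "u", "v", "gamma", "phi",
    "z", "a", "rho", "sigma",
)


@dataclasses.dataclass(frozen=True)
class McmcConfig:
    """Sampler configuration.

    The defaults mirror a two-chain run with 45,000 burn-in iterations and
    5,000 retained samples; tests and examples use much shorter, scaled
    configurations (run length is a precision choice, not a correctness
    requirement).
    """

    n_chains: int = 2
    n_burnin: int = 45_000
    n_samples: int = 5_000
    thin: int = 1
    seed: int = 0
    adapt_step: float = 0.05
    target_accept: float = 0.44
    update_families: tuple[str, ...] | None = None
    prior_only: bool = False
    randomize_order: bool = False

    def __post_init__(self) -> None:
        if self.n_burnin <= 0 or self.n_samples <= 0:
            raise ValueError("n_burnin and n_samples must be positive")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.update_families is not None:
            bad = set(self.update_families) - set(_EFFECT_FAMILIES)
            if bad:
                raise ValueError(f"unknown update families {sorted(bad)}")


@dataclasses.dataclass
class PosteriorSamples:
    """Posterior draws plus the pointwise quantities fit assessment needs.

    ``draws`` maps parameter-family names to arrays with leading axes
    (n_chains, n_draws); ``loglik`` and ``y_rep`` are (n_chains, n_draws,
    I, J, K) arrays of pointwise Poisson log likelihoods and
    posterior-predictive counts.
    """

    draws: dict
    loglik: np.ndarray
    y_rep: np.ndarray
    accept_rates: dict
    spec: ModelSpec
    config: McmcConfig
    counties: list[str]
    years: np.ndarray
    diseases: list[str]

    @property
    def n_chains(self) -> int:
        return self.loglik.shape[0]

    @property
    def n_draws(self) -> int:
        return self.loglik.shape[1]

    def stacked(self, name: str) -> np.ndarray:
        """Draws of one family with chains concatenated: (C*D, ...)."""
        d = self.draws[name]
        return d.reshape((-1,) + d.shape[2:])

    def loglik_matrix(self) -> np.ndarray:
        """Pointwise log likelihood as (total draws, I*J*K)."""
        c, d = self.loglik.shape[:2]
        return self.loglik.reshape(c * d, -1)

    def y_rep_matrix(self) -> np.ndarray:
        c, d = self.y_rep.shape[:2]
        return self.y_rep.reshape(c * d, -1)

    # -- persistence --------------------------------------------------------

    def save(self, outdir: str | Path) -> None:
        """Persist draws as one CSV per parameter family plus a manifest."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        shapes = {}
        for name, arr in list(self.draws.items()) + [
            ("loglik", self.loglik), ("y_rep", self.y_rep)
        ]:
            shapes[name] = list(arr.shape)
            flat = arr.reshape(arr.shape[0] * arr.shape[1], -1)
            pd.DataFrame(flat).to_csv(outdir / f"{name}.csv", index=False)
        manifest = {
            "spec": {
                "variant": self.spec.variant,
                "n_diseases": self.spec.n_diseases,
                "sd_bound": self.spec.sd_bound
                if not isinstance(self.spec.sd_bound, dict)
                else dict(self.spec.sd_bound),
                "time_varying_beta_st": self.spec.time_varying_beta_st,
            },
            "config": dataclasses.asdict(self.config),
            "accept_rates": {k: float(v) for k, v in self.accept_rates.items()},
            "counties": self.counties,
            "years": self.years.tolist(),
            "diseases": self.diseases,
            "shapes": shapes,
            "rhat": {
                k: float(v) for k, v in rhat_table(self)["rhat_max"].items()
            },
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))

    @classmethod
    def load(cls, outdir: str | Path) -> "PosteriorSamples":
        outdir = Path(outdir)
        manifest = json.loads((outdir / "manifest.json").read_text())
        cfgdict = dict(manifest["config"])
        if cfgdict.get("update_families") is not None:
            cfgdict["update_families"] = tuple(cfgdict["update_families"])
        spec = ModelSpec(**manifest["spec"])
        config = McmcConfig(**cfgdict)
        draws = {}
        loglik = y_rep = None
        for name, shape in manifest["shapes"].items():
            arr = pd.read_csv(outdir / f"{name}.csv").to_numpy()
            arr = arr.reshape(shape)
            if name == "loglik":
                loglik = arr
            elif name == "y_rep":
                y_rep = arr
            else:
                draws[name] = arr
        return cls(
            draws, loglik, y_rep, manifest["accept_rates"], spec, config,
            manifest["counties"], np.asarray(manifest["years"]),
            manifest["diseases"],
        )


# ---------------------------------------------------------------------------
# Initialization
# ---------------------------------------------------------------------------


def initialize(
    spec: ModelSpec,
    frame: StudyFrame,
    graph: AdjacencyGraph | None,
    seed: int = 0,
    cov: CovariateSet | None = None,
) -> ParameterState:
    """Deterministic starting state.

    Intercepts start at the per-disease log standardized incidence ratio
    log(sum y / sum e); every other effect starts at zero (equal mixture
    weights); SDs at C/2; Alt3 scalings at their prior mean.
    """
    I, J, K = frame.I, frame.J, frame.K
    if K != spec.K:
        raise ValueError(f"frame has K={K} diseases but spec expects {spec.K}")
    if frame.expected is None:
        raise ValueError("expected counts not computed")
    cov = cov if cov is not None else CovariateSet.empty(I, J)
    p_s, p_t, p_st = cov.P

    alpha0 = np.zeros(K)
    for k in range(K):
        sy = frame.y[:, :, k].sum()
        if sy == 0:
            raise ValueError(
                f"disease {frame.diseases[k]!r} has all-zero counts"
            )
        alpha0[k] = np.log(sy / frame.expected[:, :, k].sum())

    nz = 3 if spec.three_component else 1
    z_shape = (I, K, 3) if spec.three_component else (I, K)
    sigma = {
        fam: (np.full(K, spec.C(fam) / 2) if fam in ("u", "phi", "z", "a")
              else spec.C(fam) / 2)
        for fam in ("alpha0", "beta", "u", "v", "gamma", "phi", "z", "a")
    }
    rho = None
    if spec.has_rho:
        if spec.variant == "Alt3a":
            rho = np.zeros(K)
            sigma["rho"] = np.full(K, spec.C("rho") / 2)
        else:  # Alt3b: Gamma(2, 1) prior mean
            rho = np.full(K, 2.0)
    gamma = np.zeros((J, K)) if spec.gamma_per_disease else np.zeros(J)
    beta_st_shape = (J, K, p_st) if spec.time_varying_beta_st else (K, p_st)
    return ParameterState(
        alpha0=alpha0,
        beta_s=np.zeros((K, p_s)),
        beta_t=np.zeros((K, p_t)),
        beta_st=np.zeros(beta_st_shape),
        u=np.zeros((I, K)),
        v=np.zeros(I),
        gamma=gamma,
        phi=np.zeros((I, J, K)),
        z=np.zeros(z_shape),
        a=np.zeros(z_shape),
        sigma=sigma,
        rho=rho,
    )


# ---------------------------------------------------------------------------
# The sampler engine
# ---------------------------------------------------------------------------


class _Sampler:
    """Single-chain engine; see the module docstring for the scheme."""

    def __init__(self, spec, frame, graph, cov, config, rng, init_state=None):
        self.spec = spec
        self.frame = frame
        self.graph = graph
        self.cov = cov
        self.config = config
        self.rng = rng
        self.y = frame.y.astype(float)
        self.e = frame.expected
        self.state = init_state.copy() if init_state is not None else initialize(
            spec, frame, graph, cov=cov
        )
        self.eta = linear_predictor(spec, self.state, cov)
        if not np.all(np.isfinite(self.eta)):
            raise FloatingPointError("non-finite linear predictor at initialization")
        self.adapting = False

        I, J = frame.I, frame.J
        if graph is not None:
            self.colors = graph.color_classes()
            self.nn = graph.n_neighbors.astype(float)
        # chain-graph neighbour counts for the temporal walk
        if J > 1:
            nt = np.full(J, 2.0)
            nt[0] = nt[-1] = 1.0
            self.nt = nt
            jj = np.arange(J)
            self.t_colors = [(jj % 2 == 0), (jj % 2 == 1)]

        fams = config.update_families
        self.families = [
            f for f in _EFFECT_FAMILIES if fams is None or f in fams
        ]
        if not spec.has_rho and "rho" in self.families:
            self.families.remove("rho")

        st = self.state
        self.scales = {
            "alpha0": np.full(st.alpha0.shape, np.log(0.1)),
            "beta_s": np.full(st.beta_s.shape, np.log(0.1)),
            "beta_t": np.full(st.beta_t.shape, np.log(0.1)),
            "beta_st": np.full(st.beta_st.shape, np.log(0.1)),
            "u": np.full(st.u.shape, np.log(0.2)),
            "v": np.full(st.v.shape, np.log(0.2)),
            "gamma": np.full(st.gamma.shape, np.log(0.2)),
            "phi": np.full(st.phi.shape, np.log(0.2)),
            "z": np.full(st.z.shape, np.log(0.5)),
            "a": np.full(st.a.shape, np.log(0.5)),
        }
        if st.rho is not None:
            self.scales["rho"] = np.full(st.rho.shape, np.log(0.2))
        for fam, s in st.sigma.items():
            self.scales[f"sigma_{fam}"] = np.full(np.shape(s), np.log(0.3))
        self.acc_n = {k: 0.0 for k in self.scales}
        self.acc_d = {k: 0.0 for k in self.scales}

    # -- helpers ------------------------------------------------------------

    def _noise(self, key, subshape=None):
        ls = self.scales[key] if subshape is None else self.scales[key][subshape]
        return self.rng.standard_normal(np.shape(ls)) * np.exp(ls)

    def _ll_delta(self, eta_prop):
        """Cellwise log-likelihood change moving eta -> eta_prop."""
        if self.config.prior_only:
            return np.zeros_like(self.eta)
        with np.errstate(over="ignore", invalid="ignore"):
            d = self.y * (eta_prop - self.eta) - self.e * (
                np.exp(eta_prop) - np.exp(self.eta)
            )
        return np.where(np.isfinite(d), d, -np.inf)

    def _accept(self, logalpha):
        return np.log(self.rng.uniform(size=np.shape(logalpha))) < logalpha

    def _adapt(self, key, acc, mask=None):
        if self.adapting:
            step = self.config.adapt_step
            tgt = self.config.target_accept
            upd = step * (acc.astype(float) - tgt)
            if mask is None:
                self.scales[key] += upd
            else:
                self.scales[key][mask] += upd[mask]
        else:
            if mask is None:
                self.acc_n[key] += float(np.sum(acc))
                self.acc_d[key] += acc.size
            else:
                self.acc_n[key] += float(np.sum(acc[mask]))
                self.acc_d[key] += float(np.sum(mask))

    def _sigma_of(self, fam):
        return np.asarray(self.state.sigma[fam], dtype=float)

    def _patched(self, eta_prop, cell_mask):
        return np.where(cell_mask, eta_prop, self.eta)

    # -- effect updates -----------------------------------------------------

    def _update_alpha0(self):
        st = self.state
        old = st.alpha0
        prop = old + self._noise("alpha0")
        st.alpha0 = prop
        eta_p = linear_predictor(self.spec, st, self.cov)
        d_site = self._ll_delta(eta_p).sum(axis=(0, 1))  # (K,)
        s = self._sigma_of("alpha0")
        pr = (old**2 - prop**2) / (2 * s**2)
        acc = self._accept(d_site + pr)
        st.alpha0 = np.where(acc, prop, old)
        self.eta = self._patched(eta_p, acc[None, None, :])
        self._adapt("alpha0", acc)

    def _update_beta_block(self, attr, key):
        """One covariate column at a time; sites are disjoint across k
        (and across j for per-year spatio-temporal coefficients)."""
        st = self.state
        beta = getattr(st, attr)
        if beta.size == 0:
            return
        P = beta.shape[-1]
        s = self._sigma_of("beta")
        for p in range(P):
            old = beta[..., p].copy()
            prop = old + self._noise(key, (..., p))
            beta[..., p] = prop
            eta_p = linear_predictor(self.spec, st, self.cov)
            d = self._ll_delta(eta_p)
            if attr == "beta_s" or attr == "beta_t" or beta.ndim == 2:
                d_site = d.sum(axis=(0, 1))  # (K,)
                cell_mask_of = lambda a: a[None, None, :]
            else:  # time-varying beta_st: sites (J, K)
                d_site = d.sum(axis=0)  # (J, K)
                cell_mask_of = lambda a: a[None, :, :]
            pr = (old**2 - prop**2) / (2 * s**2)
            acc = self._accept(d_site + pr)
            beta[..., p] = np.where(acc, prop, old)
            self.eta = self._patched(eta_p, cell_mask_of(acc))
            if self.adapting:
                self.scales[key][..., p] += self.config.adapt_step * (
                    acc.astype(float) - self.config.target_accept
                )
            else:
                self.acc_n[key] += float(np.sum(acc))
                self.acc_d[key] += acc.size

    def _update_u(self):
        st = self.state
        old = st.u
        prop = old + self._noise("u")
        st.u = prop
        eta_p = linear_predictor(self.spec, st, self.cov)
        d_site = self._ll_delta(eta_p).sum(axis=1)  # (I, K)
        s = self._sigma_of("u")  # (K,)
        pr = (old**2 - prop**2) / (2 * s[None, :] ** 2)
        acc = self._accept(d_site + pr)
        st.u = np.where(acc, prop, old)
        self.eta = self._patched(eta_p, acc[:, None, :])
        self._adapt("u", acc)

    def _update_v(self):
        st = self.state
        s = float(self._sigma_of("v"))
        for cmask in self.colors:
            old = st.v
            prop = np.where(cmask, old + self._noise("v"), old)
            nbr_mean = (self.graph.W @ old) / self.nn
            pr = self.nn * ((old - nbr_mean) ** 2 - (prop - nbr_mean) ** 2) / (
                2 * s**2
            )
            st.v = prop
            eta_p = linear_predictor(self.spec, st, self.cov)
            d_site = self._ll_delta(eta_p).sum(axis=(1, 2))  # (I,)
            acc = self._accept(np.where(cmask, d_site + pr, -np.inf))
            st.v = np.where(acc, prop, old)
            self.eta = self._patched(eta_p, acc[:, None, None])
            self._adapt("v", acc, mask=cmask)

    def _update_gamma(self):
        st = self.state
        if st.gamma.shape[0] == 1:
            return  # single year: the walk has no free differences
        s = float(self._sigma_of("gamma"))
        per_k = st.gamma.ndim == 2
        for cmask in self.t_colors:
            old = st.gamma
            noise = self._noise("gamma")
            m = np.broadcast_to(cmask[:, None], old.shape) if per_k else cmask
            prop = np.where(m, old + noise, old)
            S = np.zeros_like(old)
            S[1:] += old[:-1]
            S[:-1] += old[1:]
            nt = self.nt[:, None] if per_k else self.nt
            nbr_mean = S / nt
            pr = nt * ((old - nbr_mean) ** 2 - (prop - nbr_mean) ** 2) / (2 * s**2)
            st.gamma = prop
            eta_p = linear_predictor(self.spec, st, self.cov)
            d = self._ll_delta(eta_p)
            if per_k:
                d_site = d.sum(axis=0)  # (J, K)
                acc = self._accept(np.where(m, d_site + pr, -np.inf))
                cell = acc[None, :, :]
            else:
                d_site = d.sum(axis=(0, 2))  # (J,)
                acc = self._accept(np.where(m, d_site + pr, -np.inf))
                cell = acc[None, :, None]
            st.gamma = np.where(acc, prop, old)
            self.eta = self._patched(eta_p, cell)
            self._adapt("gamma", acc, mask=m)

    def _update_phi(self):
        st = self.state
        old = st.phi
        prop = old + self._noise("phi")
        st.phi = prop
        eta_p = linear_predictor(self.spec, st, self.cov)
        d_site = self._ll_delta(eta_p)  # (I, J, K)
        s = self._sigma_of("phi")
        pr = (old**2 - prop**2) / (2 * s[None, None, :] ** 2)
        acc = self._accept(d_site + pr)
        st.phi = np.where(acc, prop, old)
        self.eta = self._patched(eta_p, acc)
        self._adapt("phi", acc)

    def _update_z(self):
        st = self.state
        s = self._sigma_of("z")  # (K,)
        three = st.z.ndim == 3
        h_range = range(3) if three else (None,)
        for h in h_range:
            for cmask in self.colors:
                old = st.z.copy()
                sub = (slice(None), slice(None), h) if three else (Ellipsis,)
                prop_field = old[sub] + self._noise("z", sub)
                prop = old.copy()
                prop[sub] = np.where(cmask[:, None], prop_field, old[sub])
                nbr_mean = (self.graph.W @ old[sub]) / self.nn[:, None]
                pr = self.nn[:, None] * (
                    (old[sub] - nbr_mean) ** 2 - (prop[sub] - nbr_mean) ** 2
                ) / (2 * s[None, :] ** 2)
                st.z = prop
                eta_p = linear_predictor(self.spec, st, self.cov)
                d_site = self._ll_delta(eta_p).sum(axis=1)  # (I, K)
                acc = self._accept(np.where(cmask[:, None], d_site + pr, -np.inf))
                new = old.copy()
                new[sub] = np.where(acc, prop[sub], old[sub])
                st.z = new
                self.eta = self._patched(eta_p, acc[:, None, :])
                if self.adapting:
                    upd = self.config.adapt_step * (
                        acc.astype(float) - self.config.target_accept
                    )
                    tgtmask = cmask[:, None] & np.ones_like(acc, dtype=bool)
                    self.scales["z"][sub][tgtmask] += upd[tgtmask]
                else:
                    self.acc_n["z"] += float(np.sum(acc[cmask, :]))
                    self.acc_d["z"] += float(np.sum(cmask) * acc.shape[1])

    def _update_a(self):
        st = self.state
        s = self._sigma_of("a")  # (K,)
        three = st.a.ndim == 3
        h_range = range(3) if three else (None,)
        for h in h_range:
            sub = (slice(None), slice(None), h) if three else (Ellipsis,)
            old = st.a.copy()
            prop = old.copy()
            prop[sub] = old[sub] + self._noise("a", sub)
            st.a = prop
            eta_p = linear_predictor(self.spec, st, self.cov)
            d_site = self._ll_delta(eta_p).sum(axis=1)  # (I, K)
            pr = (old[sub] ** 2 - prop[sub] ** 2) / (2 * s[None, :] ** 2)
            acc = self._accept(d_site + pr)
            new = old.copy()
            new[sub] = np.where(acc, prop[sub], old[sub])
            st.a = new
            self.eta = self._patched(eta_p, acc[:, None, :])
            if self.adapting:
                if three:
                    self.scales["a"][:, :, h] += self.config.adapt_step * (
                        acc.astype(float) - self.config.target_accept
                    )
                else:
                    self.scales["a"] += self.config.adapt_step * (
                        acc.astype(float) - self.config.target_accept
                    )
            else:
                self.acc_n["a"] += float(np.sum(acc))
                self.acc_d["a"] += acc.size

    def _update_rho(self):
        st = self.state
        old = st.rho
        prop = old + self._noise("rho")
        if self.spec.variant == "Alt3a":
            s = self._sigma_of("rho")
            pr = (old**2 - prop**2) / (2 * s**2)
        else:  # Alt3b: Gamma(2, 1)
            with np.errstate(divide="ignore", invalid="ignore"):
                pr = np.where(
                    prop > 0, (np.log(prop) - prop) - (np.log(old) - old), -np.inf
                )
        ok = prop > 0 if self.spec.variant == "Alt3b" else np.ones_like(prop, bool)
        st.rho = np.where(ok, prop, old)
        eta_p = linear_predictor(self.spec, st, self.cov)
        d_site = self._ll_delta(eta_p).sum(axis=(0, 1))  # (K,)
        acc = self._accept(np.where(ok, d_site + pr, -np.inf))
        st.rho = np.where(acc, prop, old)
        self.eta = self._patched(eta_p, acc[None, None, :])
        self._adapt("rho", acc)

    # -- scale (sigma) updates ---------------------------------------------

    def _sigma_targets(self):
        """(family, SS array, rank array) triples for active families."""
        st, spec = self.state, self.spec
        out = []
        active = set(self.families)

        def icar_ss(x):
            e = self.graph.edges
            d = x[e[:, 0]] - x[e[:, 1]]
            return (d * d).sum(axis=0)

        if "alpha0" in active:
            out.append(("alpha0", np.sum(st.alpha0**2), st.alpha0.size))
        if {"beta_s", "beta_t", "beta_st"} & active:
            ss = sum(float((b * b).sum()) for b in (st.beta_s, st.beta_t, st.beta_st))
            n = st.beta_s.size + st.beta_t.size + st.beta_st.size
            if n:
                out.append(("beta", ss, n))
        if "u" in active:
            out.append(("u", (st.u**2).sum(axis=0), st.u.shape[0]))
        if "v" in active:
            rank = self.graph.I - self.graph.n_components()
            out.append(("v", icar_ss(st.v), rank))
        if "gamma" in active and st.gamma.shape[0] > 1:
            g = st.gamma if st.gamma.ndim == 2 else st.gamma[:, None]
            ss = float((np.diff(g, axis=0) ** 2).sum())
            out.append(("gamma", ss, g.shape[1] * (g.shape[0] - 1)))
        if "phi" in active:
            out.append(
                ("phi", (st.phi**2).sum(axis=(0, 1)), st.phi.shape[0] * st.phi.shape[1])
            )
        if "z" in active:
            rank = self.graph.I - self.graph.n_components()
            if st.z.ndim == 3:
                ss = np.stack([icar_ss(st.z[:, :, h]) for h in range(3)]).sum(axis=0)
                out.append(("z", ss, 3 * rank))
            else:
                out.append(("z", icar_ss(st.z), rank))
        if "a" in active:
            if st.a.ndim == 3:
                out.append(("a", (st.a**2).sum(axis=(0, 2)), 3 * st.a.shape[0]))
            else:
                out.append(("a", (st.a**2).sum(axis=0), st.a.shape[0]))
        if "rho" in active and spec.variant == "Alt3a":
            out.append(("rho", st.rho**2, 1))
        return out

    def _update_sigmas(self):
        for fam, ss, rank in self._sigma_targets():
            key = f"sigma_{fam}"
            old = np.asarray(self.state.sigma[fam], dtype=float)
            logp = np.log(old) + self._noise(key)
            prop = np.exp(logp)
            C = self.spec.C(fam)
            # conditional: sigma^-rank * exp(-SS / 2 sigma^2) on (0, C),
            # with the log-scale Jacobian sigma
            delta = (
                -(rank - 1) * (logp - np.log(old))
                - 0.5 * np.asarray(ss) * (1.0 / prop**2 - 1.0 / old**2)
            )
            delta = np.where(prop < C, delta, -np.inf)
            acc = self._accept(delta)
            new = np.where(acc, prop, old)
            self.state.sigma[fam] = new if old.ndim else float(new)
            self._adapt(key, np.asarray(acc).reshape(np.shape(self.scales[key])))

    # -- recentring (burn-in only) -----------------------------------------

    def _recenter(self):
        """Sum-to-zero recentring with likelihood-preserving compensation."""
        st, spec = self.state, self.spec
        changed_eta = False
        if "v" in self.families:
            m = st.v.mean()
            st.v = st.v - m
            st.u = st.u + m
        if "z" in self.families:
            m = st.z.mean(axis=0, keepdims=True)
            st.z = st.z - m
            st.a = st.a + m
        if "gamma" in self.families and st.gamma.shape[0] > 1:
            m = st.gamma.mean(axis=0, keepdims=True)
            if spec.variant == "Alt3b":
                pass  # level enters the likelihood through the power transform
            elif spec.three_component:
                st.gamma = st.gamma - m  # no exact partner; burn-in only
                changed_eta = True
            elif spec.variant == "Alt3a":
                st.gamma = st.gamma - m
                st.phi = st.phi + float(m.squeeze()) * st.rho[None, None, :]
            elif st.gamma.ndim == 2:
                st.gamma = st.gamma - m
                st.phi = st.phi + m[None, :, :]
            else:
                st.gamma = st.gamma - m
                st.phi = st.phi + float(m.squeeze())
        if changed_eta:
            self.eta = linear_predictor(spec, st, self.cov)

    # -- sweep --------------------------------------------------------------

    def sweep(self):
        updaters = {
            "alpha0": self._update_alpha0,
            "beta_s": lambda: self._update_beta_block("beta_s", "beta_s"),
            "beta_t": lambda: self._update_beta_block("beta_t", "beta_t"),
            "beta_st": lambda: self._update_beta_block("beta_st", "beta_st"),
            "u": self._update_u,
            "v": self._update_v,
            "gamma": self._update_gamma,
            "phi": self._update_phi,
            "z": self._update_z,
            "a": self._update_a,
            "rho": self._update_rho,
            "sigma": self._update_sigmas,
        }
        order = [f for f in self.families if f in updaters]
        if self.config.randomize_order:
            order = [order[i] for i in self.rng.permutation(len(order))]
        for fam in order:
            if fam == "rho" and self.state.rho is None:
                continue
            if fam in ("v", "z") and self.graph is None:
                raise ValueError(f"updating {fam!r} requires an adjacency graph")
            updaters[fam]()

    def pointwise_loglik(self):
        with np.errstate(over="ignore"):
            mu = self.e * np.exp(self.eta)
        y = self.y
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(y > 0, y * np.log(mu), 0.0) - mu - gammaln(y + 1.0)

    def draw_y_rep(self):
        with np.errstate(over="ignore"):
            mu = self.e * np.exp(self.eta)
        return self.rng.poisson(np.clip(mu, 0, 1e12))


# ---------------------------------------------------------------------------
# Driver
# ---------------------------------------------------------------------------

_RECORDED = (
    "alpha0", "beta_s", "beta_t", "beta_st", "u", "v", "gamma", "phi",
    "z", "a", "rho",
)


def run_mcmc(
    frame: StudyFrame,
    graph: AdjacencyGraph | None,
    cov: CovariateSet | None = None,
    spec: ModelSpec | None = None,
    config: McmcConfig | None = None,
    init_state: ParameterState | None = None,
) -> PosteriorSamples:
    """Run the Metropolis-within-Gibbs sampler.

    Requires an imputed frame with expected counts and standardized
    covariates.  Shared effects (v always; gamma except in Alt1) are stored
    once and used by every disease.  Reproducible bit-for-bit under
    (config.seed, config).
    """
    spec = spec if spec is not None else ModelSpec("Alt1", frame.K)
    config = config or McmcConfig()
    if frame.expected is None:
        raise ValueError("expected counts not computed; run preprocessing first")
    if frame.coded.any() and not frame.imputed:
        raise ValueError("frame contains threshold codes; impute before fitting")
    cov = cov if cov is not None else CovariateSet.empty(frame.I, frame.J)
    if cov.P != (0, 0, 0) and not cov.standardized:
        raise ValueError("covariates must be standardized before fitting")

    n_keep = config.n_samples // config.thin
    children = np.random.SeedSequence(config.seed).spawn(config.n_chains)
    draws: dict[str, list] = {}
    logliks, yreps = [], []
    acc_n: dict[str, float] = {}
    acc_d: dict[str, float] = {}

    for chain, child in enumerate(children):
        rng = np.random.Generator(np.random.PCG64(child))
        eng = _Sampler(spec, frame, graph, cov, config, rng, init_state)
        eng.adapting = True
        for t in range(config.n_burnin):
            eng.sweep()
            eng._recenter()
            if t % 200 == 199:  # refresh the patched cache against drift
                eng.eta = linear_predictor(spec, eng.state, cov)
        eng.adapting = False
        eng.eta = linear_predictor(spec, eng.state, cov)

        chain_draws: dict[str, list] = {}
        ll = np.empty((n_keep,) + frame.y.shape)
        yr = np.empty((n_keep,) + frame.y.shape, dtype=np.int64)
        kept = 0
        for t in range(config.n_samples):
            eng.sweep()
            if t % config.thin == 0 and kept < n_keep:
                st = eng.state
                for name in _RECORDED:
                    val = getattr(st, name)
                    if val is None or val.size == 0:
                        continue
                    chain_draws.setdefault(name, []).append(val.copy())
                for fam, s in st.sigma.items():
                    chain_draws.setdefault(f"sigma_{fam}", []).append(
                        np.array(s, copy=True)
                    )
                if config.prior_only:
                    ll[kept] = 0.0
                    yr[kept] = 0
                else:
                    ll[kept] = eng.pointwise_loglik()
                    yr[kept] = eng.draw_y_rep()
                kept += 1
        for name, lst in chain_draws.items():
            draws.setdefault(name, []).append(np.stack(lst))
        logliks.append(ll)
        yreps.append(yr)
        for k in eng.acc_n:
            acc_n[k] = acc_n.get(k, 0.0) + eng.acc_n[k]
            acc_d[k] = acc_d.get(k, 0.0) + eng.acc_d[k]

    accept = {k: (acc_n[k] / acc_d[k] if acc_d[k] else np.nan) for k in acc_n}
    return PosteriorSamples(
        draws={k: np.stack(v) for k, v in draws.items()},
        loglik=np.stack(logliks),
        y_rep=np.stack(yreps),
        accept_rates=accept,
        spec=spec,
        config=config,
        counties=frame.counties,
        years=frame.years,
        diseases=frame.diseases,
    )


# ---------------------------------------------------------------------------
# Convergence
# ---------------------------------------------------------------------------


def gelman_rubin(samples: PosteriorSamples, parameter: str) -> np.ndarray:
    """Potential scale reduction factor, elementwise for one family.

    Classic formula: with m chains of n draws, W the mean within-chain
    variance and B/n the variance of the chain means,
    Rhat = sqrt(((n-1)/n W + B/n) / W).  Identical chains give the
    statistic's no-variance limit sqrt((n-1)/n).
    """
    x = samples.draws[parameter]
    m, n = x.shape[:2]
    if m < 2:
        raise ValueError("Gelman-Rubin needs at least two chains")
    mean_c = x.mean(axis=1)
    W = x.var(axis=1, ddof=1).mean(axis=0)
    Bn = mean_c.var(axis=0, ddof=1)
    vhat = (n - 1) / n * W + Bn
    with np.errstate(divide="ignore", invalid="ignore"):
        rhat = np.sqrt(vhat / W)
    return np.where(W > 0, rhat, 1.0)


def rhat_table(samples: PosteriorSamples) -> pd.DataFrame:
    """Max Rhat per parameter family plus an overall convergence flag."""
    rows = {}
    for name in samples.draws:
        x = samples.draws[name]
        if x.ndim < 2 or x.shape[1] < 2:
            continue
        r = gelman_rubin(samples, name)
        rows[name] = float(np.nanmax(r))
    df = pd.DataFrame({"rhat_max": pd.Series(rows)})
    df["converged"] = df["rhat_max"] < 1.1
    return df
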
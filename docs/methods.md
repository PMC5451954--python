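# Methods note

This note records the modelling assumptions, parameterization, numerical
choices and known limitations of `stmix`. The README gives the overview;
this is the reference for anyone auditing or extending the implementation.

## 1. Likelihood and mixture structure

Counts are conditionally independent Poisson:

```
y_ijk | θ_ijk ~ Poisson(e_ijk · θ_ijk),    e_ijk = rate_k · n_ij,
log θ_ijk = α_0k + Σ_h p_ikh · M_ijkh,     Σ_h p_ikh = 1.
```

Indices: county `i = 1..I`, year `j = 1..J`, disease `k = 1..K` (K ≤ 3).
The expected counts `e` act as a fixed offset; they are computed from the
data (overall rate × population) and are not model parameters.

Component predictors:

- Spatial: `M_ijkS = x_i' β_kS + u_ik + v_i`.
- Temporal (three-component variant only): `M_ijkT = x_j' β_kT + γ_j`.
- Spatio-temporal: `M_ijkST = x_ij' β_jkST + [x_j' β_kT] + [g_jk] + φ_ijk`,
  where the bracketed temporal terms fold into this component in the
  two-component variants, and `g_jk` is the effective walk below.

Effective temporal walk `g_jk` by variant:

| Variant | `g_jk` |
|---|---|
| `F2PRED` | `γ_j` (shared) |
| `Alt1` | `γ_jk` if K > 1, else `γ_j` (identical to `F2PRED` at K = 1) |
| `Alt2` | `γ_j` in its own component |
| `Alt3a` | `ρ_k γ_j`, `ρ_k ~ Normal(0, σ_ρ²)` |
| `Alt3b` | `sign(γ_j)·\|γ_j\|^{ρ_k}`, `ρ_k ~ Gamma(2, 1)` |

`Alt3b`'s sign-preserving power is the identity at `ρ = 1`, maps 0 to 0,
and stays monotone for negative walk values where a plain real power would
be undefined. `Alt3a`/`Alt3b` require K ≥ 2 (with one disease the scaling
is unidentifiable from the walk's own scale).

Mixture weights. Two-component: `p_ikS = logistic(z_ik + a_ik)`,
`p_ikST = 1 − p_ikS`. Three-component: `q_ikh = logistic(z_ikh + a_ikh)`,
`p_ikh = q_ikh / Σ_h q_ikh` over `h ∈ {S, T, ST}`. `z` is an intrinsic-CAR
field per disease (per disease × component for `Alt2`), `a` iid Normal.
The logistic saturates safely at extreme logits; the three-component
normalization raises an error only in the (measure-zero) case that every
`q` underflows to exactly zero.

Spatio-temporal covariates get per-year coefficient vectors `β_jkST` by
default (`time_varying_beta_st=True`); a time-constant `β_kST` is
available.

## 2. Priors

- `α_0k ~ N(0, σ_α²)`, all `β ~ N(0, σ_β²)` (one shared `σ_β`).
- `u_ik ~ N(0, σ_uk²)`, `φ_ijk ~ N(0, σ_φk²)`, `a ~ N(0, σ_ak²)` — iid,
  with per-disease scales.
- `v` — intrinsic CAR (pairwise-difference kernel over adjacency edges),
  one field shared by all diseases; rank `I − c` with `c` the number of
  graph components.
- `z` — intrinsic CAR per disease (× component for `Alt2`), scale `σ_zk`.
- `γ` — first-order random walk, rank `J − 1` per column; one shared
  `σ_γ` even when `Alt1` has per-disease walks.
- Every scale: `σ ~ Uniform(0, C)`, C = 10 by default, configurable per
  family via `ModelSpec.sd_bound`.
- `Alt3a`: `ρ_k ~ N(0, σ_ρ²)` with `σ_ρ ~ U(0, C)`; `Alt3b`:
  `ρ_k ~ Gamma(2, 1)` (mean 2, support ρ > 0).

The ICAR and RW1 kernels include their σ-dependent normalizing exponent
`−rank·log σ`, so the scale parameters have exact conditionals; in a
prior-only run the sampled σ marginals are exactly Uniform(0, C) (verified
by test).

Isolated counties (no neighbours) are rejected at graph construction —
the ICAR conditional for such a county is undefined.

## 3. Identifiability

The intrinsic CAR and RW1 kernels are improper (invariant to level shifts)
and the additive pairs (u, v), (z, a), (γ, φ) are only identified through
their sums. The joint posterior is still proper: the intercept has a
proper prior and the mixture weights break the remaining flats. The
sampler therefore:

- runs **unconstrained exact Metropolis** during the sampling phase — no
  recentering, so recorded draws target the exact posterior;
- during **burn-in only**, periodically recenters each improper field and
  pushes the removed level into its additive partner with an exact,
  likelihood-preserving compensation (`v→u`, `z→a`, `γ→φ`; through the
  `ρ` scaling for `Alt3a`; no compensation exists for `Alt3b`'s nonlinear
  transform, so `Alt3b` skips it), which keeps the chains numerically
  anchored without biasing the retained draws.

Consequence: convergence diagnostics for *individual* fields in an
additive pair (e.g. `z` alone) can stay above 1.1 long after the
identified sums have mixed; judge convergence primarily on intercepts,
coefficients, scales and predictions.

## 4. Sampler

Adaptive random-walk Metropolis within Gibbs, vectorized:

- cell-level fields (`φ`) update all cells simultaneously — proposals at
  disjoint cells interact only through their own likelihood terms, so the
  accept/reject decisions factorize exactly;
- row/column fields (`u`, `a`, per-year `β_jST`, `γ`) update in
  axis-aligned blocks with the same factorization; `γ` uses even/odd
  index classes (RW1 neighbours interact), CAR fields (`v`, `z`) use
  greedy graph-coloring classes so that no two neighbours move together;
- scalars (`α_0k`, shared `β`, `ρ_k`) update one at a time;
- scales `σ` update on the log scale with the Jacobian correction,
  rejecting outside (0, C).

Each site keeps its own log proposal scale, adapted during burn-in by a
Robbins–Monro step (0.05) toward 0.44 acceptance and frozen afterwards, so
the sampling phase is a valid fixed-kernel Markov chain. The linear
predictor is cached and patched incrementally after each accepted block;
the cache is refreshed from scratch every 200 sweeps to stop rounding
drift. Chains are seeded from `SeedSequence(seed).spawn(n_chains)` (PCG64)
and runs are bit-for-bit reproducible.

Convergence is summarized by the classic Gelman–Rubin potential scale
reduction factor per parameter family (threshold 1.1); a cross-check
against `arviz` is part of the test suite.

## 5. Threshold imputation

For a cell coded with interval [lo, hi], the imputed count is an exact
inverse-CDF draw from Poisson(`e_ijk`) truncated to [lo, hi], with `e`
computed from the coded panel. If the interval's Poisson mass underflows
(< 1e-12, e.g. a tiny interval far in the tail), the draw falls back to a
uniform on the interval with a warning. After imputation, rates and
expected counts are recomputed so that `Σe = Σy` per disease again.
Imputation is a single pre-processing draw, not part of the MCMC — the
posterior conditions on the imputed panel.

## 6. Assessment

```
lppd  = Σ_cells log( mean_draws exp(ll) )      (log-sum-exp stabilized)
pWAIC = Σ_cells var_draws(ll)                  (ddof = 1)
WAIC  = −2 (lppd − pWAIC)
MSPE  = mean over draws × cells of (y_rep − y)²
```

`y_rep` are full posterior-predictive draws. Both measures are additive
over cells and therefore decompose exactly by disease and by year window;
per-disease WAICs sum to the all-disease WAIC (tested to 1e-10). The
standard error of a WAIC difference uses the paired cellwise convention
`se = sqrt(n · var(d_i))`; differences within ~2 SEs are treated as ties.

## 7. Synthetic data realism

Defaults mirror a state cancer registry: disease rates (1e-4, 3e-4, 8e-4)
per person-year, log-uniform county populations between 1e4 and 5e5
(constant over years), a rook-adjacency lattice. Under these defaults a
realistic fraction of cells (typically 20–60%, rate-dependent) falls into
the 1–9 range and gets threshold-coded. Generative fields are drawn from
the model's own priors — ICAR via the Laplacian eigenbasis (null direction
excluded, fields centered), RW1 as a centered cumulative sum — with fixed,
user-chosen regression coefficients so recovery can be scored. The
`recovery_harness` runs simulate → (censor + impute) → fit → score
replicates and flags (never drops) non-convergent fits.

## 8. Numerical choices

- Poisson log-pmf computed via `gammaln`; `y log μ` is defined as 0 when
  `y = 0` regardless of μ; non-finite Poisson means raise with the
  offending cell named.
- WAIC uses `scipy.special.logsumexp`; everything else is plain
  vectorized numpy.
- Covariates must be standardized (mean 0, sample SD 1) before fitting;
  the transform is invertible (`destandardize`) for reporting on the
  original scale.
- Seeds: every internal derivation uses `numpy.random.SeedSequence`
  spawning; derived integer seeds are reduced mod 2³¹ − 1.

## 9. Limitations

- Metropolis-within-Gibbs mixes slowly through the (u, v) spatial
  convolution and the mixture-logit pair; the default 45,000-iteration
  burn-in reflects that. Short demo runs will show PSRFs above 1.1 on
  individual random-effect fields (see §3).
- K is capped at 3 diseases; the mixture is over at most three
  components; adjacency must be a single connected component per county
  (isolated counties rejected).
- Threshold imputation is single-draw, so imputation uncertainty is not
  propagated into the posterior (run the pipeline across several
  imputation seeds to gauge its effect).
- The temporal walk is first-order only; no seasonal or higher-order
  temporal structure.
- WAIC and MSPE are in-sample pointwise criteria; no cross-validation is
  implemented.
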
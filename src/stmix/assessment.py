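"""Goodness-of-fit measures and posterior interpretation summaries.

Model comparison uses the Watanabe-Akaike information criterion computed
from the pointwise log-likelihood matrix over posterior draws,

    lppd   = sum_cells log( mean_draws exp(ll) )
    pWAIC  = sum_cells var_draws(ll)            (variance form)
    WAIC   = -2 (lppd - pWAIC),

together with the mean squared predictive error between
posterior-predictive count draws and the observed counts.  Both are
additive over cells, so they decompose exactly by disease and by year
window — the layout used to compare variants per disease over the full
study period and early/late sub-windows.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.special import logsumexp, expit

from .data_io import StudyFrame
from .inference import PosteriorSamples
from .model_family import ModelSpec, mixture_weights_three


@dataclasses.dataclass(frozen=True)
class FitMeasures:
    """One row of a fit table: measures for a disease subset and window."""

    waic: float
    p_waic: float
    mspe: float
    disease: str
    window: str

    def __post_init__(self) -> None:
        if not np.isfinite(self.waic):
            raise ValueError("non-finite WAIC")
        if self.p_waic < 0 or self.mspe < 0:
            raise ValueError("pWAIC and MSPE must be non-negative")


def waic(
    pointwise_loglik: np.ndarray, mask: np.ndarray | None = None
) -> tuple[float, float]:
    """WAIC and its effective-parameter count pWAIC.

    ``pointwise_loglik`` has draws on the first axis and cells on the
    remaining axes; ``mask`` (boolean, over the cell axes) restricts the
    computation to a subset of cells.  Computed with log-sum-exp
    stabilization; sample variances use ddof = 1.
    """
    ll = np.asarray(pointwise_loglik, dtype=float)
    n_draws = ll.shape[0]
    if n_draws < 2:
        raise ValueError("WAIC needs at least two posterior draws")
    ll = ll.reshape(n_draws, -1)
    if mask is not None:
        m = np.asarray(mask, dtype=bool).reshape(-1)
        if not m.any():
            raise ValueError("empty cell mask")
        ll = ll[:, m]
    lppd = float(np.sum(logsumexp(ll, axis=0) - np.log(n_draws)))
    p_waic = float(np.sum(ll.var(axis=0, ddof=1)))
    return -2.0 * (lppd - p_waic), p_waic


def mspe(
    y_rep: np.ndarray, y: np.ndarray, mask: np.ndarray | None = None
) -> float:
    """Mean squared predictive error over draws and selected cells.

    The expectation is over full posterior-predictive count draws, not a
    plug-in posterior-mean prediction; pass ``y_rep`` with the draw mean
    already taken (and a leading axis of 1) for the plug-in flavour.
    """
    y_rep = np.asarray(y_rep, dtype=float)
    n_draws = y_rep.shape[0]
    y_rep = y_rep.reshape(n_draws, -1)
    y = np.asarray(y, dtype=float).reshape(-1)
    if y_rep.shape[1] != y.size:
        raise ValueError("y_rep and y cell counts differ")
    if mask is not None:
        m = np.asarray(mask, dtype=bool).reshape(-1)
        if not m.any():
            raise ValueError("empty cell mask")
        y_rep, y = y_rep[:, m], y[m]
    return float(np.mean((y_rep - y[None, :]) ** 2))


def waic_difference_se(
    loglik_a: np.ndarray, loglik_b: np.ndarray
) -> tuple[float, float]:
    """WAIC difference (a - b) and its standard error.

    The SE follows the paired convention for pointwise criteria: with
    cellwise WAIC contributions d_i = waic_i(a) - waic_i(b) over n cells,
    se = sqrt(n * var(d_i)).  Two models whose |difference| is within a
    couple of SEs are statistically equivalent.
    """
    def cellwise(ll):
        ll = np.asarray(ll, dtype=float)
        n = ll.shape[0]
        ll = ll.reshape(n, -1)
        lppd_i = logsumexp(ll, axis=0) - np.log(n)
        p_i = ll.var(axis=0, ddof=1)
        return -2.0 * (lppd_i - p_i)

    da, db = cellwise(loglik_a), cellwise(loglik_b)
    if da.size != db.size:
        raise ValueError("models were evaluated on different cell sets")
    d = da - db
    return float(d.sum()), float(np.sqrt(d.size * d.var(ddof=1)))


def _window_mask(frame: StudyFrame, years: tuple[int, int]) -> np.ndarray:
    y0, y1 = years
    if y0 < frame.years.min() or y1 > frame.years.max() or y0 > y1:
        raise ValueError(
            f"window {years} outside study years "
            f"[{frame.years.min()}, {frame.years.max()}]"
        )
    sel = (frame.years >= y0) & (frame.years <= y1)
    mask = np.zeros((frame.I, frame.J, frame.K), dtype=bool)
    mask[:, sel, :] = True
    return mask


def fit_table(
    samples: PosteriorSamples,
    frame: StudyFrame,
    windows: dict[str, tuple[int, int]] | None = None,
    by_disease: bool = True,
) -> pd.DataFrame:
    """WAIC / pWAIC / MSPE for every disease x year-window combination.

    ``windows`` maps a label to an inclusive calendar-year range; by
    default the single full study window is used.  An ``all`` disease row
    aggregates every disease; because all measures are sums or means over
    disjoint cells, per-disease WAICs add up to the all-disease WAIC.
    """
    if windows is None:
        windows = {"full": (int(frame.years.min()), int(frame.years.max()))}
    ll = samples.loglik.reshape(-1, frame.I, frame.J, frame.K)
    yr = samples.y_rep.reshape(-1, frame.I, frame.J, frame.K)
    diseases = ["all"] + (list(frame.diseases) if by_disease and frame.K > 1 else [])
    rows = []
    for wname, span in windows.items():
        wmask = _window_mask(frame, span)
        for dz in diseases:
            mask = wmask.copy()
            if dz != "all":
                k = frame.diseases.index(dz)
                keep = np.zeros(frame.K, dtype=bool)
                keep[k] = True
                mask &= keep[None, None, :]
            w, p = waic(ll, mask)
            m = mspe(yr, frame.y, mask)
            rows.append(FitMeasures(w, p, m, dz, wname))
    return pd.DataFrame(
        [
            {
                "measure": meas,
                "disease": r.disease,
                "window": r.window,
                "value": getattr(r, attr),
            }
            for r in rows
            for meas, attr in (("WAIC", "waic"), ("pWAIC", "p_waic"), ("MSPE", "mspe"))
        ]
    )


def format_fit_table(table: pd.DataFrame) -> str:
    """Pretty text layout: one block per measure, windows as columns."""
    out = []
    for meas, sub in table.groupby("measure", sort=False):
        piv = sub.pivot(index="disease", columns="window", values="value")
        out.append(f"{meas}\n{piv.round(2).to_string()}")
    return "\n\n".join(out)


# ---------------------------------------------------------------------------
# Interpretation: total random component and mixture-weight shares
# ---------------------------------------------------------------------------


def mixture_weight_draws(samples: PosteriorSamples) -> np.ndarray:
    """Mixture-weight draws (total draws, I, K, H) from the logit fields."""
    z = samples.stacked("z")
    a = samples.stacked("a")
    if z.ndim == 4:  # three-component
        return mixture_weights_three(z, a)
    p_s = expit(z + a)
    return np.stack([p_s, 1.0 - p_s], axis=-1)


def random_component_summary(
    samples: PosteriorSamples,
    spec: ModelSpec | None = None,
    ci: float = 0.95,
) -> dict:
    """Posterior summary of the total random component per cell.

    For the three-component variant the summarized quantity is

        p_ikS (u_ik + v_i) + p_ikT gamma_j + p_ikST phi_ijk,

    the total confounding adjusted for by the fitted model; two-component
    variants use the analogous p_ikS (u_ik + v_i) + p_ikST (gamma + phi).
    Returns posterior means and central credible bounds per (i, j, k),
    plus posterior-mean mixture weights per (i, k) — interpretable as the
    share of risk variability each component explains (a county with
    weights 0.1/0.5/0.4 has 10% spatial, 50% temporal and 40%
    space-time-explained variability).
    """
    spec = spec if spec is not None else samples.spec
    u = samples.stacked("u")  # (D, I, K)
    v = samples.stacked("v")  # (D, I)
    gamma = samples.stacked("gamma")  # (D, J) or (D, J, K)
    phi = samples.stacked("phi")  # (D, I, J, K)
    p = mixture_weight_draws(samples)  # (D, I, K, H)
    sp = u + v[:, :, None]  # (D, I, K)
    if gamma.ndim == 2:
        g = gamma[:, :, None]  # (D, J, 1) broadcast over k
    else:
        g = gamma
    if spec.has_rho:
        rho = samples.stacked("rho")  # (D, K)
        if spec.variant == "Alt3a":
            g = rho[:, None, :] * g
        else:
            g = np.sign(g) * np.abs(g) ** rho[:, None, :]
    if spec.three_component:
        total = (
            p[:, :, None, :, 0] * sp[:, :, None, :]
            + p[:, :, None, :, 1] * g[:, None, :, :]
            + p[:, :, None, :, 2] * phi
        )
    else:
        total = p[:, :, None, :, 0] * sp[:, :, None, :] + p[:, :, None, :, 1] * (
            g[:, None, :, :] + phi
        )
    lo = (1 - ci) / 2
    return {
        "mean": total.mean(axis=0),
        "lower": np.quantile(total, lo, axis=0),
        "upper": np.quantile(total, 1 - lo, axis=0),
        "weight_mean": p.mean(axis=0),  # (I, K, H)
    }
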
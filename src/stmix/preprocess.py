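"""Threshold imputation, overall rates, expected counts and SIRs.

Registry data often arrive with small counts *threshold-coded*: a count in
1-4 is reported as 5 and a count in 5-9 as 10, to protect privacy.  The
pipeline here undoes that coding in two passes:

1. compute a per-disease overall rate and expected counts *from the coded
   values*, and
2. replace each coded cell by a draw from a Poisson distribution with that
   expected count as mean, truncated to the code's interval, then recompute
   the rate and expected counts from the imputed panel.

The recomputed expected counts are the ones used as the offset in model
fitting; the standardized incidence ratio is SIR = y / e.
"""

from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path

import numpy as np
import yaml
from scipy import stats

from .data_io import DataError, StudyFrame


@dataclasses.dataclass(frozen=True)
class ThresholdScheme:
    """Mapping from sentinel codes to censoring intervals.

    ``intervals`` is a list of (code, lower, upper) triples: a true count in
    [lower, upper] is reported as ``code``.  Intervals must be disjoint and
    codes distinct.
    """

    intervals: tuple[tuple[int, int, int], ...] = ((5, 1, 4), (10, 5, 9))

    def __post_init__(self) -> None:
        codes = [c for c, _, _ in self.intervals]
        if len(set(codes)) != len(codes):
            raise ValueError("duplicate threshold codes")
        spans = []
        for code, lo, hi in self.intervals:
            if lo > hi:
                raise ValueError(f"code {code}: lower {lo} > upper {hi}")
            spans.append((lo, hi))
        spans.sort()
        for (l0, h0), (l1, h1) in zip(spans, spans[1:]):
            if l1 <= h0:
                raise ValueError("overlapping threshold intervals")

    def interval(self, code: int) -> tuple[int, int]:
        for c, lo, hi in self.intervals:
            if c == code:
                return lo, hi
        raise KeyError(f"unknown threshold code {code}")

    @classmethod
    def default(cls) -> "ThresholdScheme":
        return cls()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ThresholdScheme":
        raw = yaml.safe_load(Path(path).read_text())
        return cls(
            tuple((int(d["code"]), int(d["lower"]), int(d["upper"])) for d in raw)
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(
                [
                    {"code": c, "lower": lo, "upper": hi}
                    for c, lo, hi in self.intervals
                ]
            )
        )


def overall_rate(frame: StudyFrame, disease: str | int) -> float:
    """Overall disease rate: total incidence over total person-years.

    Coded cells contribute their sentinel value as-is; this is the rate
    used to parameterize the truncated-Poisson imputation.
    """
    k = disease if isinstance(disease, int) else frame.diseases.index(str(disease))
    total_pop = float(frame.population.sum())
    if total_pop <= 0:
        raise DataError("zero total population at risk")
    return float(frame.y[:, :, k].sum()) / total_pop


def expected_counts(
    frame: StudyFrame, rates: np.ndarray | list[float] | None = None
) -> StudyFrame:
    """Attach expected counts e_ijk = rate_k * n_ij.

    If ``rates`` is omitted, per-disease overall rates are computed from
    the frame itself, in which case sum(e) equals sum(y) per disease.
    """
    if rates is None:
        rates = [overall_rate(frame, k) for k in range(frame.K)]
    rates = np.asarray(rates, dtype=float)
    if rates.shape != (frame.K,):
        raise DataError(f"need {frame.K} rates, got shape {rates.shape}")
    if np.any(rates < 0):
        raise DataError("negative disease rate")
    out = frame.copy()
    out.expected = rates[None, None, :] * frame.population[:, :, None]
    return out


def _truncated_poisson_draw(
    rng: np.random.Generator, mean: float, lo: int, hi: int
) -> int:
    """Exact inverse-CDF draw from Poisson(mean) truncated to [lo, hi]."""
    support = np.arange(lo, hi + 1)
    pmf = stats.poisson.pmf(support, mean)
    total = pmf.sum()
    if total < 1e-12:
        warnings.warn(
            f"truncated Poisson support mass {total:.2e} at mean {mean:.3g} "
            f"on [{lo},{hi}]; falling back to a uniform draw",
            stacklevel=2,
        )
        return int(rng.integers(lo, hi + 1))
    u = rng.uniform(0.0, total)
    return int(support[np.searchsorted(np.cumsum(pmf), u)])


def impute_thresholded(
    frame: StudyFrame,
    scheme: ThresholdScheme | None = None,
    seed: int | np.random.Generator = 0,
) -> StudyFrame:
    """Replace threshold-coded cells by truncated-Poisson draws.

    Each coded cell with code interval [lo, hi] is replaced by a draw from
    Poisson(e_ijk) truncated to [lo, hi], where e_ijk is the cell's
    expected count computed from the coded panel.  Uncoded cells are left
    bit-identical.  Deterministic under ``seed``.
    """
    scheme = scheme or ThresholdScheme.default()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    work = frame if frame.expected is not None else expected_counts(frame)
    out = work.copy()
    cells = np.argwhere(frame.coded)
    for i, j, k in cells:
        lo, hi = scheme.interval(int(frame.y[i, j, k]))
        out.y[i, j, k] = _truncated_poisson_draw(
            rng, float(work.expected[i, j, k]), lo, hi
        )
    out.coded = frame.coded.copy()  # provenance: which cells were imputed
    out.imputed = True
    return out


def recompute_expected(frame: StudyFrame) -> StudyFrame:
    """Recompute overall rates and expected counts from imputed counts.

    These post-imputation expected counts are the offset used for model
    fitting; per disease they conserve the total, sum(e) = sum(y).
    """
    return expected_counts(frame, rates=None)


def compute_sir(frame: StudyFrame) -> np.ndarray:
    """Standardized incidence ratio SIR_ijk = y_ijk / e_ijk.

    A value of 1 means the observed incidence equals the expected count.
    """
    if frame.expected is None:
        raise DataError("expected counts not computed; call expected_counts first")
    if np.any(frame.expected <= 0):
        i, j, k = np.argwhere(frame.expected <= 0)[0]
        raise DataError(
            f"non-positive expected count at county {frame.counties[i]!r}, "
            f"year {frame.years[j]}, disease {frame.diseases[k]!r}"
        )
    return frame.y / frame.expected


def truncated_poisson_pmf(mean: float, lo: int, hi: int) -> np.ndarray:
    """Exact pmf of Poisson(mean) truncated to [lo, hi] (oracle helper)."""
    support = np.arange(lo, hi + 1)
    pmf = stats.poisson.pmf(support, mean)
    return pmf / pmf.sum()
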
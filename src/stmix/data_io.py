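"""Reading, writing and validation of count panels, covariates and adjacency.

The central containers are :class:`StudyFrame` (a complete county x year x
disease panel of counts, populations and expected counts),
:class:`AdjacencyGraph` (a symmetric county neighbourhood structure that
drives the intrinsic CAR priors) and :class:`CovariateSet` (spatial,
temporal and spatio-temporal design matrices).

Counts may arrive *threshold-coded*: the data provider recodes small counts
onto sentinel values (e.g. 1-4 -> 5, 5-9 -> 10).  A boolean ``coded`` mask
travels with the counts so that downstream code can never silently treat a
sentinel as a true count; see :mod:`stmix.preprocess` for the imputation
that undoes the coding.
"""

from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp


class DataError(ValueError):
    """Raised for malformed or inconsistent input data."""


# ---------------------------------------------------------------------------
# StudyFrame
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class StudyFrame:
    """A complete I x J x K panel of disease counts.

    Parameters
    ----------
    counties
        I county labels, in panel row order.
    years
        J consecutive calendar years.
    diseases
        K disease labels, K in {1, 2, 3}.
    y
        Integer counts (or threshold codes where ``coded`` is True),
        shape (I, J, K).
    population
        Population at risk per county-year, shape (I, J), strictly positive.
    coded
        Boolean mask of threshold-coded cells, shape (I, J, K).
    expected
        Expected counts e_ijk (optional until computed), shape (I, J, K).
    imputed
        True once threshold codes have been replaced by imputed counts.
    """

    counties: list[str]
    years: np.ndarray
    diseases: list[str]
    y: np.ndarray
    population: np.ndarray
    coded: np.ndarray | None = None
    expected: np.ndarray | None = None
    imputed: bool = False

    def __post_init__(self) -> None:
        self.counties = [str(c) for c in self.counties]
        self.diseases = [str(d) for d in self.diseases]
        self.years = np.asarray(self.years, dtype=int)
        self.y = np.asarray(self.y)
        self.population = np.asarray(self.population)
        I, J, K = len(self.counties), len(self.years), len(self.diseases)
        if self.y.shape != (I, J, K):
            raise DataError(f"counts shape {self.y.shape} != {(I, J, K)}")
        if self.population.shape != (I, J):
            raise DataError(f"population shape {self.population.shape} != {(I, J)}")
        if self.coded is None:
            self.coded = np.zeros((I, J, K), dtype=bool)
        self.coded = np.asarray(self.coded, dtype=bool)
        if self.coded.shape != (I, J, K):
            raise DataError("coded mask shape mismatch")
        if J > 1 and not np.all(np.diff(self.years) == 1):
            raise DataError(f"years must be consecutive, got {self.years.tolist()}")
        if np.any(self.population <= 0):
            i, j = np.argwhere(self.population <= 0)[0]
            raise DataError(
                f"non-positive population for county {self.counties[i]!r}, "
                f"year {self.years[j]}"
            )
        if np.any(self.y < 0):
            i, j, k = np.argwhere(self.y < 0)[0]
            raise DataError(
                f"negative count at county {self.counties[i]!r}, year "
                f"{self.years[j]}, disease {self.diseases[k]!r}"
            )
        if self.expected is not None:
            self.expected = np.asarray(self.expected, dtype=float)
            if self.expected.shape != (I, J, K):
                raise DataError("expected counts shape mismatch")

    # -- basic geometry -----------------------------------------------------

    @property
    def I(self) -> int:  # noqa: E743 - field-standard index letter
        return len(self.counties)

    @property
    def J(self) -> int:
        return len(self.years)

    @property
    def K(self) -> int:
        return len(self.diseases)

    def copy(self) -> "StudyFrame":
        return StudyFrame(
            counties=list(self.counties),
            years=self.years.copy(),
            diseases=list(self.diseases),
            y=self.y.copy(),
            population=self.population.copy(),
            coded=self.coded.copy(),
            expected=None if self.expected is None else self.expected.copy(),
            imputed=self.imputed,
        )

    def to_long(self) -> pd.DataFrame:
        """Long-format DataFrame with one row per (county, year, disease)."""
        I, J, K = self.I, self.J, self.K
        idx = pd.MultiIndex.from_product(
            [self.counties, self.years, self.diseases],
            names=["county", "year", "disease"],
        )
        df = pd.DataFrame(index=idx).reset_index()
        df["count"] = self.y.reshape(-1)
        df["population"] = np.repeat(self.population.reshape(-1), K)
        df["coded"] = self.coded.reshape(-1).astype(int)
        df["imputed"] = int(self.imputed)
        if self.expected is not None:
            df["expected"] = self.expected.reshape(-1)
        return df


def read_counts(path: str | Path) -> StudyFrame:
    """Read a long-format count panel CSV into a :class:`StudyFrame`.

    Required columns: ``county, year, disease, count, population``; an
    optional ``coded`` column (0/1) marks threshold-coded cells.  The file
    must describe a complete county x year x disease grid.
    """
    df = pd.read_csv(path)
    required = {"county", "year", "disease", "count", "population"}
    missing = required - set(df.columns)
    if missing:
        raise DataError(f"counts file missing columns: {sorted(missing)}")
    df["county"] = df["county"].astype(str)
    df["disease"] = df["disease"].astype(str)

    dup = df.duplicated(subset=["county", "year", "disease"])
    if dup.any():
        r = df[dup].iloc[0]
        raise DataError(
            f"duplicate cell: county {r['county']!r}, year {r['year']}, "
            f"disease {r['disease']!r}"
        )

    counties = sorted(df["county"].unique())
    years = np.sort(df["year"].unique().astype(int))
    diseases = sorted(df["disease"].unique())
    I, J, K = len(counties), len(years), len(diseases)
    if len(df) != I * J * K:
        full = pd.MultiIndex.from_product(
            [counties, years, diseases], names=["county", "year", "disease"]
        )
        have = pd.MultiIndex.from_frame(df[["county", "year", "disease"]])
        absent = full.difference(have)
        c, yr, d = absent[0]
        raise DataError(
            f"missing cell: county {c!r}, year {yr}, disease {d!r} "
            f"({len(absent)} cells absent)"
        )

    ci = {c: i for i, c in enumerate(counties)}
    yi = {int(y): j for j, y in enumerate(years)}
    di = {d: k for k, d in enumerate(diseases)}
    ii = df["county"].map(ci).to_numpy()
    jj = df["year"].astype(int).map(yi).to_numpy()
    kk = df["disease"].map(di).to_numpy()

    y = np.zeros((I, J, K), dtype=int)
    y[ii, jj, kk] = df["count"].to_numpy()
    coded = np.zeros((I, J, K), dtype=bool)
    if "coded" in df.columns:
        coded[ii, jj, kk] = df["coded"].to_numpy().astype(bool)

    pop = np.full((I, J), -1.0)
    pop[ii, jj] = df["population"].to_numpy()
    # population consistency across diseases within a county-year
    chk = df.groupby(["county", "year"])["population"].nunique()
    if (chk > 1).any():
        c, yr = chk[chk > 1].index[0]
        raise DataError(f"inconsistent population for county {c!r}, year {yr}")

    expected = None
    if "expected" in df.columns:
        expected = np.zeros((I, J, K))
        expected[ii, jj, kk] = df["expected"].to_numpy()

    imputed = bool(df["imputed"].any()) if "imputed" in df.columns else False
    return StudyFrame(counties, years, diseases, y, pop, coded, expected, imputed)


def write_counts(frame: StudyFrame, path: str | Path) -> None:
    """Write a :class:`StudyFrame` as a long-format CSV (round-trips)."""
    frame.to_long().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# AdjacencyGraph
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class AdjacencyGraph:
    """Symmetric neighbourhood structure over counties.

    ``edges`` holds each unordered neighbour pair once as integer index
    pairs (i, l) with i < l into ``counties``.  Every county must have at
    least one neighbour; isolated counties break the intrinsic CAR prior
    and are rejected at construction.
    """

    counties: list[str]
    edges: np.ndarray  # (E, 2) int, i < l, unique

    def __post_init__(self) -> None:
        self.counties = [str(c) for c in self.counties]
        e = np.asarray(self.edges, dtype=int).reshape(-1, 2)
        e = np.sort(e, axis=1)
        e = np.unique(e, axis=0)
        if len(e) and (e[:, 0] == e[:, 1]).any():
            raise DataError("self-edge in adjacency")
        self.edges = e
        I = len(self.counties)
        if len(e) and e.max() >= I:
            raise DataError("edge index out of range")
        n = np.zeros(I, dtype=int)
        np.add.at(n, e.reshape(-1), 1)
        if (n == 0).any():
            bad = self.counties[int(np.argmax(n == 0))]
            raise DataError(f"isolated county {bad!r} (no neighbours)")
        self.n_neighbors = n
        rows = np.concatenate([e[:, 0], e[:, 1]])
        cols = np.concatenate([e[:, 1], e[:, 0]])
        self.W = sp.csr_matrix(
            (np.ones(len(rows)), (rows, cols)), shape=(I, I)
        )

    @property
    def I(self) -> int:  # noqa: E743
        return len(self.counties)

    def neighbor_sum(self, x: np.ndarray) -> np.ndarray:
        """Sum of x over neighbours, applied along the first axis."""
        return self.W @ x

    def n_components(self) -> int:
        ncomp, _ = sp.csgraph.connected_components(self.W, directed=False)
        return int(ncomp)

    def color_classes(self) -> list[np.ndarray]:
        """Greedy proper colouring; returns boolean masks per colour.

        Nodes in one class are mutually non-adjacent, so they can be
        Metropolis-updated simultaneously under a Markov random field prior.
        """
        I = self.I
        color = np.full(I, -1, dtype=int)
        indptr, indices = self.W.indptr, self.W.indices
        for i in range(I):
            used = {color[l] for l in indices[indptr[i] : indptr[i + 1]]}
            c = 0
            while c in used:
                c += 1
            color[i] = c
        return [color == c for c in range(color.max() + 1)]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AdjacencyGraph):
            return NotImplemented
        return self.counties == other.counties and np.array_equal(
            self.edges, other.edges
        )


def _edges_from_pairs(
    pairs: Sequence[tuple[str, str]], counties: list[str]
) -> np.ndarray:
    idx = {c: i for i, c in enumerate(counties)}
    return np.array([[idx[a], idx[b]] for a, b in pairs], dtype=int)


def read_adjacency(
    path: str | Path, counties: Sequence[str] | None = None
) -> AdjacencyGraph:
    """Read adjacency from a GAL file or a two-column edge list.

    The format is auto-detected: GAL files start with a header whose first
    or second token is the county count followed by id/neighbour-list line
    pairs; anything else is parsed as one edge per line (two labels,
    whitespace or comma separated).  An edge list that is not symmetric is
    symmetrised with a warning.  If ``counties`` is given, the file must
    cover exactly those labels (a county absent from the file would be
    isolated, which is an error).
    """
    text = Path(path).read_text().strip()
    lines = [ln.strip() for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise DataError(f"empty adjacency file {path}")

    pairs: list[tuple[str, str]] = []
    labels: list[str] = []
    header = lines[0].replace(",", " ").split()
    is_gal = False
    if len(header) in (1, 4) and header[0].isdigit():
        # "I" or "0 I <file> <key>" style GAL header
        n_declared = int(header[0]) if len(header) == 1 else int(header[1])
        body = lines[1:]
        if len(body) == 2 * n_declared:
            is_gal = True
            directed_pairs = []
            for r in range(n_declared):
                head = body[2 * r].split()
                node, deg = head[0], int(head[1])
                labels.append(node)
                nbrs = body[2 * r + 1].split()
                if len(nbrs) != deg:
                    raise DataError(
                        f"GAL entry for {node!r} declares {deg} neighbours, "
                        f"lists {len(nbrs)}"
                    )
                if deg == 0:
                    raise DataError(f"isolated county {node!r} (no neighbours)")
                directed_pairs.extend((node, nb) for nb in nbrs)
            pairs = directed_pairs
    if not is_gal:
        for ln in lines:
            toks = ln.replace(",", " ").split()
            if len(toks) != 2:
                raise DataError(f"bad edge-list line: {ln!r}")
            pairs.append((toks[0], toks[1]))
        seen = set(pairs)
        asym = [(a, b) for a, b in pairs if (b, a) not in seen]
        if asym:
            warnings.warn(
                f"edge list not symmetric; symmetrising {len(asym)} edge(s)",
                stacklevel=2,
            )
        for a, b in pairs:
            labels.extend((a, b))
        labels = list(dict.fromkeys(labels))

    if counties is not None:
        counties = [str(c) for c in counties]
        extra = set(labels) - set(counties)
        if extra:
            raise DataError(f"adjacency mentions unknown counties: {sorted(extra)}")
        absent = set(counties) - set(labels)
        if absent:
            raise DataError(
                f"isolated county {sorted(absent)[0]!r} (absent from adjacency)"
            )
        order = counties
    else:
        order = sorted(labels) if not is_gal else labels
    return AdjacencyGraph(list(order), _edges_from_pairs(pairs, list(order)))


def write_adjacency(
    graph: AdjacencyGraph, path: str | Path, fmt: str = "gal"
) -> None:
    """Write adjacency as GAL (default) or an edge list (both directions)."""
    out: list[str] = []
    if fmt == "gal":
        out.append(str(graph.I))
        indptr, indices = graph.W.indptr, graph.W.indices
        for i, c in enumerate(graph.counties):
            nbrs = [graph.counties[l] for l in indices[indptr[i] : indptr[i + 1]]]
            out.append(f"{c} {len(nbrs)}")
            out.append(" ".join(nbrs))
    elif fmt == "edgelist":
        for i, l in graph.edges:
            out.append(f"{graph.counties[i]} {graph.counties[l]}")
            out.append(f"{graph.counties[l]} {graph.counties[i]}")
    else:
        raise ValueError(f"unknown adjacency format {fmt!r}")
    Path(path).write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# CovariateSet
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class CovariateSet:
    """Spatial (I x P_S), temporal (J x P_T) and spatio-temporal
    (I x J x P_ST) design matrices, row-aligned with a StudyFrame.

    Any block may be empty (P = 0).  ``standardize`` scales each column to
    mean 0 and sample SD 1 over its own index set, storing the centre and
    scale so the transformation can be inverted.
    """

    x_spatial: np.ndarray  # (I, P_S)
    x_temporal: np.ndarray  # (J, P_T)
    x_st: np.ndarray  # (I, J, P_ST)
    names_spatial: list[str] = dataclasses.field(default_factory=list)
    names_temporal: list[str] = dataclasses.field(default_factory=list)
    names_st: list[str] = dataclasses.field(default_factory=list)
    standardized: bool = False
    _center: dict | None = None
    _scale: dict | None = None

    def __post_init__(self) -> None:
        self.x_spatial = np.atleast_2d(np.asarray(self.x_spatial, dtype=float))
        self.x_temporal = np.atleast_2d(np.asarray(self.x_temporal, dtype=float))
        self.x_st = np.asarray(self.x_st, dtype=float)
        if self.x_st.ndim != 3:
            raise DataError("spatio-temporal covariates must be (I, J, P_ST)")
        if not self.names_spatial:
            self.names_spatial = [f"xs{p}" for p in range(self.x_spatial.shape[1])]
        if not self.names_temporal:
            self.names_temporal = [f"xt{p}" for p in range(self.x_temporal.shape[1])]
        if not self.names_st:
            self.names_st = [f"xst{p}" for p in range(self.x_st.shape[2])]

    @classmethod
    def empty(cls, I: int, J: int) -> "CovariateSet":
        """A covariate set with no predictors (all P = 0)."""
        return cls(
            np.zeros((I, 0)), np.zeros((J, 0)), np.zeros((I, J, 0)),
            standardized=True,
        )

    @property
    def P(self) -> tuple[int, int, int]:
        return (
            self.x_spatial.shape[1],
            self.x_temporal.shape[1],
            self.x_st.shape[2],
        )

    def standardize(self) -> "CovariateSet":
        """Return a standardized copy (each column mean 0, sample SD 1)."""
        if self.standardized:
            raise DataError("covariates already standardized")
        center, scale = {}, {}

        def _std(x2d, names, block):
            m = x2d.mean(axis=0)
            s = x2d.std(axis=0, ddof=1) if x2d.shape[0] > 1 else np.ones(x2d.shape[1])
            zero = np.isclose(s, 0)
            if zero.any():
                raise DataError(
                    f"zero-variance covariate column {names[int(np.argmax(zero))]!r}"
                )
            center[block], scale[block] = m, s
            return (x2d - m) / s

        xs = _std(self.x_spatial, self.names_spatial, "spatial")
        xt = _std(self.x_temporal, self.names_temporal, "temporal")
        I, J, P = self.x_st.shape
        xst = _std(self.x_st.reshape(I * J, P), self.names_st, "st").reshape(I, J, P)
        return CovariateSet(
            xs, xt, xst,
            list(self.names_spatial), list(self.names_temporal), list(self.names_st),
            standardized=True, _center=center, _scale=scale,
        )

    def destandardize(self) -> "CovariateSet":
        """Invert :meth:`standardize` using the stored centre and scale."""
        if not self.standardized or self._center is None:
            raise DataError("covariates were not standardized by this package")
        c, s = self._center, self._scale
        I, J, P = self.x_st.shape
        return CovariateSet(
            self.x_spatial * s["spatial"] + c["spatial"],
            self.x_temporal * s["temporal"] + c["temporal"],
            (self.x_st.reshape(I * J, P) * s["st"] + c["st"]).reshape(I, J, P),
            list(self.names_spatial), list(self.names_temporal), list(self.names_st),
            standardized=False,
        )


def read_covariates(
    counties: Sequence[str],
    years: Sequence[int],
    spatial: str | Path | None = None,
    temporal: str | Path | None = None,
    st: str | Path | None = None,
) -> CovariateSet:
    """Read covariate CSVs keyed by county and/or year.

    Spatial files have a ``county`` column, temporal files a ``year``
    column, spatio-temporal files both; remaining columns are predictors.
    Missing rows for any requested county/year are an error.
    """
    counties = [str(c) for c in counties]
    years = [int(y) for y in years]
    I, J = len(counties), len(years)

    def _aligned(path, keys, labels):
        df = pd.read_csv(path)
        for k in keys:
            if k not in df.columns:
                raise DataError(f"covariate file {path} missing column {k!r}")
        if "county" in keys:
            df["county"] = df["county"].astype(str)
        df = df.set_index(keys)
        try:
            df = df.loc[labels]
        except KeyError as exc:
            raise DataError(f"covariate file {path} missing rows: {exc}") from exc
        return df

    if spatial is not None:
        df = _aligned(spatial, ["county"], counties)
        xs, ns = df.to_numpy(float), list(df.columns)
    else:
        xs, ns = np.zeros((I, 0)), []
    if temporal is not None:
        df = _aligned(temporal, ["year"], years)
        xt, nt = df.to_numpy(float), list(df.columns)
    else:
        xt, nt = np.zeros((J, 0)), []
    if st is not None:
        idx = pd.MultiIndex.from_product([counties, years])
        df = _aligned(st, ["county", "year"], idx)
        xst = df.to_numpy(float).reshape(I, J, -1)
        nst = list(df.columns)
    else:
        xst, nst = np.zeros((I, J, 0)), []
    return CovariateSet(xs, xt, xst, ns, nt, nst)


def write_covariates(
    cov: CovariateSet,
    counties: Sequence[str],
    years: Sequence[int],
    spatial: str | Path | None = None,
    temporal: str | Path | None = None,
    st: str | Path | None = None,
) -> None:
    """Write covariate blocks to CSVs (inverse of :func:`read_covariates`)."""
    if spatial is not None:
        pd.DataFrame(cov.x_spatial, columns=cov.names_spatial).assign(
            county=list(counties)
        ).to_csv(spatial, index=False)
    if temporal is not None:
        pd.DataFrame(cov.x_temporal, columns=cov.names_temporal).assign(
            year=list(years)
        ).to_csv(temporal, index=False)
    if st is not None:
        I, J, P = cov.x_st.shape
        df = pd.DataFrame(cov.x_st.reshape(I * J, P), columns=cov.names_st)
        df["county"] = np.repeat(list(counties), J)
        df["year"] = np.tile(list(years), I)
        df.to_csv(st, index=False)
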
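"""Genome scans with a fixed covariance matrix.

The polygenic/residual covariance is estimated once under the no-QTL null
and then held fixed; each locus is tested by generalized least squares in
the whitened space (one Cholesky factorization, shared by every locus).
The per-locus statistic is the Gaussian likelihood-ratio
``LRT = n log(RSS0 / RSS1)`` comparing the covariate-only model with the
model adding the locus coding; ``LOD = LRT / (2 ln 10)`` and p-values come
from the chi-square with as many degrees of freedom as locus terms fitted
(2 for additive+dominance, 1 for additive only).

Also here: the Haldane map function, Haley-Knott genotype probabilities
for interval mapping with biallelic markers, two-locus epistasis scans and
forward step-wise multiple-QTL mapping.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, stats

__all__ = [
    "GenomeMap",
    "GenotypeData",
    "ScanResult",
    "haldane",
    "genotype_probabilities",
    "scan_one",
    "scan_two",
    "forward_multiple_qtl",
]

_2LN10 = 2.0 * np.log(10.0)
_DEG_TOL = 1e-10


def haldane(d):
    """Haldane map function: distance in cM -> recombination fraction.

    ``r = (1 - exp(-2 d / 100)) / 2``; assumes no crossover interference.
    """
    d = np.asarray(d, float)
    if np.any(d < 0):
        raise ValueError("map distance must be non-negative")
    r = 0.5 * (1.0 - np.exp(-2.0 * d / 100.0))
    return float(r) if r.ndim == 0 else r


@dataclass
class GenomeMap:
    """Ordered marker map: name, chromosome, position (cM)."""

    table: pd.DataFrame

    def __post_init__(self):
        t = self.table
        cols = {c.lower(): c for c in t.columns}
        for req in ("marker", "chrom", "pos_cm"):
            alt = {"chrom": ("chrom", "chromosome", "chr"),
                   "pos_cm": ("pos_cm", "pos", "position", "cm"),
                   "marker": ("marker", "name", "snp")}[req]
            hit = next((cols[a] for a in alt if a in cols), None)
            if hit is None:
                raise ValueError(f"genetic map is missing a {req!r} column")
            if hit != req:
                t = t.rename(columns={hit: req})
        t = t[["marker", "chrom", "pos_cm"]].copy()
        t["marker"] = t["marker"].astype(str)
        t["chrom"] = t["chrom"].astype(str)
        t["pos_cm"] = t["pos_cm"].astype(float)
        if t["marker"].duplicated().any():
            dup = sorted(t.loc[t["marker"].duplicated(), "marker"].unique())
            raise ValueError(f"duplicate marker name(s) in map: {dup}")
        if not np.all(np.isfinite(t["pos_cm"])):
            raise ValueError("non-finite marker position in map")
        for c, grp in t.groupby("chrom", sort=False):
            if not np.all(np.diff(grp["pos_cm"].to_numpy()) >= 0):
                raise ValueError(f"marker positions not nondecreasing on chromosome {c}")
        self.table = t.reset_index(drop=True)

    @property
    def markers(self) -> list:
        return self.table["marker"].tolist()

    @property
    def n_markers(self) -> int:
        return len(self.table)

    def chromosomes(self) -> list:
        return list(dict.fromkeys(self.table["chrom"]))

    def chrom_slices(self) -> dict:
        out = {}
        for c in self.chromosomes():
            idx = np.where(self.table["chrom"].to_numpy() == c)[0]
            out[c] = idx
        return out


@dataclass
class GenotypeData:
    """Individuals x biallelic markers, coded 0/1/2 = allele count, NaN missing."""

    ids: list
    markers: list
    matrix: np.ndarray

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, float)
        if self.matrix.shape != (len(self.ids), len(self.markers)):
            raise ValueError("genotype matrix shape does not match ids x markers")
        ok = np.isnan(self.matrix) | np.isin(self.matrix, (0.0, 1.0, 2.0))
        if not ok.all():
            bad = np.argwhere(~ok)[0]
            raise ValueError(
                f"invalid genotype value {self.matrix[tuple(bad)]!r} for individual "
                f"{self.ids[bad[0]]!r} at marker {self.markers[bad[1]]!r}"
            )

    @property
    def missing_rate(self) -> np.ndarray:
        return np.isnan(self.matrix).mean(axis=0)

    def subset(self, ids) -> "GenotypeData":
        pos = {x: k for k, x in enumerate(self.ids)}
        rows = [pos[i] for i in ids]
        return GenotypeData(list(ids), list(self.markers), self.matrix[rows])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.ids, columns=self.markers)


@dataclass
class ScanResult:
    """Per-locus scan statistics (``table`` columns: marker, chrom, pos_cM,
    df, lrt, lod, p, add_effect, dom_effect, testable)."""

    table: pd.DataFrame

    def max_row(self):
        t = self.table[self.table["testable"]]
        if len(t) == 0:
            return None
        return t.loc[t["lrt"].idxmax()]

    @property
    def max_lrt(self) -> float:
        t = self.table[self.table["testable"]]
        return float(t["lrt"].max()) if len(t) else float("nan")


def _codings(G: np.ndarray, coding: str):
    """Additive (count - 1) and dominance (heterozygote indicator) codings."""
    A = G - 1.0
    D = (G == 1.0).astype(float)
    D[np.isnan(G)] = np.nan
    if coding == "additive":
        return A, None
    if coding in ("additive+dominance", "add+dom"):
        return A, D
    raise ValueError(f"unknown coding {coding!r}")


class _WhitenedRegression:
    """Shared machinery: whiten by the Cholesky factor of sigma once, then
    test locus columns against the covariate-only null by GLS."""

    def __init__(self, y, X, sigma=None):
        y = np.asarray(y, float)
        X = np.atleast_2d(np.asarray(X, float))
        if X.shape[0] != len(y):
            X = X.T
        self.n = len(y)
        if sigma is None:
            L = None
            yw, Xw = y, X
        else:
            sigma = np.asarray(sigma, float)
            try:
                L = linalg.cholesky(sigma, lower=True, check_finite=False)
            except linalg.LinAlgError as e:
                raise ValueError("covariance matrix is not positive definite") from e
            yw = linalg.solve_triangular(L, y, lower=True, check_finite=False)
            Xw = linalg.solve_triangular(L, X, lower=True, check_finite=False)
        self.L = L
        self.yw, self.Xw = yw, Xw
        Q, _ = np.linalg.qr(Xw)
        self.Q = Q
        self.r0 = yw - Q @ (Q.T @ yw)
        self.rss0 = float(self.r0 @ self.r0)

    def whiten(self, M):
        if self.L is None:
            return np.asarray(M, float)
        return linalg.solve_triangular(self.L, np.asarray(M, float), lower=True,
                                       check_finite=False)

    def lrt_columns(self, A, D=None):
        """Vectorized per-column LRT for additive (and optional dominance)
        whitened codings; returns (lrt, df, beta_a, beta_d)."""
        A = np.atleast_2d(A.T).T
        At = A - self.Q @ (self.Q.T @ A)
        Saa = np.einsum("ij,ij->j", At, At)
        Say = At.T @ self.r0
        m = A.shape[1]
        lrt = np.zeros(m)
        dfv = np.zeros(m, int)
        ba = np.full(m, np.nan)
        bd = np.full(m, np.nan)
        if D is not None:
            Dt = D - self.Q @ (self.Q.T @ D)
            Sdd = np.einsum("ij,ij->j", Dt, Dt)
            Sad = np.einsum("ij,ij->j", At, Dt)
            Sdy = Dt.T @ self.r0
            det = Saa * Sdd - Sad**2
            full = det > _DEG_TOL * np.maximum(Saa * Sdd, 1e-300)
        else:
            full = np.zeros(m, bool)
        add_only = ~full & (Saa > _DEG_TOL * self.n)
        if D is not None and np.any(full):
            f = full
            red = (Sdd[f] * Say[f] ** 2 - 2 * Sad[f] * Say[f] * Sdy[f] + Saa[f] * Sdy[f] ** 2) / det[f]
            rss1 = np.maximum(self.rss0 - red, 1e-300)
            lrt[f] = self.n * np.log(self.rss0 / rss1)
            dfv[f] = 2
            ba[f] = (Sdd[f] * Say[f] - Sad[f] * Sdy[f]) / det[f]
            bd[f] = (Saa[f] * Sdy[f] - Sad[f] * Say[f]) / det[f]
        if np.any(add_only):
            a = add_only
            red = Say[a] ** 2 / Saa[a]
            rss1 = np.maximum(self.rss0 - red, 1e-300)
            lrt[a] = self.n * np.log(self.rss0 / rss1)
            dfv[a] = 1
            ba[a] = Say[a] / Saa[a]
        testable = dfv > 0
        lrt = np.maximum(lrt, 0.0)
        return lrt, dfv, ba, bd, testable

    def rss_of(self, cols) -> float:
        """Residual sum of squares after adding (whitened) columns to X."""
        M = np.column_stack([self.Xw] + [np.asarray(c, float) for c in cols])
        _, rss, rank, _ = np.linalg.lstsq(M, self.yw, rcond=None)
        if rank < M.shape[1] or len(rss) == 0:
            r = self.yw - M @ np.linalg.lstsq(M, self.yw, rcond=None)[0]
            return float(r @ r), rank
        return float(rss[0]), rank


def _missing_patterns(G: np.ndarray):
    """Group marker columns by their missingness pattern."""
    miss = np.isnan(G)
    if not miss.any():
        return {(): np.arange(G.shape[1])}
    out: dict = {}
    for j in range(G.shape[1]):
        key = tuple(np.where(miss[:, j])[0])
        out.setdefault(key, []).append(j)
    return {k: np.array(v) for k, v in out.items()}


def scan_one(y, X, genotypes=None, sigma=None, coding: str = "additive+dominance",
             probabilities=None, gmap: GenomeMap | None = None,
             positions=None) -> ScanResult:
    """Single-locus genome scan with the covariance held fixed.

    Either ``genotypes`` (marker-based scan; individuals with a missing
    genotype are dropped for that marker only) or ``probabilities`` (an
    ``(n, n_pos, 3)`` array of Haley-Knott genotype probabilities, scanned
    via their expected codings) must be given.  ``sigma=None`` means an
    identity covariance (ordinary regression).
    """
    y = np.asarray(y, float)
    if (genotypes is None) == (probabilities is None):
        raise ValueError("supply exactly one of genotypes= or probabilities=")

    if probabilities is not None:
        P = np.asarray(probabilities, float)
        A = P[:, :, 2] - P[:, :, 0]
        D = P[:, :, 1] if coding != "additive" else None
        wr = _WhitenedRegression(y, X, sigma)
        lrt, dfv, ba, bd, testable = wr.lrt_columns(
            wr.whiten(A), None if D is None else wr.whiten(D))
        if positions is not None:
            pos_tab = pd.DataFrame(positions)
        else:
            pos_tab = pd.DataFrame({"marker": [f"pos{k}" for k in range(A.shape[1])]})
        tab = pos_tab.reset_index(drop=True)
    else:
        if isinstance(genotypes, GenotypeData):
            G = genotypes.matrix
            markers = genotypes.markers
        else:
            G = np.asarray(genotypes, float)
            markers = [f"m{j}" for j in range(G.shape[1])]
        m = G.shape[1]
        lrt = np.zeros(m)
        dfv = np.zeros(m, int)
        ba = np.full(m, np.nan)
        bd = np.full(m, np.nan)
        testable = np.zeros(m, bool)
        X = np.atleast_2d(np.asarray(X, float))
        if X.shape[0] != len(y):
            X = X.T
        sig = None if sigma is None else np.asarray(sigma, float)
        for patt, cols in _missing_patterns(G).items():
            keep = np.setdiff1d(np.arange(len(y)), np.array(patt, int))
            if len(keep) <= X.shape[1] + 1:
                continue
            wr = _WhitenedRegression(
                y[keep], X[keep],
                None if sig is None else sig[np.ix_(keep, keep)])
            A, D = _codings(G[np.ix_(keep, cols)], coding)
            l, d, a_, d_, t_ = wr.lrt_columns(
                wr.whiten(A), None if D is None else wr.whiten(D))
            lrt[cols], dfv[cols], ba[cols], bd[cols], testable[cols] = l, d, a_, d_, t_
        tab = pd.DataFrame({"marker": markers})
        if gmap is not None:
            tab = tab.merge(gmap.table, on="marker", how="left")

    p = np.full(len(lrt), np.nan)
    ok = testable
    p[ok] = stats.chi2.sf(lrt[ok], dfv[ok])
    p[ok] = np.clip(p[ok], np.finfo(float).tiny, 1.0)
    lrt_out = np.where(testable, lrt, np.nan)
    tab = tab.assign(
        df=np.where(testable, dfv, 0),
        lrt=lrt_out,
        lod=lrt_out / _2LN10,
        p=p,
        add_effect=np.where(testable, ba, np.nan),
        dom_effect=np.where(testable, bd, np.nan),
        testable=testable,
    )
    return ScanResult(tab)


# ---------------------------------------------------------------------------
# Haley-Knott genotype probabilities


def _gamete_transition(r):
    """2x2 haplotype transition matrix for recombination fraction r."""
    r = np.asarray(r, float)
    T = np.empty(r.shape + (2, 2))
    T[..., 0, 0] = T[..., 1, 1] = 1.0 - r
    T[..., 0, 1] = T[..., 1, 0] = r
    return T


def _conditional_tables(r1, r2):
    """P(g_t | g_L, g_R) for an F2-like cross, vectorized over positions.

    Each of the two gametes follows an independent two-state Markov chain
    with switch probabilities r1 (left flank -> target) and r2 (target ->
    right flank); a flank with no information is encoded as r = 0.5, which
    makes the corresponding conditioning vacuous.  Returns an array
    ``(k, 3, 3, 3)`` indexed by (gL, gt, gR) before normalization.
    """
    T1 = _gamete_transition(r1)
    T2 = _gamete_transition(r2)
    # single gamete path weight: P(bL) T1[bL,bt] T2[bt,bR]
    W = 0.5 * T1[:, :, :, None] * T2[:, None, :, :]  # (k, bL, bt, bR)
    P = np.zeros(W.shape[:1] + (3, 3, 3))
    for b1L in range(2):
        for b1t in range(2):
            for b1R in range(2):
                w1 = W[:, b1L, b1t, b1R]
                for b2L in range(2):
                    for b2t in range(2):
                        for b2R in range(2):
                            P[:, b1L + b2L, b1t + b2t, b1R + b2R] += w1 * W[:, b2L, b2t, b2R]
    return P


def genotype_probabilities(genotypes: GenotypeData, gmap: GenomeMap,
                           positions=None, step: float = 1.0,
                           cross: str = "ail_f2_like"):
    """Haley-Knott genotype probabilities at arbitrary map positions.

    For each individual and query position the nearest non-missing typed
    markers on either side are used as flanking information under a
    two-point Markov approximation with Haldane distances and F2-like
    transition probabilities (heterozygous-by-heterozygous cross).  At a
    typed marker the probability mass sits on the observed genotype; with
    no typed flank on a side that side is uninformative, and with no typed
    marker at all on the chromosome the F2 prior (1/4, 1/2, 1/4) is
    returned.

    Returns ``(positions_table, P)`` with ``P`` of shape
    ``(n_individuals, n_positions, 3)``.
    """
    if cross != "ail_f2_like":
        raise ValueError(f"unknown cross type {cross!r}")
    G = genotypes.matrix
    n = G.shape[0]
    sl = gmap.chrom_slices()
    if positions is None:
        rows = []
        for c, idx in sl.items():
            pos = gmap.table["pos_cm"].to_numpy()[idx]
            grid = np.arange(pos.min(), pos.max() + 1e-9, step)
            if grid[-1] < pos.max():
                grid = np.append(grid, pos.max())
            rows += [(f"{c}@{p:g}", c, float(p)) for p in grid]
        pos_tab = pd.DataFrame(rows, columns=["marker", "chrom", "pos_cm"])
    else:
        pos_tab = pd.DataFrame(positions)
        if "pos_cm" not in pos_tab.columns or "chrom" not in pos_tab.columns:
            raise ValueError("positions need 'chrom' and 'pos_cm' columns")
        if "marker" not in pos_tab.columns:
            pos_tab["marker"] = [f"{c}@{p:g}" for c, p in zip(pos_tab["chrom"], pos_tab["pos_cm"])]
        pos_tab["chrom"] = pos_tab["chrom"].astype(str)

    unknown = set(pos_tab["chrom"]) - set(sl)
    if unknown:
        raise ValueError(f"position(s) on unknown chromosome(s): {sorted(unknown)}")
    P = np.empty((n, len(pos_tab), 3))
    pos_all = gmap.table["pos_cm"].to_numpy()
    for c, midx in sl.items():
        qmask = np.where(pos_tab["chrom"].to_numpy() == c)[0]
        if len(qmask) == 0:
            continue
        q = pos_tab["pos_cm"].to_numpy()[qmask]
        span = (pos_all[midx].min() - 1e-9, pos_all[midx].max() + 1e-9)
        if np.any((q < span[0]) | (q > span[1])):
            raise ValueError(f"query position outside marker span of chromosome {c}")
        Gc = G[:, midx]
        mpos = pos_all[midx]
        for i in range(n):
            obs = np.where(~np.isnan(Gc[i]))[0]
            if len(obs) == 0:
                warnings.warn(
                    f"individual {genotypes.ids[i]!r} has no typed marker on "
                    f"chromosome {c}; using the uninformative prior",
                    stacklevel=2,
                )
                P[i, qmask] = (0.25, 0.5, 0.25)
                continue
            opos = mpos[obs]
            og = Gc[i, obs].astype(int)
            ri = np.searchsorted(opos, q, side="left")
            li = np.searchsorted(opos, q, side="right") - 1
            has_l = li >= 0
            has_r = ri < len(obs)
            dL = np.where(has_l, q - opos[np.clip(li, 0, None)], 0.0)
            dR = np.where(has_r, opos[np.clip(ri, None, len(obs) - 1)] - q, 0.0)
            r1 = np.where(has_l, haldane(np.maximum(dL, 0.0)), 0.5)
            r2 = np.where(has_r, haldane(np.maximum(dR, 0.0)), 0.5)
            gL = np.where(has_l, og[np.clip(li, 0, None)], 0)
            gR = np.where(has_r, og[np.clip(ri, None, len(obs) - 1)], 0)
            tab = _conditional_tables(r1, r2)
            k = np.arange(len(q))
            joint = tab[k, gL, :, gR]
            P[i, qmask] = joint / joint.sum(axis=1, keepdims=True)
    return pos_tab, P


# ---------------------------------------------------------------------------
# Two-locus epistasis scan


def scan_two(y, X, genotypes, sigma=None, gmap: GenomeMap | None = None,
             min_sep_cM: float = 20.0, interaction: str = "aa",
             pairs=None) -> pd.DataFrame:
    """Two-locus interaction scan.

    For each marker pair the model with both loci's marginal terms is
    compared against that model plus interaction terms (``"aa"``: the
    additive-by-additive product, 1 df; ``"full"``: all four products of
    additive/dominance codings).  Pairs default to all inter-chromosome
    pairs plus intra-chromosome pairs separated by at least
    ``min_sep_cM`` (collinearity guard).  The statistic is symmetric in
    pair order; collinear interaction columns flag the pair untestable.
    """
    if isinstance(genotypes, GenotypeData):
        G = genotypes.matrix
        markers = genotypes.markers
    else:
        G = np.asarray(genotypes, float)
        markers = [f"m{j}" for j in range(G.shape[1])]
    y = np.asarray(y, float)
    m = G.shape[1]
    if pairs is None:
        if gmap is not None:
            chrom = gmap.table["chrom"].to_numpy()
            pos = gmap.table["pos_cm"].to_numpy()
        else:
            chrom = np.zeros(m)
            pos = np.zeros(m)
        pairs = []
        for a in range(m):
            for b in range(a + 1, m):
                if gmap is None or chrom[a] != chrom[b] or abs(pos[b] - pos[a]) >= min_sep_cM:
                    pairs.append((a, b))
    else:
        norm = []
        for a, b in pairs:
            ia = markers.index(a) if isinstance(a, str) else int(a)
            ib = markers.index(b) if isinstance(b, str) else int(b)
            if ia == ib:
                raise ValueError(f"pair uses the same locus twice: {a!r}")
            norm.append((min(ia, ib), max(ia, ib)))
        pairs = norm

    wr = _WhitenedRegression(y, X, sigma)
    A = wr.whiten(np.nan_to_num(G - 1.0))
    D = wr.whiten(np.nan_to_num((G == 1.0).astype(float)))
    # interaction columns are built from raw codings, then whitened
    Araw = np.nan_to_num(G - 1.0)
    Draw = np.nan_to_num((G == 1.0).astype(float))
    rows = []
    n = len(y)
    for a, b in pairs:
        if np.isnan(G[:, a]).any() or np.isnan(G[:, b]).any():
            keep = ~(np.isnan(G[:, a]) | np.isnan(G[:, b]))
            sub = None if sigma is None else np.asarray(sigma, float)[np.ix_(keep, keep)]
            wr_ab = _WhitenedRegression(y[keep], np.atleast_2d(np.asarray(X, float))[keep], sub)
            Ac = [wr_ab.whiten(Araw[keep, a]), wr_ab.whiten(Araw[keep, b])]
            Dc = [wr_ab.whiten(Draw[keep, a]), wr_ab.whiten(Draw[keep, b])]
            n_ab = int(keep.sum())
        else:
            wr_ab = wr
            Ac = [A[:, a], A[:, b]]
            Dc = [D[:, a], D[:, b]]
            n_ab = n
        marg = [Ac[0], Dc[0], Ac[1], Dc[1]]
        rss_m, rank_m = wr_ab.rss_of(marg)
        if interaction == "aa":
            inter = [wr_ab.whiten(Araw[:, a] * Araw[:, b]) if wr_ab is wr
                     else wr_ab.whiten(Araw[np.asarray(keep), a] * Araw[np.asarray(keep), b])]
        elif interaction == "full":
            if wr_ab is wr:
                inter = [wr_ab.whiten(u * v) for u in (Araw[:, a], Draw[:, a])
                         for v in (Araw[:, b], Draw[:, b])]
            else:
                kk = np.asarray(keep)
                inter = [wr_ab.whiten(u * v) for u in (Araw[kk, a], Draw[kk, a])
                         for v in (Araw[kk, b], Draw[kk, b])]
        else:
            raise ValueError(f"unknown interaction set {interaction!r}")
        rss_i, rank_i = wr_ab.rss_of(marg + inter)
        df = rank_i - rank_m
        testable = df > 0 and rss_i > 0
        if testable:
            lrt = max(0.0, n_ab * np.log(rss_m / rss_i))
            p = float(np.clip(stats.chi2.sf(lrt, df), np.finfo(float).tiny, 1.0))
        else:
            lrt, p = np.nan, np.nan
        rows.append((markers[a], markers[b], df if testable else 0, lrt,
                     (lrt / _2LN10) if testable else np.nan, p, testable))
    return pd.DataFrame(rows, columns=["marker1", "marker2", "df", "lrt", "lod", "p", "testable"])


def forward_multiple_qtl(y, X, genotypes, sigma=None, threshold: float = 0.0,
                         max_qtl: int = 10, coding: str = "additive+dominance",
                         gmap: GenomeMap | None = None):
    """Forward step-wise multiple-QTL mapping.

    Iteratively adds the genome-wide best locus to the fixed covariates
    while its LRT exceeds ``threshold`` (typically an empirical genome-wide
    threshold); previously selected loci are excluded from later scans.
    Returns a dict with the selection order, the per-step scans, and joint
    effect estimates from the final whitened regression.
    """
    if max_qtl <= 0:
        raise ValueError("max_qtl must be positive")
    if isinstance(genotypes, GenotypeData):
        G = genotypes.matrix
        markers = genotypes.markers
    else:
        G = np.asarray(genotypes, float)
        markers = [f"m{j}" for j in range(G.shape[1])]
    y = np.asarray(y, float)
    X0 = np.atleast_2d(np.asarray(X, float))
    if X0.shape[0] != len(y):
        X0 = X0.T
    gd = GenotypeData([f"i{k}" for k in range(G.shape[0])], markers, G)
    selected: list = []
    steps = []
    Xcur = X0
    while len(selected) < max_qtl:
        res = scan_one(y, Xcur, genotypes=gd, sigma=sigma, coding=coding, gmap=gmap)
        t = res.table
        t = t[t["testable"] & ~t["marker"].isin([markers[j] for j in selected])]
        if len(t) == 0:
            break
        best = t.loc[t["lrt"].idxmax()]
        if best["lrt"] <= threshold:
            break
        j = markers.index(best["marker"])
        selected.append(j)
        steps.append({"marker": markers[j], "lrt": float(best["lrt"]),
                      "lod": float(best["lod"])})
        Araw, Draw = _codings(G[:, [j]], coding)
        cols = [np.nan_to_num(Araw[:, 0])]
        if Draw is not None:
            cols.append(np.nan_to_num(Draw[:, 0]))
        Xcur = np.column_stack([Xcur] + cols)
    # joint effects from the final model
    wr = _WhitenedRegression(y, X0, sigma)
    cols, names = [], []
    for j in selected:
        Araw, Draw = _codings(G[:, [j]], coding)
        cols.append(np.nan_to_num(Araw[:, 0]))
        names.append(f"{markers[j]}:a")
        if Draw is not None:
            cols.append(np.nan_to_num(Draw[:, 0]))
            names.append(f"{markers[j]}:d")
    effects = {}
    if cols:
        M = np.column_stack([wr.Xw] + [wr.whiten(c) for c in cols])
        beta = np.linalg.lstsq(M, wr.yw, rcond=None)[0]
        effects = dict(zip(names, map(float, beta[wr.Xw.shape[1]:])))
    return {
        "selected": [markers[j] for j in selected],
        "steps": steps,
        "effects": effects,
    }
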
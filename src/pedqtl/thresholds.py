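"""Empirical genome-wide significance thresholds.

Two resampling schemes over the null of "no locus effect anywhere":

- permutation: the genotype rows are permuted jointly across all markers
  (whole genomes are relabelled, preserving within-individual linkage)
  while the phenotypes, covariates and covariance matrix stay put;
- gene dropping: founder alleles are dropped through the pedigree with
  Haldane-model recombination, generating replicate genotype sets that
  carry the family structure of the real data.

Each replicate is scanned against the real phenotypes with the same fixed
covariance, and the genome-wide maximum statistic is recorded; the
threshold is an empirical quantile of those maxima.  Permutation is only
calibrated when the covariance model actually captures the polygenic
structure; gene dropping controls the genome-wide error rate even when
polygenic variation is ignored, because the replicate genotypes inherit
the same relatedness that confounds the observed scan.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .pedigree import Pedigree
from .scan import GenomeMap, GenotypeData, haldane, _WhitenedRegression, _codings

__all__ = [
    "MaxDistribution",
    "permutation_threshold",
    "gene_drop",
    "gene_drop_threshold",
]


@dataclass
class MaxDistribution:
    """Genome-wide maximum statistics across null replicates."""

    samples: np.ndarray
    method: str
    n_replicates: int
    seed: int | None

    def __post_init__(self):
        self.samples = np.asarray(self.samples, float)
        if len(self.samples) != self.n_replicates:
            raise ValueError("sample count does not match n_replicates")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("non-finite genome-wide maxima")

    def quantile(self, q) -> float:
        """Empirical quantile with type-7 (linear) interpolation."""
        q = float(q)
        if not 0.0 < q <= 1.0:
            raise ValueError("quantile level must be in (0, 1]")
        return float(np.quantile(self.samples, q, method="linear"))


class _MaxScanner:
    """Whiten once, then compute genome-wide max LRT for many complete
    genotype matrices against the same y, X, sigma."""

    def __init__(self, y, X, sigma, coding="additive+dominance"):
        self.wr = _WhitenedRegression(y, X, sigma)
        self.coding = coding

    def max_lrt(self, G: np.ndarray) -> float:
        A, D = _codings(np.asarray(G, float), self.coding)
        lrt, _, _, _, testable = self.wr.lrt_columns(
            self.wr.whiten(A), None if D is None else self.wr.whiten(D))
        if not testable.any():
            return 0.0
        return float(lrt[testable].max())


def permutation_threshold(y, X, genotypes, sigma=None, n_perm: int = 1000,
                          q: float = 0.95, seed: int | None = None,
                          coding: str = "additive+dominance",
                          permutations=None):
    """Genome-wide threshold from genotype permutations.

    Each replicate applies one random permutation to the rows of the
    genotype matrix (all markers jointly), rescans against the unchanged
    ``y``, ``X`` and ``sigma``, and records the genome-wide maximum LRT.
    Returns ``(threshold, MaxDistribution)`` with the threshold at the
    empirical ``q`` quantile.  ``permutations`` may supply an explicit
    sequence of row permutations (testing hook / custom schemes).
    """
    if permutations is None and n_perm < 2:
        raise ValueError("n_perm must be at least 2")
    if not 0.0 < q <= 1.0:
        raise ValueError("quantile level must be in (0, 1]")
    G = genotypes.matrix if isinstance(genotypes, GenotypeData) else np.asarray(genotypes, float)
    scanner = _MaxScanner(y, X, sigma, coding)
    rng = np.random.default_rng(seed)
    if permutations is None:
        permutations = (rng.permutation(G.shape[0]) for _ in range(n_perm))
        n_rep = n_perm
    else:
        permutations = list(permutations)
        n_rep = len(permutations)
    maxima = np.empty(n_rep)
    for k, perm in enumerate(permutations):
        maxima[k] = scanner.max_lrt(G[np.asarray(perm)])
    dist = MaxDistribution(maxima, "permutation", n_rep, seed)
    return dist.quantile(q), dist


# ---------------------------------------------------------------------------
# Gene dropping


def _founder_haplotypes(ped: Pedigree, m: int, founder_alleles):
    """Per-founder haplotype pair, shape (2, m) of allele counts in {0, 1}.

    ``"two_strain"``: the pedigree must have exactly two founders; the
    first is homozygous for allele 1 (genotype 2), the second for allele 0.
    A dict maps founder id -> 0 / 2 (homozygous strain origin) or to an
    explicit (2, m) haplotype array.
    """
    founders = [i for i in ped.founders]
    haps = {}
    if isinstance(founder_alleles, str) and founder_alleles == "two_strain":
        if len(founders) != 2:
            raise ValueError(
                f"two_strain mode needs exactly 2 founders, pedigree has {len(founders)}"
            )
        haps[founders[0]] = np.ones((2, m), dtype=np.int8)
        haps[founders[1]] = np.zeros((2, m), dtype=np.int8)
        return haps
    if not isinstance(founder_alleles, dict):
        raise ValueError("founder_alleles must be 'two_strain' or a dict keyed by founder id")
    for i in founders:
        fid = ped.ids[i]
        if fid not in founder_alleles:
            raise ValueError(f"founder allele specification missing for {fid!r}")
        v = founder_alleles[fid]
        if np.isscalar(v):
            if v not in (0, 2):
                raise ValueError(f"homozygous founder genotype must be 0 or 2, got {v!r}")
            haps[i] = np.full((2, m), v // 2, dtype=np.int8)
        else:
            v = np.asarray(v, dtype=np.int8)
            if v.shape != (2, m):
                raise ValueError(f"founder haplotypes for {fid!r} must have shape (2, {m})")
            haps[i] = v
    return haps


def _switch_probabilities(gmap: GenomeMap) -> np.ndarray:
    """Per-interval haplotype switch probabilities along the map order;
    chromosome boundaries switch with probability 1/2 (independence)."""
    t = gmap.table
    if len(t) == 0:
        raise ValueError("empty genetic map")
    pos = t["pos_cm"].to_numpy()
    chrom = t["chrom"].to_numpy()
    r = haldane(np.maximum(np.diff(pos), 0.0))
    r = np.atleast_1d(r)
    r[chrom[1:] != chrom[:-1]] = 0.5
    return r


def _drop_genomes(ped: Pedigree, gmap: GenomeMap, founder_alleles, rng,
                  n_rep: int, keep: list[int] | None = None) -> np.ndarray:
    """Simulate ``n_rep`` independent gene drops; returns genotypes of the
    ``keep`` individuals (default all) with shape (n_rep, len(keep), m)."""
    m = gmap.n_markers
    rvec = _switch_probabilities(gmap)
    fh = _founder_haplotypes(ped, m, founder_alleles)
    hapP = {}
    hapQ = {}

    def meiosis(par: int) -> np.ndarray:
        start = rng.random((n_rep, 1)) < 0.5
        if m > 1:
            sw = rng.random((n_rep, m - 1)) < rvec
            idx = np.logical_xor.accumulate(np.concatenate([start, sw], axis=1), axis=1)
        else:
            idx = start
        return np.where(idx, hapQ[par], hapP[par])

    for i in range(ped.n):
        s, d = ped.sire[i], ped.dam[i]
        if s < 0 and d < 0:
            hapP[i] = np.broadcast_to(fh[i][0], (n_rep, m))
            hapQ[i] = np.broadcast_to(fh[i][1], (n_rep, m))
        else:
            hapP[i] = meiosis(int(s))
            hapQ[i] = meiosis(int(d))
    if keep is None:
        keep = list(range(ped.n))
    out = np.empty((n_rep, len(keep), m), dtype=np.int8)
    for k, i in enumerate(keep):
        out[:, k, :] = hapP[i].astype(np.int8) + hapQ[i].astype(np.int8)
    return out


def gene_drop(ped: Pedigree, gmap: GenomeMap, founder_alleles="two_strain",
              seed: int | None = None, ids=None) -> GenotypeData:
    """One simulated transmission of founder alleles through the pedigree.

    Each meiosis walks along every chromosome: the first marker's allele
    comes from a uniformly chosen parental haplotype, and subsequent
    markers switch haplotype with probability ``haldane(delta d)`` (no
    crossover interference).  Offspring genotype = paternal + maternal
    gamete.  Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    if ids is None:
        keep = [i for i in range(ped.n) if not ped.hidden[i]]
    else:
        keep = [ped.index[x] for x in ids]
    geno = _drop_genomes(ped, gmap, founder_alleles, rng, 1, keep)[0]
    return GenotypeData([ped.ids[i] for i in keep], gmap.markers, geno.astype(float))


def gene_drop_threshold(ped: Pedigree, gmap: GenomeMap, y, X, sigma=None,
                        n_drop: int = 1000, q: float = 0.95,
                        seed: int | None = None, ids=None,
                        founder_alleles="two_strain",
                        coding: str = "additive+dominance"):
    """Genome-wide threshold from gene-dropping replicates.

    Each replicate generates a gene-dropped genotype matrix for the
    phenotyped individuals (``ids``; default every non-placeholder
    pedigree member) and scans it against the real ``y``, ``X`` and
    ``sigma``; the threshold is the ``q`` quantile of the genome-wide
    maxima.  Reproducible given ``seed``.
    """
    if n_drop < 2:
        raise ValueError("n_drop must be at least 2")
    if not 0.0 < q <= 1.0:
        raise ValueError("quantile level must be in (0, 1]")
    rng = np.random.default_rng(seed)
    if ids is None:
        keep = [i for i in range(ped.n) if not ped.hidden[i]]
    else:
        keep = [ped.index[x] for x in ids]
    if len(keep) != len(np.asarray(y)):
        raise ValueError("phenotype length does not match the individual set")
    scanner = _MaxScanner(y, X, sigma, coding)
    maxima = np.empty(n_drop)
    # replicate in modest batches to bound memory on large pedigrees
    batch = max(1, min(n_drop, int(2e8 // max(1, ped.n * gmap.n_markers))))
    k = 0
    while k < n_drop:
        b = min(batch, n_drop - k)
        G = _drop_genomes(ped, gmap, founder_alleles, rng, b, keep)
        for r in range(b):
            maxima[k + r] = scanner.max_lrt(G[r].astype(float))
        k += b
    dist = MaxDistribution(maxima, "gene_drop", n_drop, seed)
    return dist.quantile(q), dist
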
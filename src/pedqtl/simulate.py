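"""Synthetic advanced-intercross-line (AIL) data factory.

Everything the rest of the package consumes can be generated here with a
known truth: an AIL pedigree (two inbred founder strains, an F1, then
repeated intercrossing), marker genotypes obtained by dropping founder
alleles through that pedigree with Haldane-model recombination, and
phenotypes drawn from the polygenic model
``y = X beta + sum_q (a_q * add + d_q * dom) + u + eps`` with
``u ~ N(0, sigma_a^2 AA + sigma_d^2 DD)`` and ``eps ~ N(0, sigma_e^2 I)``.

Breeding mimics standard mouse-AIL husbandry: each generation is produced
by disjoint monogamous breeding pairs (males and females of the previous
generation paired at random, no selfing by construction) with offspring
distributed evenly across pairs and sexes alternating, giving litters of
roughly ``n_per_generation / n_breeding_pairs``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pedigree import Pedigree, validate_pedigree
from .scan import GenomeMap, GenotypeData
from .thresholds import _drop_genomes

__all__ = ["SimulationSpec", "simulate_ail", "simulate_phenotypes"]


@dataclass
class SimulationSpec:
    """Study design for the synthetic AIL.

    Defaults give the package's reduced-scale test fixture: a 5-generation
    AIL with 400 individuals per intercross generation, 5 chromosomes of
    100 cM carrying 60 evenly spaced markers each, and variance components
    (sigma_a^2, sigma_d^2, sigma_e^2) = (1, 0.5, 1).
    """

    n_generations: int = 5
    n_per_generation: int = 400
    n_breeding_pairs: int | None = None  # default: one pair per ~6 offspring
    mating: str = "random_nonself"
    chromosomes: int = 5
    chrom_length_cM: float = 100.0
    markers_per_chromosome: int = 60
    qtl: list = field(default_factory=list)  # (marker_name, add_effect, dom_effect)
    var_a: float = 1.0
    var_d: float = 0.5
    var_e: float = 1.0
    beta0: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_generations < 2:
            raise ValueError("an intercross needs at least 2 generations (F0 and F1)")
        if self.mating not in ("random_nonself", "sib_mating"):
            raise ValueError(f"unknown mating scheme {self.mating!r}")
        if min(self.var_a, self.var_d, self.var_e) < 0:
            raise ValueError("variance parameters must be non-negative")
        for q in self.qtl:
            if not np.all(np.isfinite([q[1], q[2]])):
                raise ValueError(f"non-finite QTL effect: {q!r}")
        if self.n_breeding_pairs is None:
            self.n_breeding_pairs = max(1, round(self.n_per_generation / 6))


def _genetic_map(spec: SimulationSpec) -> GenomeMap:
    rows = []
    for c in range(1, spec.chromosomes + 1):
        pos = np.linspace(0.0, spec.chrom_length_cM, spec.markers_per_chromosome)
        rows += [(f"c{c}m{k + 1}", str(c), float(p)) for k, p in enumerate(pos)]
    return GenomeMap(pd.DataFrame(rows, columns=["marker", "chrom", "pos_cm"]))


def simulate_ail(spec: SimulationSpec):
    """Simulate pedigree, genetic map and genotypes for an AIL.

    F0 is a pair of fully inbred founder strains (genotypes 2 and 0 at
    every marker), F1 a single intercross litter, and later generations
    follow the breeding scheme in ``spec``.  Genotypes for every
    individual come from one gene drop through the pedigree.  Returns
    ``(Pedigree, GenomeMap, GenotypeData)``; deterministic given
    ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    recs = [("F0_A", "0", "0", "M", 0), ("F0_B", "0", "0", "F", 0)]
    prev_m, prev_f = ["F0_A"], ["F0_B"]
    prev_litter = {"F0_A": -1, "F0_B": -2}
    for g in range(1, spec.n_generations):
        males, females, litter_of = [], [], {}
        if g == 1:
            pairs = [("F0_A", "F0_B")]
        elif spec.mating == "sib_mating":
            # mate within litters where possible (maximizes inbreeding)
            by_litter: dict = {}
            for x in prev_m:
                by_litter.setdefault(prev_litter[x], [[], []])[0].append(x)
            for x in prev_f:
                by_litter.setdefault(prev_litter[x], [[], []])[1].append(x)
            pairs = []
            leftover_m, leftover_f = [], []
            for lit, (ms, fs) in sorted(by_litter.items()):
                k = min(len(ms), len(fs))
                pairs += list(zip(ms[:k], fs[:k]))
                leftover_m += ms[k:]
                leftover_f += fs[k:]
            pairs += list(zip(leftover_m, leftover_f))
            pairs = pairs[: spec.n_breeding_pairs] or pairs
        else:
            k = min(spec.n_breeding_pairs, len(prev_m), len(prev_f))
            if k == 0:
                raise ValueError("population too small to form a breeding pair")
            mm = [prev_m[t] for t in rng.permutation(len(prev_m))[:k]]
            ff = [prev_f[t] for t in rng.permutation(len(prev_f))[:k]]
            pairs = list(zip(mm, ff))
        if not pairs:
            raise ValueError("population too small to avoid selfing")
        for k2 in range(spec.n_per_generation):
            s, d = pairs[k2 % len(pairs)]
            name = f"F{g}_{k2:03d}"
            sex = "M" if k2 % 2 == 0 else "F"
            recs.append((name, s, d, sex, g))
            litter_of[name] = k2 % len(pairs)
            (males if sex == "M" else females).append(name)
        prev_m, prev_f, prev_litter = males, females, litter_of
    ped = validate_pedigree(recs)
    gmap = _genetic_map(spec)
    geno_seed = int(rng.integers(0, 2**31 - 1))
    drop_rng = np.random.default_rng(geno_seed)
    keep = list(range(ped.n))
    geno = _drop_genomes(ped, gmap, "two_strain", drop_rng, 1, keep)[0]
    gd = GenotypeData([ped.ids[i] for i in keep], gmap.markers, geno.astype(float))
    return ped, gmap, gd


def simulate_phenotypes(ids, genotypes: GenotypeData, spec: SimulationSpec,
                        AA=None, DD=None, X=None, seed=None):
    """Draw one phenotype vector under the polygenic model.

    ``AA`` / ``DD`` are the additive and dominance incidence matrices over
    ``ids`` (either may be omitted when its variance is zero).  QTL effects
    from ``spec.qtl`` enter through the additive coding ``count - 1`` and
    the heterozygote indicator.  Returns ``(y, u)`` with ``u`` the true
    polygenic values, for diagnostics.  Deterministic given ``seed``
    (default ``spec.seed + 1``).
    """
    ids = list(ids)
    n = len(ids)
    rng = np.random.default_rng(spec.seed + 1 if seed is None else seed)
    if X is None:
        X = np.ones((n, 1))
    beta = np.full(X.shape[1] if X.ndim > 1 else 1, spec.beta0)
    y = np.atleast_2d(X).reshape(n, -1) @ beta

    gsub = genotypes.subset(ids)
    for marker, a_eff, d_eff in spec.qtl:
        j = gsub.markers.index(marker)
        g = gsub.matrix[:, j]
        if np.isnan(g).any():
            raise ValueError(f"QTL marker {marker!r} has missing genotypes")
        y = y + a_eff * (g - 1.0) + d_eff * (g == 1.0)

    Gcov = np.zeros((n, n))
    if spec.var_a > 0:
        if AA is None:
            raise ValueError("AA matrix required when var_a > 0")
        Gcov += spec.var_a * np.asarray(AA, float)
    if spec.var_d > 0:
        if DD is None:
            raise ValueError("DD matrix required when var_d > 0")
        Gcov += spec.var_d * np.asarray(DD, float)
    u = np.zeros(n)
    if Gcov.any():
        Gcov = 0.5 * (Gcov + Gcov.T)
        try:
            L = np.linalg.cholesky(Gcov)
        except np.linalg.LinAlgError:
            # PSD up to rounding: symmetrize + tiny jitter
            L = np.linalg.cholesky(Gcov + 1e-8 * np.eye(n))
        u = L @ rng.standard_normal(n)
    eps = np.sqrt(spec.var_e) * rng.standard_normal(n)
    return y + u + eps, u
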
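"""Permutation vs gene-dropping genome-wide significance thresholds.

On a polygenic (no-QTL) AIL phenotype, compares the 5% genome-wide LRT
thresholds produced by genotype permutation and by gene dropping, first
with the polygenic covariance modeled, then with it deliberately ignored.
Permutation breaks down in the second case; gene dropping does not.
"""

import numpy as np

from pedqtl import (SimulationSpec, VarianceModel, fit_ml, gene_drop_threshold,
                    kinship_matrix, permutation_threshold, scan_one,
                    simulate_ail)

spec = SimulationSpec(n_generations=6, n_per_generation=150, chromosomes=4,
                      markers_per_chromosome=25, var_a=2.0, var_d=0.0,
                      var_e=1.0, seed=5)
ped, gmap, geno = simulate_ail(spec)
idx = [i for i in range(ped.n) if ped.generation[i] == 5]
animals = [ped.ids[i] for i in idx]
AA = 2.0 * kinship_matrix(ped)[np.ix_(idx, idx)]
n = len(animals)
rng = np.random.default_rng(2)
y = np.linalg.cholesky(AA + 1e-10 * np.eye(n)) @ rng.standard_normal(n) * np.sqrt(2.0) \
    + rng.standard_normal(n)
X = np.ones((n, 1))
gsub = geno.subset(animals)

fit = fit_ml(VarianceModel([("AA", AA)], n=n), y)
for label, sigma in (("polygenic covariance modeled", fit.sigma),
                     ("polygenic covariance ignored", None)):
    obs = scan_one(y, X, genotypes=gsub, sigma=sigma).max_lrt
    thr_p, _ = permutation_threshold(y, X, gsub, sigma, n_perm=300, seed=8)
    thr_g, _ = gene_drop_threshold(ped, gmap, y, X, sigma, n_drop=300, seed=8,
                                   ids=animals)
    call = lambda t: "SIGNIFICANT (false positive!)" if obs > t else "not significant"
    print(f"{label}:")
    print(f"  observed genome-wide max LRT {obs:6.2f}")
    print(f"  permutation  0.95 threshold {thr_p:6.2f} -> {call(thr_p)}")
    print(f"  gene-drop    0.95 threshold {thr_g:6.2f} -> {call(thr_g)}\n")
print("There is no QTL in these data. When the polygenic covariance is")
print("ignored, the permutation threshold is far too low because permuting")
print("genomes destroys the family structure that inflates the observed")
print("scan; gene-dropped genotypes keep that structure, so the threshold")
print("rises with the confounding and the error rate stays controlled.")
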
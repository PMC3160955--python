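"""Genome scan with a fixed covariance, at markers and between them.

Simulates an AIL phenotype with a planted QTL plus polygenic background,
fits the null covariance once, scans every marker, and then runs
Haley-Knott interval mapping on a 2 cM grid between markers.
"""

import numpy as np

from pedqtl import (SimulationSpec, VarianceModel, condensed_identity, fit_ml,
                    genetic_matrices, genotype_probabilities, scan_one,
                    simulate_ail, simulate_phenotypes)

spec = SimulationSpec(n_generations=5, n_per_generation=300, chromosomes=3,
                      markers_per_chromosome=30, qtl=[("c2m15", 0.8, 0.0)],
                      var_a=0.5, var_d=0.0, var_e=1.0, seed=15)
ped, gmap, geno = simulate_ail(spec)
animals = [ped.ids[i] for i in range(ped.n) if ped.generation[i] == 4]
gm = genetic_matrices(condensed_identity(ped, animals))
y, _ = simulate_phenotypes(animals, geno, spec, AA=gm.AA)
gsub = geno.subset(animals)
X = np.ones((len(y), 1))

# covariance fitted once under the no-QTL null, then held fixed
fit = fit_ml(VarianceModel([("AA", gm.AA)], n=len(y)), y)
res = scan_one(y, X, genotypes=gsub, sigma=fit.sigma, gmap=gmap)
top = res.max_row()
print(f"planted QTL at marker c2m15 (chromosome 2, "
      f"{gmap.table.set_index('marker').loc['c2m15', 'pos_cm']:.1f} cM)")
print(f"marker scan top hit: {top['marker']} LOD = {top['lod']:.2f} "
      f"(additive effect {top['add_effect']:+.2f})")

pos_tab, P = genotype_probabilities(gsub, gmap, step=2.0)
res_hk = scan_one(y, X, probabilities=P, sigma=fit.sigma, positions=pos_tab)
top_hk = res_hk.max_row()
print(f"Haley-Knott grid top hit:  {top_hk['marker']} LOD = {top_hk['lod']:.2f}")
print("The interval-mapping curve peaks at the same place as the marker")
print("scan; between typed markers it interpolates evidence through the")
print("flanking-marker genotype probabilities.")
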
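"""Fit additive + dominance variance components on a simulated AIL.

Simulates a 5-generation advanced intercross with known variance
components, assembles the additive (AA) and dominance (DD) incidence
matrices from condensed identity coefficients, and estimates the
components by maximum likelihood with a boundary-corrected LRT for the
additive term.
"""

from pedqtl import (SimulationSpec, VarianceModel, condensed_identity, fit_ml,
                    genetic_matrices, lrt_component, simulate_ail,
                    simulate_phenotypes)

spec = SimulationSpec(n_generations=5, n_per_generation=200, chromosomes=3,
                      markers_per_chromosome=30, var_a=1.0, var_d=0.5,
                      var_e=1.0, seed=7)
ped, gmap, geno = simulate_ail(spec)
animals = [ped.ids[i] for i in range(ped.n) if ped.generation[i] == 4]

ic = condensed_identity(ped, animals)
gm = genetic_matrices(ic)
y, _ = simulate_phenotypes(animals, geno, spec, AA=gm.AA, DD=gm.DD)

full = VarianceModel([("AA", gm.AA), ("DD", gm.DD)], n=len(y))
fit = fit_ml(full, y)
print(f"n = {len(y)} phenotyped animals; true (var_a, var_d, var_e) = (1.0, 0.5, 1.0)")
print("ML estimates:")
for name, v in fit.estimates.items():
    print(f"  {name:9s} {v:.3f}")
print(f"log-likelihood {fit.loglik:.2f}  (converged: {fit.converged})")

no_add = VarianceModel([("DD", gm.DD)], n=len(y))
stat, p = lrt_component(full, no_add, y)
print(f"\nLRT for the additive component: statistic {stat:.2f}, "
      f"boundary-mixture p = {p:.2g}")
print("A single estimate is noisy (additive and dominance relatedness are")
print("highly correlated in a compact AIL), but the additive term is")
print("clearly supported against the boundary null var_a = 0.")
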
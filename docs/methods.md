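# Methods

`pedqtl` maps quantitative trait loci (QTL) in populations where
individuals are unequally related — advanced intercross lines (AILs),
heterogeneous stocks, extended families — by combining four pieces:
pedigree-based identity coefficients, a variance-component mixed model,
genome scans with the fitted covariance held fixed, and empirical
genome-wide significance thresholds.  This note records the models, the
algorithms, the numerical choices, and what the synthetic benchmarks do
and do not establish.

## The phenotype model

For phenotypes `y` on n individuals,

    y = X beta + Q gamma + u + eps,
    u ~ N(0, G),   eps ~ N(0, I sigma_e^2),

where `X beta` are covariate effects, `Q gamma` the effect of a putative
locus through its additive/dominance coding, and `u` a polygenic effect.
The polygenic covariance can carry up to five genetic components,

    G = sigma_a^2 AA + sigma_d^2 DD + sigma_h^2 HH + sigma_adh AD + iota^2 MH,

plus arbitrary non-genetic random effects (cage, litter) supplied as
their own incidence matrices.  Each individual carries one polygenic
value (repeated measures are out of scope).  The five genetic matrices
are linear functions of the pair's condensed identity coefficients
(below); for fully outbred pedigrees HH, AD and MH vanish and the model
reduces to the familiar additive + dominance decomposition.  The default
component set is {AA, DD, residual}; the inbreeding-related terms are
opt-in, because in practice they are small and hard to separate unless
inbreeding varies strongly.

## Condensed identity coefficients

For a pair (i, j) at an autosomal locus, Jacquard's nine condensed
states partition the IBD configurations of the four alleles the pair
carries; their probabilities Δ1..Δ9 are the complete pedigree summary
for second-moment genetics.  Δ3/Δ4 refer to autozygosity of the first
individual of the pair and Δ5/Δ6 of the second; the accessor re-orients
a reversed query accordingly.

The engine evaluates *generalized kinship states*: collections of groups
of gene draws, valued by the probability that all genes within every
group are IBD.  Nine such values per pair — 1, f_i, f_j, φ(i,j),
φ(i,i,j), φ(i,j,j), φ(i,i,j,j), φ(i,i; j,j), φ(i,j; i,j) — determine
Δ1..Δ9 through a 9×9 linear system whose entries were derived state by
state (the conditional probability of each observable event given each
condensed state) and inverted once in exact rational arithmetic.

States reduce by *synchronous substitution*: every member of the deepest
generation present is replaced, simultaneously, by a uniformly chosen
parental gene.  Copies of one individual that land on the same gene
collapse to a single draw from the corresponding parent; a gene shared
between two groups merges them.  On generation-stratified pedigrees
(every parent in the previous generation, as in an intercross) this
keeps all intermediate states inside a single generation, so the state
space grows with pedigree *width*, not depth.  Memoization uses a
sibship-canonical key: individuals with the same (sire, dam) pair — and
all founders — have exchangeable ancestries, so states differing only by
such a relabelling share one cache entry.  The relabelling is restricted
to members that are not ancestors of another member of the same state
(an in-state ancestor is pinned to its identity, since substituting it
would rewire descent paths below it), and instance numbers within a
sibship are assigned by a deterministic occurrence signature.  Both
devices are exactness-preserving; they only increase cache hits.

Three computational *strategies* expose the storage/compute trade-off the
recursion admits.  `bottom_up` resolves everything lazily from the
target pairs (minimal storage); `top_down` first sweeps the pedigree
founders-down to tabulate all pairwise kinships and uses the table as
the two-gene base case; `hybrid(g)` tabulates only generations ≤ g
(default `depth − 6`) and recurses above the table.  All three return
identical values — verified to 1e-12 on a 10-generation, 200-per-
generation AIL — and the choice only matters for memory and speed on
deep pedigrees.

Two correctness anchors are built in: an independent brute-force oracle
that enumerates all 4^m transmission patterns of a small pedigree
(m ≤ 12 non-founders) in exact `Fraction` arithmetic, and the structural
invariants (Σ_k Δk = 1, marginal autozygosity consistency, the kinship
identity φ = Δ1 + (Δ3+Δ5+Δ7)/2 + Δ8/4).  The production float path
agrees with the oracle exactly on dyadic-rational pedigrees and to
≤ 1e-12 in general.

Founders are assumed non-inbred and mutually unrelated (the standard
recursion base case); a record naming only one parent gets a hidden
placeholder founder, which reproduces the convention that the unknown
side contributes no relatedness.  Sex is stored but unused (X-linked
coefficients are out of scope).

## Variance-component estimation

Fixed effects are profiled out by generalized least squares, so the
likelihood is maximized over variance parameters only:

    -2 l(theta) = n log 2π + log|Σ(theta)| + (y - X b(theta))' Σ(theta)^{-1} (y - X b(theta)).

Estimation is plain maximum likelihood (not REML; at the sample sizes
this package targets the two are nearly equivalent, and ML keeps
likelihood-ratio tests simple).  Non-negative variances are searched on
the log scale; the signed additive-dominance covariance is searched
untransformed; a non-positive-definite Σ returns a large penalty
(1e10-scaled) instead of raising, which keeps the default Nelder-Mead
simplex inside the feasible region.  Nelder-Mead is the default for
robustness on boundary-prone surfaces; BFGS with numerical gradients is
available and agrees on well-conditioned problems to 1e-4 in the
log-likelihood.  Defaults: `fatol 1e-8`, `max_iter 5000`, initial point
= phenotypic variance split equally across non-negative components.

Component tests use the likelihood ratio clamped at zero with the 50:50
chi-square(0):chi-square(1) mixture p-value appropriate for one variance
tested on its boundary (`boundary=False` gives the naive chi-square,
deliberately flagged as anti-conservative).  Model selection is greedy
forward inclusion by AIC (default) or boundary-corrected LRT; the
information criterion is this package's choice, made because greedy
AIC-forward is cheap, deterministic (ties break on candidate order), and
monotone in likelihood along the accepted path.

**Identifiability caveat.**  In a compact AIL the AA and DD matrices are
strongly correlated (≈ 0.95 at five generations in the default fixture),
so the additive/dominance *split* is estimated with large sampling
variance even though each mean recovers its truth within Monte-Carlo
error; the total genetic variance is the stable quantity.  Designs with
more generations, or with litter contrasts, decorrelate the two.

## Genome scans

The polygenic/residual covariance is estimated once under the no-QTL
null and then treated as known across the genome (re-estimating at each
of thousands of loci is both slow and unnecessary when the single-locus
effect is small relative to the polygenic background; a
`reestimate-every-k` style refit is available by simply refitting and
rescanning).  One Cholesky factorization whitens y, X and all locus
codings; each locus is then an ordinary regression problem,

    LRT = n log(RSS0 / RSS1),   LOD = LRT / (2 ln 10),

with p-values from chi-square on df = number of locus terms fitted (2
for additive + dominance, 1 for additive-only or when the dominance
column is degenerate — e.g. no heterozygotes).  The statistic equals a
brute-force ordinary-regression likelihood ratio to 1e-8 when Σ = s²I,
and whitening is exact: scanning raw data under Σ equals scanning
hand-whitened data under I to 1e-10.  Genotypes are coded a = count − 1
∈ {−1, 0, 1} and d = 1{het}; individuals missing a genotype are dropped
for that marker only (scans group markers by missingness pattern and
factor the sub-covariance per pattern).  A likelihood-ratio statistic
was chosen over an F statistic because it composes directly into LOD
scores and into the threshold machinery; the OLS-oracle equivalence test
pins the definition.

*Interval mapping.*  Between markers, Haley-Knott regression replaces
the codings by their conditional expectations given the nearest
non-missing flanking markers.  The conditional distribution treats the
two gametes as independent two-state Markov chains with Haldane
switch probabilities (an F2-like approximation: exact for an F2, and
applied to AILs as the standard two-point approximation — the
accumulated map expansion of an AIL is not modeled, so between-marker
probabilities in late generations are mildly over-smoothed; at-marker
values are unaffected).  A side with no typed marker is encoded as
switch probability 1/2, which makes that conditioning vacuous and
degrades gracefully to the F2 prior (1/4, 1/2, 1/4) with no information.
Only biallelic markers are supported.  Default grid step: 1 cM.

*Epistasis and multiple QTL.*  The two-locus scan tests interaction
terms (additive×additive by default, the full 4-df set optionally) on
top of both loci's marginal terms; intra-chromosome pairs closer than
20 cM are excluded by default to limit collinearity, and rank-deficient
interaction columns flag the pair untestable.  Forward step-wise
multiple-QTL mapping repeatedly adds the genome-wide best locus to the
covariates while its LRT exceeds a (typically empirical) threshold,
reporting the selection path and joint effect estimates.

## Empirical significance thresholds

Both methods build the null distribution of the genome-wide maximum LRT
and report an empirical quantile (type-7 interpolation; default q = 0.95,
1000 replicates in production use, scaled down in the test suite).

*Permutation* shuffles whole genotype rows (genomes travel together, so
within-individual linkage is preserved) against fixed phenotypes and
covariance.  This is valid exactly when, under the null, phenotypes are
exchangeable with respect to genomes — i.e. when the fitted covariance
actually absorbs the family structure.

*Gene dropping* re-simulates genotypes through the real pedigree:
founder haplotypes (two-strain mode for intercrosses, or explicit
per-founder haplotypes) are transmitted with Haldane-model recombination
(per meiosis and chromosome: uniform starting haplotype, switch
probability `haldane(Δd)` between adjacent markers, no interference),
and each replicate genotype set is scanned against the real phenotypes.
Because the replicates inherit the same relatedness that confounds the
observed scan, the method controls the genome-wide error rate even when
the polygenic structure is ignored in the model.  The synthetic
benchmark reproduces exactly this contrast: with a correctly specified
covariance both methods sit inside the binomial 95% band around 0.05
(100 outer replicates × 200 resamples); with the covariance forced to
s²I the permutation type-I rate inflates severalfold while gene dropping
stays at nominal.  Replicate founder haplotypes are regenerated per
drop; conditioning on observed founder genotypes instead is available
through the explicit founder-haplotype mode.

Both methods are bit-for-bit reproducible given a seed.

## The synthetic AIL generator

The generator is the package's data contract: F0 is a pair of fully
inbred founder strains fixed for opposite alleles at every marker, F1 a
single intercross litter, and each later generation is produced by
disjoint monogamous breeding pairs — males and females of the previous
generation paired at random (no selfing by construction), offspring
dealt round-robin across pairs, sexes alternating.  The default of one
breeding pair per ~6 offspring mirrors typical mouse-AIL husbandry
(litters of about six, each cage contributing a litter) and gives the
pedigree genuine sibship structure, which both drives the
identifiability of dominance variance and is what the identity engine's
sibship canonicalization exploits.  A `sib_mating` scheme (mate within
litters) is provided for rapid-inbreeding scenarios.  Genotypes come
from one gene drop through the pedigree; phenotypes from the model above
with known variance components and optional planted QTL, returning the
true polygenic values for diagnostics.

Default fixture scale: 5 generations × 400 individuals, 5 chromosomes
× 100 cM × 60 markers, (sigma_a², sigma_d², sigma_e²) = (1, 0.5, 1).
These sizes were chosen so that every calibration in the test suite is a
single-CPU, minutes-scale computation while still exhibiting the
phenomena of interest (relatedness heterogeneity, LD around planted
QTL, polygenic confounding).  What the synthetic benchmarks do *not*
establish: behavior under genotyping error, selection, mutation,
non-Gaussian phenotypes, or the map expansion of very late AIL
generations — none of which the generator models.

## Numerical conventions and degenerate inputs

- Incidence matrices are symmetrized as (M + Mᵀ)/2 on assembly; the
  phenotype simulator adds ≤ 1e-8 jitter to a PSD-but-rounded genetic
  covariance before factorizing.
- Tiny negative Δ estimates from float solves (≥ −1e-9) are clipped to 0.
- Monomorphic or all-missing markers are flagged untestable, never
  statistics; p-values are clipped away from exact 0.
- Chromosome boundaries in the gene dropper are encoded as switch
  probability 1/2 (independent assortment).
- Quantiles everywhere are type-7 (linear interpolation), matching the
  convention of the surrounding ecosystem.
- Missing-parent tokens `0`, `""`, `NA`, `-` are normalized; an
  individual used as both sire and dam, duplicate ids, unknown parents
  and pedigree cycles are hard errors naming the offending ids.

## Known limitations

X-linked inheritance, multi-allelic Haley-Knott interval mapping,
REML, composite interval mapping, founder inbreeding priors and
repeated-measures designs are out of scope.  The identity engine's
fast path assumes the standard recursion's founder assumptions; its
cost on pedigrees that are deep *and* unstratified (parents scattered
across many earlier generations) grows beyond the stratified bound,
though correctness is unaffected.
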
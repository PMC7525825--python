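# Methods

## The line-cross model

Line-cross analysis treats the mean phenotypes of a set of related
cohorts — two selected parental lines, their reciprocal F1 hybrids and
backcrosses — as a linear function of *composite genetic effects*:
aggregate parameters, one per mode of gene action, summed over all
contributing loci. The observed cohort means `y` satisfy `y = Cβ + e`
with independent Gaussian errors whose variances are taken as known from
the cohort standard errors: `V = diag(se²)`. Estimation is weighted
least squares, i.e. minimisation of `(y − Cβ)ᵀV⁻¹(y − Cβ)`; cohorts
measured precisely dominate the fit.

Treating the error variances as known has two consequences used
throughout. First, the Gaussian log-likelihood is fully determined by
the weighted residual sum of squares, so AIC = −2·loglik + 2k is well
defined for every model, including saturated ones. Second, conditional
standard errors come directly from the inverse weighted normal-equations
matrix, with no residual-variance estimate.

A `v_mode="se"` compatibility switch places the standard errors
themselves (rather than their squares) on the diagonal of V, for
comparison with software that phrases the weight matrix that way. The
default is the variance reading, which is the statistically coherent
one.

## The C-matrix and its conventions

Coefficients are derived from the expected genomic composition of each
cohort, computed recursively through the pedigree (so non-standard cross
directions are supported by configuration, not new code):

* additive effects on [−1, +1] with P2 positive: `Aa = 2·(P2 genome
  fraction) − 1`;
* dominance effects on [0, 1]: expected fraction of loci heterozygous
  for line-origin alleles;
* cytotype `Ca = ±1` by the unbroken dam line; maternal effects `Ma`,
  `Md` take the dam line's `Aa`/`Ad` values;
* X-linked coefficients from expected X doses under male-heterogametic
  (XY) transmission — a male's single X comes from his dam, and males
  contribute no X dominance; `Ya` follows the unbroken sire line;
* the `pooled` sex mode (default) averages female and male coefficient
  values 1:1; `female`/`male` modes give sex-specific matrices (in the
  female matrix the `Ya` column is zero).

A Monte-Carlo oracle in the test suite pushes labelled X chromosomes and
cytoplasm through the crossing design and reproduces the `Xa`, `Xd` and
`Ca` columns to within binomial error.

Digenic epistatic columns are elementwise products of their factor
columns — the standard approximation for unlinked loci in digenic
models. The default effect set takes the 8 simple effects plus the
first 19 admissible products in canonical order (`Aa, Ad, Xa, Xd, Ya,
Ca, Ma, Md`; pairs with replacement), where a product is inadmissible if
its column is identically zero, constant, or an exact duplicate of a
column already present. With the standard pooled 8-cohort design this
yields `AaAa … XaCa`, 27 effects in total. The identity and ordering of
the epistatic set is a genuine design choice — published analyses have
used bespoke supplementary matrices — so any user matrix can be loaded
from delimited text and is aligned to the cohort table by cohort id.

Note a structural feature of pooled-sex 8-cohort designs: the `Xd`
column is exactly proportional to `Ad` (both track expected
heterozygosity, X dominance being female-only), and several X-involving
products are proportional to autosomal ones. Such pairs can never enter
one model together (the collinearity screen removes them); across
models they act as interchangeable substitutes and share model weight.

## Model search, screening, and averaging

With `n` cohorts only `n − 1` effects are estimable alongside the mean
`mu`, so the search space is every subset of 1–7 effects (μ always
estimated, never counted): 1,285,623 models for 27 effects. A subset is
dropped before fitting when any pair of its columns has |Pearson r| ≥
0.90 (configurable; constant columns are confounded with μ and always
drop) or when its design is exactly rank deficient. Rank deficiency is
detected on the unweighted Gram matrix with a relative eigenvalue cutoff
of 1e−10; with the default matrix, exact linear dependencies sit at
~1e−16 relative and well-conditioned designs at ≥1e−5, so any cutoff in
the gap gives identical decisions — and because rank(XᵀWX) = rank(X)
for positive weights, the screen is computed once per matrix and reused
across datasets. Surviving designs are solved in vectorised batches by
gathering sub-blocks of the full weighted normal-equations matrix; the
whole 27-effect search takes a few seconds on one CPU.

Fitted models get Akaike weights `exp(−Δᵢ/2)/Σⱼ exp(−Δⱼ/2)` over all
fitted models; ties in AIC are broken by enumeration order (size, then
lexicographic) so rankings are deterministic. The 95% confidence set is
the smallest weight-ordered prefix with cumulative weight ≥ 0.95.
Within the set, weights are renormalised (raw-weight importances are
reported alongside); an effect's importance is the summed weight of set
models containing it; its model-averaged estimate is the weight average
over the containing models (*natural* averaging — a zero-substitution
mode is available); its unconditional standard error follows the
Buckland/Burnham–Anderson formula `Σ wᵢ·sqrt(seᵢ² + (β̂ᵢ − β̄)²)`, and
CIs are ±1.96 unconditional SEs. Model adequacy is summarised by the
Cox–Snell pseudo-R², `1 − exp((2/n)(loglik₀ − loglik))` against the
μ-only null, reported as a ladder over effects added in
descending-importance order. An effect is *significant* when its
importance exceeds 0.5 and its CI excludes zero; the
epistatic-to-additive ratio divides the summed |estimates| of the
significant epistatic effects (optionally: all estimated ones) by |Aa|.

Zero-variance cohorts (a fixed line at modest n can disperse 0 or n
times) would make V singular; their SE is floored at 1/(2n) — half a
count on the proportion scale.

## The simulator: what it emulates

The generator models *dispersion* — incomplete sorting of
trait-increasing alleles between selection lines — and nothing else: no
selection, no linkage, no mutation, no sex, no unequal effects.
Dispersal tendency is controlled by 20 unlinked biallelic loci: 19
autosomal plus 1 cytotype inherited strictly through the dam. Every
dispersal allele is dominant; a locus carrying at least one copy adds
0.05 to the dispersal probability (a line fixed for all 20 would
disperse with probability 1). P2 is fixed for dispersal alleles at 12
loci chosen uniformly among all 20 — the cytotype is eligible — and P1
at 1 locus chosen independently, matching the divergence of the
empirical selection lines (genotypic dispersal 0.60 vs 0.05). Gametes
assort freely; F1/rF1 are bred from parental gametes, backcrosses from
the stored F1/rF1 genomes. Every line, parentals included, is
phenotyped as 100 independent Bernoulli dispersal events (the paper-
level alternative — assigning parentals their exact genotypic value —
is rejected because WLS needs positive SEs for all cohorts).

Because the F1 expresses the *union* of both parents' dominant
dispersal sets, it frequently out-disperses P2: with the default
conditions the better F1-type cohort (F1 or rF1) exceeds P2 in ~68% of
replicates, with a mean excess of ~3.7 percentage points. Transgression
is scored on the two F1-type cohorts jointly — they are exchangeable
up to cytoplasm direction, and which one transgresses depends only on
which parent happened to carry the dispersal cytotype.

A `codominant` gene-action mode (0.025 per allele copy) plus
`n_p1_dispersal_loci=0` and a neutral cytotype gives a purely additive
truth, used to verify parameter recovery: the analysis then finds a
significant `Aa` and no significant epistasis in ≥80% of replicates.

Reproducibility: a master seed spawns one independent child stream per
replicate (numpy `SeedSequence`), so per-replicate results are
invariant to execution order and the whole study is reproducible from
the seed.

## Effect scope for simulated data

The simulated genome has no X or Y chromosome, and simulated cohorts
are sexless. Scoring simulated data against the full 27-effect matrix
therefore adds columns describing transmission the data cannot express;
on 8 pooled cohorts those columns are near-substitutes for their
autosomal counterparts (e.g. r(Aa, Xa) = 0.87), and their only effect
is to spread Akaike weight across tens of thousands of observationally
similar models, suppressing every importance score (the autosomal
additive effect then plateaus near 0.4 and is never called
significant). `simulation_study` therefore defaults to an
autosome+cytotype effect set — the 5 expressible simple effects plus
their 11 admissible products — under which the additive signal is
recovered reliably; the full matrix remains one switch away
(`effect_scope="full"`), and both behaviours are documented here
deliberately: the choice of effect scope is the single most influential
analysis decision for sparse cross designs.

This sensitivity is also the honest caveat on the simulation study.
The published analysis this package re-implements used a bespoke
supplementary C-matrix; with matrices reconstructible from stated
conventions, the additive-detection rate is essentially 0% (full set)
or ~100% (expressible set) rather than the intermediate ~70% reported
with the original matrix, and dispersion-induced epistasis is called
significant in only a few percent of replicates. What is robust across
all configurations is the headline comparison: dispersion alone
produces frequent transgressive segregation, while the epistatic:
additive ratios it induces are small — 90th percentile 0, maximum well
below 1 — an order of magnitude short of ratios in the empirical range
(≈5), so large inferred epistasis cannot be an artifact of dispersion.

## Default problem sizes

The replicated study defaults to 100 replicates of 100 individuals per
line. `scripts/acceptance.py` reports transgression statistics from
1000 simulation-only replicates (the transgressive count over the first
100, the mean excess over all 1000 so its Monte-Carlo error is ~0.2pp)
and runs the per-replicate exhaustive LCA on 30 replicates, a scale at
which detection proportions are stable to a few percentage points.

## Known limitations

* Digenic products assume free recombination; linked loci would need
  recombination-fraction-adjusted coefficients (out of scope).
* No higher-order epistasis, inbreeding-depression or scaled-variance
  parameterisations.
* The sex-split (16-cohort) analysis mode applies only to empirical
  tables that provide sex-specific cohorts; the simulator cannot
  generate them.
* Cohort means are proportions but the model is Gaussian; with n = 100
  per line the normal approximation is adequate away from 0 and 1, and
  the SE floor handles the boundary.
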
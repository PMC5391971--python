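# Methods

## The model

`ltbayes` fits spike-and-slab whole-genome regressions for genomic
prediction.  The joint model (`LTBayesCPi`) couples a continuous trait and a
categorical (usually binary) trait through a latent liability:

```
[y1; l] = [X1 0; 0 X2][b1; b2] + [Z 0; 0 Z][g1; g2] + [e1; e2]
```

where `Z` holds allele dosages 0/1/2, residual pairs are iid `N2(0, Re)`,
and each SNP either has zero effect on both traits (probability `pi`) or an
effect pair from a bivariate normal slab `N2(0, G0)`.  The observed category
is the interval of `l` between consecutive thresholds.  Sharing one
inclusion indicator per SNP across the traits is what lets the
low-information binary trait borrow strength from the continuous one; the
alternative (per-trait indicators) is deliberately not implemented.

Identifiability: a binary trait fixes the liability residual variance at 1
and the threshold at 0.  For k >= 3 categories the first two thresholds are
fixed at 0 and 1 and the liability residual variance is free; free
thresholds (k >= 4) have an ordered-uniform prior on `[t_min, t_max]`
(default: mean +/- 10 sd of the current liabilities).

Priors: fixed effects uniform (unbounded by default), `pi ~ U(0,1)`, and
`G0`, `Re` inverse-Wishart.  The hyper-parameters default to the improper
flat case (`v = -3`, zero scale).  `Priors.S_g`/`S_e` are the scale matrices
ADDED to the cross-products in the conditional updates (the inverse of the
V-hyper-matrix in the usual (v, V) parameterisation).

The single-trait special cases are `BayesCPi` (continuous; residual variance
sampled) and `BayesTCPi` (threshold trait; liability machinery with residual
variance fixed at 1), coded independently of the bivariate chain — the two
code paths cross-validate each other through the factorization property.

## Sampling scheme

One Gibbs cycle sweeps: liabilities -> fixed effects -> per-SNP
(indicator + effect pair, with the pair integrated out of the inclusion
odds) -> `G0` -> `Re` -> `pi` -> thresholds.  Liabilities go first so the
remainder of the cycle is conditionally Gaussian.  Derivations and closed
forms are in `derivations.md`.  Notable numerical choices:

* Degrees of freedom for `G0 | ELSE` use the number of INCLUDED SNPs
  (`v_g + m1`); a switch (`g0_df_uses_total_snps`) exposes the alternative
  `v_g + q`.  The joint-distribution (Geweke) test passes with `m1` and
  fails with `q`.
* When `m1` is too small for a proper flat-prior draw, `G0` falls back to a
  ridge scale (`Sg + 1e-6 I`) with floored df; logged at debug level.  This
  only matters in near-null chains.
* For a binary trait `Re` is drawn conditionally on `Re[2,2] = 1` with the
  Korsgaard construction (positive definite by construction); it was
  validated against a rejection-sampling oracle (KS < 0.01 per margin).
* Truncated-normal draws in the kernels use plain rejection near the bulk
  and Robert's exponential-proposal rejection beyond ~0.45 sd into a tail,
  which stays exact at extreme incidences (e.g. 5%).
* Monomorphic SNPs are retained in indexing but permanently excluded from
  the slab (their conditional posterior would be improper); `pi` updates
  count only eligible SNPs.
* Residuals are maintained incrementally (each SNP update is O(n)); the
  from-scratch vs incremental discrepancy is ~1e-13 over tens of thousands
  of cycles and is asserted in tests at 1e-8.
* Chain defaults: 50,000 cycles, 30,000 burn-in, thinning 1 (all kept
  samples averaged).  Determinism: one numpy Generator plus one seeded
  kernel RNG per chain, both derived from the chain seed; identical seeds
  give bit-identical summaries when chains run sequentially.

## The simulator

`sim.simulate_dataset` emulates a livestock genomic-selection design:
100 founders (50/50 sexes), 1,000 historical generations of random
monogamous mating at constant size with per-locus allele-flip mutation
(1.25e-3 per gamete) to reach mutation-drift equilibrium; generation 1
expands to 1,000 (20 offspring per founder female), generations 2-6 come
from 50 random sires x 10 dams x 2 offspring.  Five 1-Morgan chromosomes
carry 2,000 evenly spaced markers each (spacing L/m); a candidate QTL locus
sits at each adjacent-marker midpoint (switchable to QTL-on-marker-loci).
Meiosis is a Poisson crossover process, which reproduces Haldane's map
function exactly (no interference).  Mutation is disabled in generations
1-6 (it exists to build equilibrium polymorphism, and keeping it off
preserves exact Mendelian consistency for tests).

Genetic architecture: `n_qtl` QTL drawn from candidate loci segregating in
the training generations, split into pleiotropic / A-only / B-only groups
(0.8:0.1:0.1; 0:0.5:0.5 when r_AB = 0; largest-remainder rounding).
Pleiotropic pairs are bivariate normal.  Because the single-trait groups
dilute the TBV correlation, the within-group pair correlation is inflated
to `r_AB * sqrt((n1+n2)(n1+n3)) / n1` so the EXPECTED genetic correlation
of the true breeding values equals `r_AB`.  Effects are rescaled so the
realized TBV variances in the training generations equal `var_A = 2.0` and
`var_B = 1.0` exactly.  Environmental effects have variance
`var * (1 - h2) / h2` per trait (default heritabilities 0.3 and 0.1,
environmental correlation 0); the binary threshold is the empirical
(1 - incidence) order statistic of the training liabilities, which pins the
realized incidence to within one individual.  Phenotypes exist only for the
2,000 training individuals (generations 1-2); generations 3-6 are
validation candidates.

The marker panel for inference is the set of marker loci polymorphic in the
generation-0 founders.

What the simulator does NOT emulate: sequence-level mutation models and
realistic site-frequency spectra (the flip model gives a drift-equilibrium
U-shaped MAF spectrum, not a neutral-theory SFS), selection during the
recent generations, genotyping error or missingness, epistasis and
imprinting, environmental trends.  Passing tests therefore demonstrate
correctness of the samplers and the qualitative behaviour of joint vs
single-trait prediction under idealized LD, not performance on real data.

## Evaluation

GEBV = `Z_candidate @ posterior-mean effects` per trait; accuracy is the
Pearson correlation with the true breeding values per candidate generation;
bias is the OLS slope of TBV on GEBV.  For the threshold trait the GEBV
lives on the analysis liability scale (residual variance 1), so the slope
is also reported rescaled: `slope / v_e2` (the literal convention, primary)
and `slope / sqrt(v_e2)` alongside, where `v_e2` is the generating residual
liability variance.  Dimensional analysis favours the square-root version
(liability scales are sd-proportional) and it is the one that lands near 1
in practice; both are always reported.  Method comparisons across
replicates use a paired two-sided t-test (both methods see identical data
per replicate); degenerate cases are reported as t=0, p=1 (all differences
zero) or +/-inf, p=0 (constant non-zero difference).

## Experiments and problem sizes

`experiments.run_scenario` reproduces the simulation-study structure:
a standard scenario (h2 = 0.3/0.1, 60 QTL, r_AB = 0.5, incidence 0.30) plus
one-factor-at-a-time variations (r_AB in {0, 0.2, 0.8}; QTL in
{20, 200, 500}; h2_A in {0.5, 0.8}; h2_B in {0.3, 0.5}; incidence in
{0.05, 0.1, 0.5}), 20 replicates each at full scale.  `scale_factor`
shrinks markers, training individuals and chain length proportionally
(floor 3,000 cycles / 1,500 burn-in) for desk-scale runs; it is an
approximation knob, recorded in every output row.

The bundled test suite and the acceptance script run scaled-down problems
chosen to preserve the study's marker DENSITY (0.05 cM) rather than its
genome length — thinning markers instead degrades LD tagging and moves the
spike-and-slab posterior into a diffuse many-small-effects regime that does
not represent the full-scale design.  Sizes used: sampler-correctness tests
on n = 25-2,000 and q = 10-1,000; the acceptance study is a fully
proportional 1/5-scale replica (1 chromosome x 1 Morgan x 2,000 markers and
12 QTL — genome length, marker count and QTL count divided together, which
preserves marker density, QTL density per Morgan and per-QTL signal), with
the full demography (2,000 training individuals), 4 replicates and
15,000/7,500-cycle chains.  Keeping the QTL count while shrinking the
genome would put every marker in LD with signal and push the posterior into
the diffuse mode; the proportional replica avoids that distortion.

## Known limitations

* Per-replicate posterior summaries at reduced scale are noisy: the
  estimated genetic correlation has a per-replicate sd around 0.1-0.16 and
  the estimated proportion of non-zero SNPs can occupy a diffuse mode when
  LD tagging is imperfect; replicate averages are the meaningful quantity,
  as in the full-scale study design.
* The proportion of non-zero SNPs is only comparable to n_qtl / q when
  every QTL is individually detectable and tagged by ~one marker; at small
  q the same absolute miss in the included-SNP count is a much larger
  proportion error.
* No pedigree/polygenic residual term, no more than two traits, no
  missing-phenotype handling (rows must be complete for the fitted method).
* Numba kernels use the global numba RNG; chains are deterministic when run
  sequentially but not under concurrent execution in one process.
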
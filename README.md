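# ltbayes

Joint Bayesian genomic prediction for one continuous and one binary
(threshold) trait.

In animal and plant breeding, selection decisions often involve a
continuous trait (growth rate, yield) together with a binary one (disease
status, leg weakness, calving ease).  Binary traits typically have little
information per record, so single-trait genomic prediction is weak for
them.  `ltbayes` implements a bivariate **linear-threshold spike-and-slab
model** ("LT-BayesCπ") that predicts both traits jointly, letting the
binary trait borrow information from the correlated continuous one, plus
the two single-trait special cases (BayesCπ for a continuous trait,
BayesTCπ for a threshold trait), a forward-in-time two-trait population
simulator, and accuracy/bias evaluation utilities.

## The model

With dosages `Z` (0/1/2), continuous observations `y₁` and a latent
liability `l` underlying the binary codes `y₂` (`y₂ᵢ = 1{lᵢ > 0}`):

```
[y₁; l] = [X₁ 0; 0 X₂][β₁; β₂] + [Z 0; 0 Z][g₁; g₂] + [e₁; e₂]
(e₁ᵢ, e₂ᵢ)' ~ N₂(0, Rₑ)
(g₁ⱼ, g₂ⱼ) = 0                with probability π      (shared indicator δⱼ)
(g₁ⱼ, g₂ⱼ) ~ N₂(0, G₀)       with probability 1 − π
```

`π`, `G₀`, `Rₑ`, the effects and the liabilities are all estimated by
Gibbs sampling; identifiability for the binary trait is obtained by fixing
the liability residual variance at 1 and the threshold at 0, with the
residual covariance matrix drawn from its conditional inverse-Wishart
distribution (Korsgaard construction).  Genomic estimated breeding values
(GEBVs) are `Z · ĝ` with posterior-mean effects `ĝ`.  See
`docs/methods.md` and `docs/derivations.md` for the full account.

## Worked example

Simulate a 1/10-scale replica of the validation design (1,000 markers at
0.05 cM spacing, 6 QTL, heritabilities 0.3 and 0.1, genetic correlation
target 0.5, incidence 0.30; 2,000 phenotyped training individuals in
generations 1–2) and compare joint vs single-trait prediction on
generation-3 candidates:

```python
import numpy as np
from ltbayes import LTBayesCPi, BayesTCPi, accuracy
from ltbayes.sim import (ArchitectureConfig, DemographyConfig, GenomeConfig,
                         simulate_dataset)

genome = GenomeConfig(n_chromosomes=1, chrom_length_morgan=0.5,
                      n_markers_per_chrom=1000)
demo = DemographyConfig(n_historical_generations=1000)
arch = ArchitectureConfig(n_qtl=6)   # h2 = 0.3/0.1, r_AB = 0.5, incidence 0.30
ds = simulate_dataset(genome, demo, arch, seed=7)

train, gen3 = ds.training, ds.generation == 3
X, Xc = ds.genotypes[train].astype(float), ds.genotypes[gen3].astype(float)
Y = np.column_stack([ds.pheno_A[train], ds.pheno_B[train]])

joint = LTBayesCPi(n_cycles=10_000, burn_in=5_000, random_state=0).fit(X, Y)
single = BayesTCPi(n_cycles=10_000, burn_in=5_000, random_state=0).fit(
    X, Y[:, 1].astype(int))

gebv = joint.predict(Xc)
print(f"accuracy trait A (joint):        {accuracy(ds.tbv_A[gen3], gebv[:, 0]):.3f}")
print(f"accuracy trait B (joint):        {accuracy(ds.tbv_B[gen3], gebv[:, 1]):.3f}")
print(f"accuracy trait B (single-trait): {accuracy(ds.tbv_B[gen3], single.predict(Xc)):.3f}")
print(f"estimated genetic correlation:   {joint.genetic_correlation_:.3f}")
```

Output (about a minute):

```
accuracy trait A (joint):        0.905
accuracy trait B (joint):        0.834
accuracy trait B (single-trait): 0.793
estimated genetic correlation:   0.866
```

Accuracy is the correlation between true breeding values (known from the
simulator) and GEBVs.  The joint model lifts the binary trait's accuracy
over the single-trait threshold model (0.834 vs 0.793 here) while the
continuous trait is unaffected, and the estimated genetic correlation
tracks the realized TBV correlation of this replicate (0.905 — with only
6 QTL it varies widely around the 0.5 target across replicates).

A command-line interface mirrors the library:

```
ltbayes simulate --seed 1 --out rep1/
ltbayes fit --method lt-bayescpi --genotypes rep1/genotypes.tsv \
    --phenotypes rep1/phenotypes.tsv --cycles 50000 --burn-in 30000 \
    --seed 1 --out fit1/
ltbayes evaluate --posterior fit1/ --genotypes rep1/genotypes.tsv \
    --truth rep1/phenotypes.tsv --v-e2 9.0 --out report.tsv
ltbayes experiment --scale 0.1 --replicates 5 --scenarios standard --out results/
```

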
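# Derivation of the single-site samplers

## Model

For individual i with dosage row `z_i` (length q):

```
y1_i = x1_i' b1 + z_i' g1 + e1_i        (continuous trait)
l_i  = x2_i' b2 + z_i' g2 + e2_i        (liability of the categorical trait)
(e1_i, e2_i)' ~ N2(0, Re),   iid over i
```

The observed category is determined by thresholds on `l`: binary traits use
`y2_i = 1{l_i > 0}` with `Re[2,2] = 1` fixed; k >= 3 categories fix
`t1 = 0, t2 = 1` and leave the liability residual variance free.

Each SNP j carries a shared inclusion indicator `delta_j`:

```
(g1j, g2j) = 0                 with probability pi
(g1j, g2j) ~ N2(0, G0)         with probability 1 - pi
```

## Liability update

Given everything else, `(y1_i, l_i)` is bivariate normal around its fitted
values, so `l_i | ELSE` is the usual conditional normal

```
E[l_i | ELSE]   = x2_i' b2 + z_i' g2 + (s12 / s11) (y1_i - x1_i' b1 - z_i' g1)
Var[l_i | ELSE] = s22 (1 - s12^2 / (s11 s22))
```

(with `Re = [[s11, s12], [s12, s22]]`), truncated to the category interval
`(t_{j-1}, t_j]`.

## SNP update with the effect pair integrated out

Let `r_t = e_t + z_j g_tj` be the residuals with SNP j's current
contribution added back, `c = z_j' z_j` and `s = (z_j' r1, z_j' r2)'`.
Viewing the two stacked traits as one Gaussian likelihood with residual
covariance `Re (x) I`, the effect pair has likelihood precision `c Re^{-1}`
and likelihood-score vector `b = Re^{-1} s`.  With the slab prior
`N2(0, G0)` the conditional posterior under `delta_j = 1` is

```
(g1j, g2j) | delta_j = 1, ELSE ~ N2(P^{-1} b, P^{-1}),   P = c Re^{-1} + G0^{-1}
```

Integrating the pair out gives the marginal-likelihood ratio (Bayes factor)
of slab vs spike:

```
BF_j = |I2 + c Re^{-1} G0|^{-1/2}  exp( b' P^{-1} b / 2 )
```

and the Bernoulli conditional

```
P(delta_j = 1 | ELSE) = (1 - pi) BF_j / (pi + (1 - pi) BF_j).
```

`BF_j` is computed in closed 2x2 form in the kernel; it was verified against
brute-force evaluation of the two n-dimensional multivariate-normal marginal
likelihoods (agreement to ~1e-14).

### Single-trait special case and factorization

For one trait the same algebra collapses to

```
v_post = (c / se2 + 1 / sg2)^{-1},  m_post = v_post z'r / se2,
log BF = log sqrt(v_post / sg2) + (z'r)^2 v_post / (2 se2^2)
```

which is the classical spike-and-slab odds.  When `G0` and `Re` are both
diagonal, `|I + c Re^{-1} G0|` and the quadratic form factor across traits,
so the bivariate log-odds equal the sum of the two single-trait log-odds
exactly; the test suite checks this identity (tolerance 1e-10) against the
independently coded single-trait route, and checks the induced chain-level
factorization (a covariance-constrained joint chain reproduces the two
single-trait chains' posterior-mean effects).

## Location parameters

With the mixed-model equations `C theta = r`, coordinate i has conditional
`theta_i | ELSE ~ N(C_ii^{-1} (r_i - C_{i,-i} theta_{-i}), C_ii^{-1})`.
For a fixed-effect column `x` of trait t this specializes (writing
`W = Re^{-1}`) to precision `W_tt x'x` and mean
`(W_tt x'r_t + W_ts x'e_s) / (W_tt x'x)`, which is what the chain uses with
incrementally maintained residuals.

## Dispersion parameters

With `Sg` the 2x2 cross-product of included effect pairs and m1 the included
count, flat priors give `G0 | ELSE ~ IW(scale = Sg, df = m1 - 3)` (scipy
convention).  The degrees of freedom count the pairs actually contributing
to `Sg`; using the total SNP count instead makes the joint-distribution
(Geweke) validation fail.  The residual update is
`Re | ELSE ~ IW(scale = Se, df = n - 3)`, replaced for a binary trait by the
conditional draw given `Re[2,2] = 1`:

```
V = (Se)^{-1} = [[V11, V12], [V12, V22]]
x1 ~ W1(V11, n - 3)            (= V11 * chi-square(n - 3))
x2 ~ N(V12 / V11, V22.1 / x1),  V22.1 = V22 - V12^2 / V11
Re = [[1/x1 + x2^2, -x2], [-x2, 1]]
```

`Re[1,1] - Re[1,2]^2 = 1/x1 > 0`, so the draw is positive definite by
construction.  With a proper prior the same construction applies with
`scale = S_e_prior + Se` and `df = v_e + n`.

## pi

With `pi ~ U(0,1)` and q - m1 zeros among q Bernoulli indicators,
`pi | ELSE ~ Beta(q - m1 + 1, m1 + 1)`.
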
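"""Numba kernels for the hot loops: truncated-normal draws, liability sweeps,
per-SNP spike-and-slab sweeps, and gamete formation for the simulator.

All kernels draw from numba's internal RNG, which is seeded once per chain /
simulation via :func:`seed_kernel_rng`.  Python-level code uses a separate
``numpy.random.Generator``; both are derived from the user seed, so a run is
deterministic end to end.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit


@njit(cache=True)
def seed_kernel_rng(seed):
    np.random.seed(seed)


# ---------------------------------------------------------------------------
# truncated standard normal
# ---------------------------------------------------------------------------


@njit(cache=True)
def _rtnorm_left(a):
    """Draw x ~ N(0,1) conditional on x >= a (a may be very large)."""
    if a < 0.45:
        # plain rejection: acceptance >= P(X >= 0.45) ~ 0.33
        while True:
            x = np.random.normal()
            if x >= a:
                return x
    # Robert (1995) exponential-proposal rejection for the upper tail
    lam = 0.5 * (a + math.sqrt(a * a + 4.0))
    while True:
        x = a + np.random.exponential(1.0 / lam)
        d = x - lam
        if math.log(np.random.random()) <= -0.5 * d * d:
            return x


@njit(cache=True)
def rtnorm_std(a, b):
    """Standard normal truncated to (a, b); either bound may be +/-inf."""
    if a == -np.inf and b == np.inf:
        return np.random.normal()
    if b == np.inf:
        return _rtnorm_left(a)
    if a == -np.inf:
        return -_rtnorm_left(-b)
    # two-sided
    if a < 0.0 and b > 0.0 and (b - a) > 1.0:
        while True:
            x = np.random.normal()
            if a < x <= b:
                return x
    # uniform proposal with the mode of the restricted density
    if a > 0.0:
        m = a * a
    elif b < 0.0:
        m = b * b
    else:
        m = 0.0
    while True:
        x = a + (b - a) * np.random.random()
        if math.log(np.random.random()) <= 0.5 * (m - x * x):
            return x


# ---------------------------------------------------------------------------
# liability sweeps
# ---------------------------------------------------------------------------


@njit(cache=True)
def sweep_liabilities(l, e2, e1, lo, hi, reg, cond_sd):
    """One pass of single-site liability updates (in place).

    l        current liabilities (length n)
    e2       running residual of the liability trait: e2 = l - fitted2
    e1       running residual of the continuous trait (zeros for the
             single-trait threshold model)
    lo, hi   per-individual truncation bounds from the category thresholds
    reg      regression coefficient sigma_e12 / sigma_e1^2 (0 if univariate)
    cond_sd  sqrt of the conditional residual variance of the liability
    """
    n = l.shape[0]
    for i in range(n):
        fitted = l[i] - e2[i]
        mu = fitted + reg * e1[i]
        a = (lo[i] - mu) / cond_sd
        b = (hi[i] - mu) / cond_sd
        lnew = mu + cond_sd * rtnorm_std(a, b)
        e2[i] += lnew - l[i]
        l[i] = lnew


# ---------------------------------------------------------------------------
# per-SNP spike-and-slab sweeps
# ---------------------------------------------------------------------------


@njit(cache=True)
def sweep_snps_bivariate(Z, zz, e1, e2, g1, g2, delta, eligible,
                         g0_11, g0_12, g0_22, r11, r12, r22, pi):
    """One pass over all SNPs of the bivariate spike-and-slab update.

    Z must be Fortran-ordered float64 (n x q); zz[j] = Z[:,j]'Z[:,j].
    Residuals e1, e2 (liability scale for trait 2) are updated in place and
    exclude nothing: the current effect of SNP j is added back on the fly.
    Returns the number of included SNPs.
    """
    n, q = Z.shape
    log_prior_odds = math.log1p(-pi) - math.log(pi)

    # residual precision W = Re^{-1}
    dre = r11 * r22 - r12 * r12
    w11 = r22 / dre
    w22 = r11 / dre
    w12 = -r12 / dre
    # slab precision G0^{-1}
    dg = g0_11 * g0_22 - g0_12 * g0_12
    q11 = g0_22 / dg
    q22 = g0_11 / dg
    q12 = -g0_12 / dg

    m1 = 0
    for j in range(q):
        if not eligible[j]:
            continue
        c = zz[j]
        old1 = g1[j]
        old2 = g2[j]
        included = delta[j] == 1
        # z_j' r_t with the SNP's own contribution added back
        s1 = 0.0
        s2 = 0.0
        for i in range(n):
            zij = Z[i, j]
            s1 += zij * e1[i]
            s2 += zij * e2[i]
        if included:
            s1 += c * old1
            s2 += c * old2

        b1 = w11 * s1 + w12 * s2
        b2 = w12 * s1 + w22 * s2
        # posterior precision P = c W + G0^{-1}
        p11 = c * w11 + q11
        p12 = c * w12 + q12
        p22 = c * w22 + q22
        dp = p11 * p22 - p12 * p12
        v11 = p22 / dp
        v22 = p11 / dp
        v12 = -p12 / dp
        quad = b1 * b1 * v11 + 2.0 * b1 * b2 * v12 + b2 * b2 * v22
        # |I + c W G0|
        m11 = 1.0 + c * (w11 * g0_11 + w12 * g0_12)
        m12 = c * (w11 * g0_12 + w12 * g0_22)
        m21 = c * (w12 * g0_11 + w22 * g0_12)
        m22 = 1.0 + c * (w12 * g0_12 + w22 * g0_22)
        log_bf = -0.5 * math.log(m11 * m22 - m12 * m21) + 0.5 * quad

        logit = log_prior_odds + log_bf
        if logit > 35.0:
            p_in = 1.0
        elif logit < -35.0:
            p_in = 0.0
        else:
            p_in = 1.0 / (1.0 + math.exp(-logit))

        if np.random.random() < p_in:
            # draw the pair from N(P^{-1} b, P^{-1})
            mean1 = v11 * b1 + v12 * b2
            mean2 = v12 * b1 + v22 * b2
            l11 = math.sqrt(v11)
            l21 = v12 / l11
            l22 = math.sqrt(max(v22 - l21 * l21, 1e-300))
            u1 = np.random.normal()
            u2 = np.random.normal()
            new1 = mean1 + l11 * u1
            new2 = mean2 + l21 * u1 + l22 * u2
            d1 = new1 - (old1 if included else 0.0)
            d2 = new2 - (old2 if included else 0.0)
            for i in range(n):
                zij = Z[i, j]
                e1[i] -= zij * d1
                e2[i] -= zij * d2
            g1[j] = new1
            g2[j] = new2
            delta[j] = 1
            m1 += 1
        else:
            if included:
                for i in range(n):
                    zij = Z[i, j]
                    e1[i] += zij * old1
                    e2[i] += zij * old2
            g1[j] = 0.0
            g2[j] = 0.0
            delta[j] = 0
    return m1


@njit(cache=True)
def sweep_snps_single(Z, zz, e, g, delta, eligible, sg2, se2, pi):
    """One pass of the single-trait spike-and-slab update; returns m1.

    Coded independently of the bivariate kernel (scalar algebra throughout);
    the factorisation of the bivariate inclusion odds at zero covariances is
    checked against this route in the tests.
    """
    n, q = Z.shape
    log_prior_odds = math.log1p(-pi) - math.log(pi)
    m1 = 0
    for j in range(q):
        if not eligible[j]:
            continue
        c = zz[j]
        old = g[j]
        included = delta[j] == 1
        s = 0.0
        for i in range(n):
            s += Z[i, j] * e[i]
        if included:
            s += c * old
        b = s / se2
        var_post = 1.0 / (c / se2 + 1.0 / sg2)
        mean_post = var_post * b
        log_bf = 0.5 * math.log(var_post / sg2) + 0.5 * b * b * var_post
        logit = log_prior_odds + log_bf
        if logit > 35.0:
            p_in = 1.0
        elif logit < -35.0:
            p_in = 0.0
        else:
            p_in = 1.0 / (1.0 + math.exp(-logit))
        if np.random.random() < p_in:
            new = mean_post + math.sqrt(var_post) * np.random.normal()
            d = new - (old if included else 0.0)
            for i in range(n):
                e[i] -= Z[i, j] * d
            g[j] = new
            delta[j] = 1
            m1 += 1
        else:
            if included:
                for i in range(n):
                    e[i] += Z[i, j] * old
            g[j] = 0.0
            delta[j] = 0
    return m1


# ---------------------------------------------------------------------------
# simulator: gamete formation and population loops
# ---------------------------------------------------------------------------


@njit(cache=True)
def _make_gamete(hap0, hap1, pos, chrom_start, chrom_len, mu, out):
    """Meiosis with a Poisson crossover process (Haldane: no interference).

    hap0/hap1: parental haplotypes (uint8, length L); pos: genetic position
    in Morgan within the chromosome; chrom_start: first-locus index per
    chromosome (length n_chrom + 1, last entry L); chrom_len: Morgan per
    chromosome; mu: per-locus flip probability (0 disables mutation).
    """
    n_chrom = chrom_len.shape[0]
    for c in range(n_chrom):
        s = chrom_start[c]
        e = chrom_start[c + 1]
        nx = np.random.poisson(chrom_len[c])
        xo = np.sort(np.random.random(nx) * chrom_len[c])
        cur = 0 if np.random.random() < 0.5 else 1
        k = 0
        for i in range(s, e):
            while k < nx and xo[k] < pos[i]:
                cur = 1 - cur
                k += 1
            out[i] = hap0[i] if cur == 0 else hap1[i]
    if mu > 0.0:
        L = out.shape[0]
        nmut = np.random.binomial(L, mu)
        for _ in range(nmut):
            i = np.random.randint(L)
            out[i] = 1 - out[i]


@njit(cache=True)
def run_history(haps, n_generations, pos, chrom_start, chrom_len, mu):
    """Random-mating history at constant size with mutation.

    haps: (2N, L) uint8, N individuals (first N//2 male, rest female), rows
    2i, 2i+1 are individual i's haplotypes.  Each generation pairs a random
    permutation of males with a random permutation of females; every pair
    leaves one male and one female offspring.  Returns the final haplotypes.
    """
    n2, L = haps.shape
    N = n2 // 2
    half = N // 2
    cur = haps.copy()
    nxt = np.empty_like(cur)
    for _ in range(n_generations):
        pm = np.random.permutation(half)
        pf = np.random.permutation(half)
        for p in range(half):
            sire = pm[p]
            dam = half + pf[p]
            # male offspring p, female offspring half + p
            for off, row in ((p, 2 * p), (half + p, 2 * (half + p))):
                _make_gamete(cur[2 * sire], cur[2 * sire + 1], pos,
                             chrom_start, chrom_len, mu, nxt[row])
                _make_gamete(cur[2 * dam], cur[2 * dam + 1], pos,
                             chrom_start, chrom_len, mu, nxt[row + 1])
        tmp = cur
        cur = nxt
        nxt = tmp
    return cur


@njit(cache=True)
def breed_offspring(par_haps, sire_idx, dam_idx, pos, chrom_start, chrom_len,
                    mu):
    """Produce offspring haplotypes (2n_off, L) from indexed parents."""
    n_off = sire_idx.shape[0]
    L = par_haps.shape[1]
    out = np.empty((2 * n_off, L), dtype=np.uint8)
    for o in range(n_off):
        s = sire_idx[o]
        d = dam_idx[o]
        _make_gamete(par_haps[2 * s], par_haps[2 * s + 1], pos, chrom_start,
                     chrom_len, mu, out[2 * o])
        _make_gamete(par_haps[2 * d], par_haps[2 * d + 1], pos, chrom_start,
                     chrom_len, mu, out[2 * o + 1])
    return out
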
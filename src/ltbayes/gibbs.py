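"""Gibbs samplers for spike-and-slab whole-genome regression.

Three chains are provided:

* ``BivariateChain`` — the joint linear-threshold model (one continuous and
  one categorical trait; "LT-BayesCpi").  For a binary trait the liability
  residual variance is fixed at 1 and the threshold at 0; the residual
  covariance matrix is then updated with the conditional inverse-Wishart
  algorithm of Korsgaard et al.
* ``SingleTraitChain`` — BayesCpi (continuous) and its threshold-trait
  analogue BayesTCpi, coded independently of the bivariate chain.

Every full cycle sweeps: liabilities -> fixed effects -> per-SNP
(indicator, effect pair) -> G0 -> Re -> pi -> thresholds.

The per-SNP update marginalises the effect pair out of the inclusion odds:
with c = z'z, s = z'r (effect added back), b = Re^{-1} s,

    BF_j = |I + c Re^{-1} G0|^{-1/2} exp( b' (c Re^{-1} + G0^{-1})^{-1} b / 2 )
    P(delta_j = 1 | ELSE) = (1-pi) BF_j / (pi + (1-pi) BF_j)

and, when included, (g1j, g2j) ~ N(P^{-1} b, P^{-1}) with
P = c Re^{-1} + G0^{-1}.  See docs/derivations.md.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from . import _kernels
from .model import (InputError, ModelState, PosteriorSummary, Priors,
                    SufficientStats, TrainingData, category_bounds,
                    initialize_state, validate)

logger = logging.getLogger(__name__)

METHODS = ("lt-bayescpi", "bayescpi", "bayestcpi")


class NumericalError(RuntimeError):
    """The sampler reached a numerically invalid state."""


@dataclass
class ChainConfig:
    """Chain orchestration settings.

    Defaults follow the analysis protocol of 50,000 cycles with the first
    30,000 discarded and no thinning (all kept samples averaged).
    """

    n_cycles: int = 50_000
    burn_in: int = 30_000
    thinning: int = 1
    seed: int = 0
    method: str = "lt-bayescpi"
    constrain_zero_covariance: bool = False
    g0_df_uses_total_snps: bool = False

    def __post_init__(self):
        if self.method not in METHODS:
            raise InputError(f"unknown method {self.method!r}; "
                             f"choose from {METHODS}")
        if not 0 <= self.burn_in < self.n_cycles:
            raise InputError("burn_in must be in [0, n_cycles)")
        if self.thinning < 1:
            raise InputError("thinning must be >= 1")


# ---------------------------------------------------------------------------
# dispersion-parameter draws
# ---------------------------------------------------------------------------


def draw_invwishart(rng, scale: np.ndarray, df: float) -> np.ndarray:
    """Inverse-Wishart draw (scipy convention: mean = scale / (df - p - 1))."""
    scale = np.atleast_2d(scale)
    p = scale.shape[0]
    if p == 1:
        return np.array([[scale[0, 0] / rng.chisquare(df)]])
    return np.atleast_2d(stats.invwishart.rvs(df=df, scale=scale,
                                              random_state=rng))


def sample_g0(stats_: SufficientStats, priors: Priors, rng,
              q_eligible: int | None = None,
              use_total_snps: bool = False) -> np.ndarray:
    """Conditional draw of the SNP-effect covariance G0.

    Degrees of freedom use the number of *included* SNPs (v_g + m1); the
    literal total-SNP-count reading (v_g + q) is available behind
    ``use_total_snps``.  With the flat prior and too few included SNPs the
    cross-product matrix is rank deficient; a small ridge plus a floored df
    keeps the chain alive (logged).
    """
    Sg = np.atleast_2d(stats_.Sg)
    dim = Sg.shape[0]
    scale = priors.g_scale(dim) + Sg
    count = q_eligible if use_total_snps else stats_.m1
    df = priors.v_g + count
    min_df = dim + 0.5   # proper draw needs df > dim - 1; keep margin
    eig_ok = np.all(np.linalg.eigvalsh(scale) > 1e-12)
    if df < min_df or not eig_ok:
        scale = scale + 1e-6 * np.eye(dim)
        df = max(df, dim + 2.0)
        logger.debug("G0 fallback draw (m1=%d): ridge scale, df=%.1f",
                     stats_.m1, df)
    return draw_invwishart(rng, scale, df)


def sample_re_full(stats_: SufficientStats, priors: Priors, n: int,
                   rng) -> np.ndarray:
    """Unconstrained residual-covariance draw: IW(S_e_prior + Se, v_e + n)."""
    Se = np.atleast_2d(stats_.Se)
    dim = Se.shape[0]
    scale = priors.e_scale(dim) + Se
    df = priors.v_e + n
    if df <= dim - 1:
        raise NumericalError(f"residual df {df} too small for dim {dim}")
    return draw_invwishart(rng, scale, df)


def sample_re_conditional(stats_: SufficientStats, n: int, rng,
                          priors: Priors | None = None) -> np.ndarray:
    """Residual-covariance draw conditional on the liability variance = 1.

    Korsgaard-style construction: with Psi = S_e_prior + Se and
    df = v_e + n (flat prior: Psi = Se, df = n - 3), let V = Psi^{-1}
    partitioned [[V11, V12], [V12, V22]]; draw

        x1 ~ W_1(V11, df)                (= V11 * chi-square(df))
        x2 ~ N(V11^{-1} V12, x1^{-1} V22.1),  V22.1 = V22 - V12^2 / V11

    and return [[x1^{-1} + x2^2, -x2], [-x2, 1]].  The construction makes
    T11 - T12^2 = x1^{-1} > 0, so the result is always positive definite.
    """
    Se = np.atleast_2d(stats_.Se)
    if priors is None:
        priors = Priors()
    psi = priors.e_scale(2) + Se
    df = priors.v_e + n
    det = psi[0, 0] * psi[1, 1] - psi[0, 1] ** 2
    if det <= 0 or psi[0, 0] <= 0:
        raise NumericalError("singular residual cross-product matrix")
    v11 = psi[1, 1] / det
    v12 = -psi[0, 1] / det
    v22 = psi[0, 0] / det
    x1 = v11 * rng.chisquare(df)
    v22_1 = v22 - v12 ** 2 / v11
    x2 = rng.normal(v12 / v11, np.sqrt(v22_1 / x1))
    t11 = 1.0 / x1 + x2 ** 2
    return np.array([[t11, -x2], [-x2, 1.0]])


def sample_pi(m1: int, q: int, rng) -> float:
    """pi | ELSE ~ Beta(q - m1 + 1, m1 + 1) (pi = probability of zero)."""
    return float(rng.beta(q - m1 + 1, m1 + 1))


def sample_location(C: np.ndarray, r: np.ndarray, theta: np.ndarray, i: int,
                    rng) -> float:
    """Single-site draw for coordinate i of the mixed-model equations
    C theta = r:  theta_i | ELSE ~ N(C_ii^{-1}(r_i - C_{i,-i} theta_{-i}),
    C_ii^{-1}).  Updates theta in place and returns the draw."""
    cii = C[i, i]
    if cii <= 0:
        logger.warning("degenerate MME coordinate %d skipped", i)
        return theta[i]
    adj = C[i] @ theta - cii * theta[i]
    mean = (r[i] - adj) / cii
    theta[i] = rng.normal(mean, np.sqrt(1.0 / cii))
    return theta[i]


def _draw_truncnorm(rng, mean, sd, lo, hi):
    if lo == -np.inf and hi == np.inf:
        return rng.normal(mean, sd)
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return float(stats.truncnorm.rvs(a, b, loc=mean, scale=sd,
                                     random_state=rng))


# ---------------------------------------------------------------------------
# chains
# ---------------------------------------------------------------------------


class _ChainBase:
    """Shared bookkeeping: residual recomputation, accumulation, reporting."""

    def residual_drift(self) -> float:
        """Max |incremental - from-scratch| residual; bookkeeping check."""
        fresh = self._residuals_from_scratch()
        drift = 0.0
        for inc, scr in zip(self._residual_views(), fresh):
            drift = max(drift, float(np.max(np.abs(inc - scr))))
        return drift

    def _nan_guard(self, cycle):
        for arr in self._residual_views():
            if not np.isfinite(arr).all():
                raise NumericalError(
                    f"non-finite residuals at cycle {cycle}; state: "
                    f"G0={self.state.G0!r} Re={self.state.Re!r} "
                    f"pi={self.state.pi!r}")


class BivariateChain(_ChainBase):
    """Joint chain for one continuous trait and one categorical trait."""

    def __init__(self, data: TrainingData, priors: Priors | None = None,
                 config: ChainConfig | None = None,
                 state: ModelState | None = None):
        self.data = validate(data)
        if data.y1 is None or data.y2 is None:
            raise InputError("the joint model needs both traits observed")
        self.priors = priors or Priors()
        self.config = config or ChainConfig()
        self.rng = np.random.default_rng(self.config.seed)
        self.state = state if state is not None else initialize_state(
            data, self.priors, self.config.seed, "lt-bayescpi")
        _kernels.seed_kernel_rng(int(self.rng.integers(2 ** 31)))
        self.zz = np.einsum("ij,ij->j", data.Z, data.Z)
        self.eligible = ~data.monomorphic
        self.q_eligible = int(self.eligible.sum())
        self.binary = data.k == 2
        self.e1, self.e2 = self._residuals_from_scratch()
        self.m1 = int(self.state.delta.sum())

    # residuals ------------------------------------------------------------
    def _residuals_from_scratch(self):
        d, s = self.data, self.state
        e1 = d.y1 - d.X1 @ s.beta1 - d.Z @ s.g1
        e2 = s.liability - d.X2 @ s.beta2 - d.Z @ s.g2
        return e1, e2

    def _residual_views(self):
        return (self.e1, self.e2)

    # samplers -------------------------------------------------------------
    def step_liabilities(self):
        s = self.state
        Re = s.Re
        cond_var = Re[1, 1] * (1.0 - Re[0, 1] ** 2 / (Re[0, 0] * Re[1, 1]))
        if cond_var <= 0:
            raise NumericalError("residual covariance not positive definite")
        reg = Re[0, 1] / Re[0, 0]
        lo, hi = category_bounds(self.data.y2, s.thresholds)
        _kernels.sweep_liabilities(s.liability, self.e2, self.e1, lo, hi,
                                   reg, np.sqrt(cond_var))

    def step_fixed_effects(self):
        s = self.state
        W = np.linalg.inv(s.Re)
        lo, hi = self.priors.beta_bounds
        for t, (X, beta, e_own, e_oth, w_own, w_cross) in enumerate((
                (self.data.X1, s.beta1, self.e1, self.e2, W[0, 0], W[0, 1]),
                (self.data.X2, s.beta2, self.e2, self.e1, W[1, 1], W[0, 1]))):
            for j in range(X.shape[1]):
                x = X[:, j]
                c = x @ x
                if c <= 0:
                    logger.warning("degenerate fixed-effect column skipped")
                    continue
                s_own = x @ e_own + c * beta[j]
                s_oth = x @ e_oth
                mean = (w_own * s_own + w_cross * s_oth) / (w_own * c)
                sd = np.sqrt(1.0 / (w_own * c))
                new = _draw_truncnorm(self.rng, mean, sd, lo, hi)
                e_own -= x * (new - beta[j])
                beta[j] = new

    def step_snps(self):
        s = self.state
        G0, Re = s.G0, s.Re
        self.m1 = _kernels.sweep_snps_bivariate(
            self.data.Z, self.zz, self.e1, self.e2, s.g1, s.g2, s.delta,
            self.eligible, G0[0, 0], G0[0, 1], G0[1, 1],
            Re[0, 0], Re[0, 1], Re[1, 1], s.pi)

    def sufficient_stats(self) -> SufficientStats:
        inc = self.state.delta == 1
        g = np.vstack([self.state.g1[inc], self.state.g2[inc]])
        Sg = g @ g.T
        e = np.vstack([self.e1, self.e2])
        Se = e @ e.T
        return SufficientStats(Se=Se, Sg=Sg, m1=int(inc.sum()))

    def step_g0(self, stats_: SufficientStats | None = None):
        stats_ = stats_ or self.sufficient_stats()
        if self.config.constrain_zero_covariance:
            G = np.zeros((2, 2))
            for t in range(2):
                sub = SufficientStats(Se=None, m1=stats_.m1,
                                      Sg=np.array([[stats_.Sg[t, t]]]))
                pr = Priors(v_g=self.priors.v_g,
                            S_g=np.atleast_2d(self.priors.g_scale(2))[t:t+1,
                                                                      t:t+1])
                G[t, t] = sample_g0(sub, pr, self.rng, self.q_eligible,
                                    self.config.g0_df_uses_total_snps)[0, 0]
            self.state.G0 = G
        else:
            self.state.G0 = sample_g0(stats_, self.priors, self.rng,
                                      self.q_eligible,
                                      self.config.g0_df_uses_total_snps)

    def step_re(self, stats_: SufficientStats | None = None):
        stats_ = stats_ or self.sufficient_stats()
        n = self.data.n
        if self.config.constrain_zero_covariance:
            sub = SufficientStats(Se=np.array([[stats_.Se[0, 0]]]), Sg=None,
                                  m1=0)
            pr = Priors(v_e=self.priors.v_e,
                        S_e=self.priors.e_scale(2)[:1, :1])
            s11 = sample_re_full(sub, pr, n, self.rng)[0, 0]
            if self.binary:
                self.state.Re = np.array([[s11, 0.0], [0.0, 1.0]])
            else:
                sub2 = SufficientStats(Se=np.array([[stats_.Se[1, 1]]]),
                                       Sg=None, m1=0)
                pr2 = Priors(v_e=self.priors.v_e,
                             S_e=self.priors.e_scale(2)[1:, 1:])
                s22 = sample_re_full(sub2, pr2, n, self.rng)[0, 0]
                self.state.Re = np.diag([s11, s22])
        elif self.binary:
            self.state.Re = sample_re_conditional(stats_, n, self.rng,
                                                  self.priors)
        else:
            self.state.Re = sample_re_full(stats_, self.priors, n, self.rng)

    def step_pi(self):
        self.state.pi = sample_pi(int(self.state.delta.sum()),
                                  self.q_eligible, self.rng)

    def step_thresholds(self):
        """Free thresholds exist only for k >= 4 (t1 = 0, t2 = 1 fixed)."""
        k = self.data.k
        if k < 4:
            return
        s = self.state
        l, y2 = s.liability, np.asarray(self.data.y2, dtype=np.int64)
        if self.priors.t_bounds is not None:
            tmin, tmax = self.priors.t_bounds
        else:
            mu, sd = float(np.mean(l)), float(np.std(l))
            tmin, tmax = mu - 10 * sd, mu + 10 * sd
        for j in range(2, k - 1):      # thresholds[j] separates cat j, j+1
            in_j = l[y2 == j]
            in_j1 = l[y2 == j + 1]
            lo = max(in_j.max() if in_j.size else -np.inf,
                     s.thresholds[j - 1], tmin)
            hi = min(in_j1.min() if in_j1.size else np.inf,
                     s.thresholds[j + 1] if j + 1 < k - 1 else np.inf, tmax)
            if not lo < hi:
                raise NumericalError(
                    f"empty admissible interval for threshold {j}")
            s.thresholds[j] = self.rng.uniform(lo, hi)

    def cycle(self):
        self.step_liabilities()
        self.step_fixed_effects()
        self.step_snps()
        stats_ = self.sufficient_stats()
        self.step_g0(stats_)
        self.step_re(stats_)
        self.step_pi()
        self.step_thresholds()

    def resample_data(self, rng=None):
        """Redraw (y1, liability, y2) from the model given the current
        parameters, keeping Z and X fixed.  Used by the joint-distribution
        (successive-conditional) validation of the sampler."""
        rng = rng or self.rng
        d, s = self.data, self.state
        chol = np.linalg.cholesky(s.Re)
        e = rng.standard_normal((d.n, 2)) @ chol.T
        d.y1 = d.X1 @ s.beta1 + d.Z @ s.g1 + e[:, 0]
        s.liability = d.X2 @ s.beta2 + d.Z @ s.g2 + e[:, 1]
        t = np.concatenate(([-np.inf], s.thresholds, [np.inf]))
        d.y2 = (np.searchsorted(t, s.liability, side="left") - 1).astype(int)
        self.e1, self.e2 = self._residuals_from_scratch()

    def run(self) -> PosteriorSummary:
        return _run(self, "lt-bayescpi", bivariate=True)


class SingleTraitChain(_ChainBase):
    """BayesCpi (continuous trait) or BayesTCpi (threshold trait)."""

    def __init__(self, data: TrainingData, priors: Priors | None = None,
                 config: ChainConfig | None = None,
                 state: ModelState | None = None):
        self.data = validate(data)
        self.priors = priors or Priors()
        self.config = config or ChainConfig()
        method = self.config.method
        if method == "lt-bayescpi":
            raise InputError("use BivariateChain for the joint model")
        self.threshold_trait = method == "bayestcpi"
        if self.threshold_trait and data.y2 is None:
            raise InputError("bayestcpi needs the categorical trait y2")
        if not self.threshold_trait and data.y1 is None:
            raise InputError("bayescpi needs the continuous trait y1")
        self.rng = np.random.default_rng(self.config.seed)
        self.state = state if state is not None else initialize_state(
            data, self.priors, self.config.seed, method)
        _kernels.seed_kernel_rng(int(self.rng.integers(2 ** 31)))
        self.zz = np.einsum("ij,ij->j", data.Z, data.Z)
        self.eligible = ~data.monomorphic
        self.q_eligible = int(self.eligible.sum())
        self.binary = self.threshold_trait and data.k == 2
        self.e = self._residuals_from_scratch()[0]
        self.m1 = int(self.state.delta.sum())

    @property
    def _y(self):
        return self.state.liability if self.threshold_trait else self.data.y1

    @property
    def _X(self):
        return self.data.X2 if self.threshold_trait else self.data.X1

    @property
    def _beta(self):
        return self.state.beta2 if self.threshold_trait else self.state.beta1

    @property
    def _g(self):
        return self.state.g2 if self.threshold_trait else self.state.g1

    def _residuals_from_scratch(self):
        return (self._y - self._X @ self._beta - self.data.Z @ self._g,)

    def _residual_views(self):
        return (self.e,)

    def step_liabilities(self):
        if not self.threshold_trait:
            return
        s = self.state
        sd = np.sqrt(s.Re[0, 0])
        lo, hi = category_bounds(self.data.y2, s.thresholds)
        _kernels.sweep_liabilities(s.liability, self.e,
                                   np.zeros_like(self.e), lo, hi, 0.0, sd)

    def step_fixed_effects(self):
        X, beta = self._X, self._beta
        se2 = self.state.Re[0, 0]
        lo, hi = self.priors.beta_bounds
        for j in range(X.shape[1]):
            x = X[:, j]
            c = x @ x
            if c <= 0:
                logger.warning("degenerate fixed-effect column skipped")
                continue
            mean = (x @ self.e + c * beta[j]) / c
            new = _draw_truncnorm(self.rng, mean, np.sqrt(se2 / c), lo, hi)
            self.e -= x * (new - beta[j])
            beta[j] = new

    def step_snps(self):
        s = self.state
        self.m1 = _kernels.sweep_snps_single(
            self.data.Z, self.zz, self.e, self._g, s.delta, self.eligible,
            s.G0[0, 0], s.Re[0, 0], s.pi)

    def sufficient_stats(self) -> SufficientStats:
        inc = self.state.delta == 1
        g = self._g[inc]
        return SufficientStats(Se=np.array([[self.e @ self.e]]),
                               Sg=np.array([[g @ g]]), m1=int(inc.sum()))

    def step_g0(self, stats_=None):
        stats_ = stats_ or self.sufficient_stats()
        self.state.G0 = sample_g0(stats_, self.priors, self.rng,
                                  self.q_eligible,
                                  self.config.g0_df_uses_total_snps)

    def step_re(self, stats_=None):
        if self.binary:
            return   # liability residual variance fixed at 1
        stats_ = stats_ or self.sufficient_stats()
        self.state.Re = sample_re_full(stats_, self.priors, self.data.n,
                                       self.rng)

    def step_pi(self):
        self.state.pi = sample_pi(int(self.state.delta.sum()),
                                  self.q_eligible, self.rng)

    def step_thresholds(self):
        if not self.threshold_trait or self.data.k < 4:
            return
        BivariateChain.step_thresholds(self)   # same logic, shared fields

    def cycle(self):
        self.step_liabilities()
        self.step_fixed_effects()
        self.step_snps()
        stats_ = self.sufficient_stats()
        self.step_g0(stats_)
        self.step_re(stats_)
        self.step_pi()
        self.step_thresholds()

    def run(self) -> PosteriorSummary:
        return _run(self, self.config.method, bivariate=False)


def _run(chain, method: str, bivariate: bool) -> PosteriorSummary:
    cfg = chain.config
    q = chain.data.q
    kept = 0
    g1_sum = np.zeros(q)
    g2_sum = np.zeros(q)
    incl_sum = np.zeros(q)
    pi_sum = 0.0
    dim = 2 if bivariate else 1
    G0_sum = np.zeros((dim, dim))
    Re_sum = np.zeros((dim, dim))
    n_keep = (cfg.n_cycles - cfg.burn_in + cfg.thinning - 1) // cfg.thinning
    tr = {name: np.empty(n_keep) for name in
          ("pi", "m1", "sigma_g1", "sigma_g12", "sigma_g2",
           "sigma_e1", "sigma_e12", "sigma_e2")}
    for cycle in range(cfg.n_cycles):
        try:
            chain.cycle()
        except NumericalError as err:
            raise NumericalError(f"cycle {cycle}: {err}") from err
        if cycle % 1000 == 999:
            chain._nan_guard(cycle)
        if cycle < cfg.burn_in or (cycle - cfg.burn_in) % cfg.thinning:
            continue
        s = chain.state
        if bivariate:
            g1_sum += s.g1
            g2_sum += s.g2
        elif method == "bayescpi":
            g1_sum += chain._g
        else:
            g2_sum += chain._g
        G0, Re = s.G0, s.Re
        incl_sum += s.delta
        pi_sum += s.pi
        G0_sum += G0
        Re_sum += Re
        tr["pi"][kept] = s.pi
        tr["m1"][kept] = s.delta.sum()
        tr["sigma_g1"][kept] = G0[0, 0]
        tr["sigma_g2"][kept] = G0[-1, -1]
        tr["sigma_g12"][kept] = G0[0, -1] if dim == 2 else 0.0
        tr["sigma_e1"][kept] = Re[0, 0]
        tr["sigma_e2"][kept] = Re[-1, -1]
        tr["sigma_e12"][kept] = Re[0, -1] if dim == 2 else 0.0
        kept += 1
    for name in tr:
        tr[name] = tr[name][:kept]
    has1 = method in ("lt-bayescpi", "bayescpi")
    has2 = method in ("lt-bayescpi", "bayestcpi")
    return PosteriorSummary(
        method=method,
        g1_hat=g1_sum / kept if has1 else None,
        g2_hat=g2_sum / kept if has2 else None,
        inclusion_freq=incl_sum / kept,
        pi_hat=pi_sum / kept,
        G0_hat=G0_sum / kept,
        Re_hat=Re_sum / kept,
        traces=tr,
        settings={"n_cycles": cfg.n_cycles, "burn_in": cfg.burn_in,
                  "thinning": cfg.thinning, "seed": cfg.seed,
                  "method": method, "kept": kept,
                  "constrain_zero_covariance": cfg.constrain_zero_covariance,
                  "g0_df_uses_total_snps": cfg.g0_df_uses_total_snps},
        snp_ids=chain.data.snp_ids)


def run_chain(data: TrainingData, priors: Priors | None = None,
              config: ChainConfig | None = None) -> PosteriorSummary:
    """Fit one of the three methods and return the posterior summary."""
    config = config or ChainConfig()
    if config.method == "lt-bayescpi":
        return BivariateChain(data, priors, config).run()
    return SingleTraitChain(data, priors, config).run()
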
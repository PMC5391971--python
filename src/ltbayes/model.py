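"""Data structures for the bivariate linear-threshold spike-and-slab model.

The model couples one continuous trait ``y1`` and one categorical trait
``y2`` (binary in the main use case) through a latent liability ``l``:

    [y1; l] = [X1 0; 0 X2] [beta1; beta2] + [Z 0; 0 Z] [g1; g2] + [e1; e2]

Each SNP either has zero effect on both traits (probability ``pi``) or an
effect pair drawn from a bivariate normal slab N(0, G0).  Residual pairs are
N(0, Re).  For a binary trait identifiability requires fixing the liability
residual variance to 1 and the threshold to 0; for k >= 3 categories the
first two thresholds are fixed at 0 and 1 instead and the liability residual
variance is free.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from ._kernels import rtnorm_std, seed_kernel_rng


class InputError(ValueError):
    """Invalid user-supplied data."""


@dataclass
class TrainingData:
    """Validated training inputs for the Gibbs samplers."""

    y1: np.ndarray | None      # continuous observations, shape (n,)
    y2: np.ndarray | None      # category codes 0..k-1, shape (n,)
    Z: np.ndarray              # dosage matrix (n, q), values in {0,1,2}
    X1: np.ndarray | None = None
    X2: np.ndarray | None = None
    k: int = 2                 # number of categories of y2
    snp_ids: list[str] | None = None

    n: int = field(init=False)
    q: int = field(init=False)
    monomorphic: np.ndarray = field(init=False)

    def __post_init__(self):
        self.Z = np.asfortranarray(np.asarray(self.Z, dtype=np.float64))
        self.n, self.q = self.Z.shape
        if self.y1 is not None:
            self.y1 = np.asarray(self.y1, dtype=np.float64)
        if self.y2 is not None:
            self.y2 = np.asarray(self.y2)
        if self.X1 is None and self.y1 is not None:
            self.X1 = np.ones((self.n, 1))
        if self.X2 is None and self.y2 is not None:
            self.X2 = np.ones((self.n, 1))
        self.monomorphic = np.ptp(self.Z, axis=0) == 0


def validate(data: TrainingData) -> TrainingData:
    """Check shape consistency, dosage domain and category coding.

    Monomorphic SNPs are flagged (``data.monomorphic``) and retained; the
    samplers permanently exclude them from the slab, guaranteeing zero
    estimated effects.
    """
    Z = data.Z
    bad = ~np.isin(Z, (0.0, 1.0, 2.0))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise InputError(
            f"genotype dosage must be 0, 1 or 2; found {Z[i, j]!r} at "
            f"individual {i}, SNP {j}")
    if data.y1 is not None:
        if data.y1.shape[0] != data.n:
            raise InputError(
                f"y1 length {data.y1.shape[0]} != {data.n} genotype rows")
        if not np.isfinite(data.y1).all():
            raise InputError("y1 contains non-finite values")
        if data.X1.shape[0] != data.n:
            raise InputError("X1 row count inconsistent with genotypes")
    if data.y2 is not None:
        if data.y2.shape[0] != data.n:
            raise InputError(
                f"y2 length {data.y2.shape[0]} != {data.n} genotype rows")
        if data.k < 2:
            raise InputError("a categorical trait needs k >= 2 categories")
        codes = np.unique(data.y2)
        if (codes[0] < 0 or codes[-1] >= data.k or not np.array_equal(
                codes, np.arange(codes[0], codes[-1] + 1))):
            raise InputError(
                f"y2 must use contiguous codes within 0..{data.k - 1}; "
                f"found {codes.tolist()}")
        if data.X2.shape[0] != data.n:
            raise InputError("X2 row count inconsistent with genotypes")
    if data.y1 is None and data.y2 is None:
        raise InputError("at least one trait must be observed")
    data.monomorphic = np.ptp(Z, axis=0) == 0
    return data


@dataclass
class Priors:
    """Hyper-parameters of the hierarchical model.

    ``v_g``/``v_e`` are the inverse-Wishart shape hyper-parameters; the
    associated scale matrices (``S_g``, ``S_e``) are ADDED to the effect /
    residual cross-product matrices in the conditional updates, so ``v = -3``
    with a zero scale is the improper flat prior used by default.  ``S_g``
    corresponds to V_g^{-1} in the usual (v, V) hyper-parameterisation.
    """

    v_g: float = -3.0
    S_g: np.ndarray | None = None     # 2x2 (or scalar) scale; None = 0 (flat)
    v_e: float = -3.0
    S_e: np.ndarray | None = None
    beta_bounds: tuple[float, float] = (-np.inf, np.inf)
    t_bounds: tuple[float, float] | None = None   # default mu +/- 10 sigma

    def g_scale(self, dim: int) -> np.ndarray:
        if self.S_g is None:
            return np.zeros((dim, dim))
        return np.atleast_2d(np.asarray(self.S_g, dtype=float))

    def e_scale(self, dim: int) -> np.ndarray:
        if self.S_e is None:
            return np.zeros((dim, dim))
        return np.atleast_2d(np.asarray(self.S_e, dtype=float))


@dataclass
class ModelState:
    """All Gibbs-sampled unknowns at one cycle."""

    beta1: np.ndarray | None
    beta2: np.ndarray | None
    g1: np.ndarray | None          # SNP effects, trait 1
    g2: np.ndarray | None          # SNP effects, trait 2 (liability scale)
    delta: np.ndarray              # shared inclusion indicators, int8
    liability: np.ndarray | None
    G0: np.ndarray                 # effect covariance (2x2 or 1x1)
    Re: np.ndarray                 # residual covariance (2x2 or 1x1)
    pi: float                      # probability of ZERO effect
    thresholds: np.ndarray | None  # length k-1; t[0] = 0 always

    def check(self, binary_trait: bool = True):
        """Assert the structural invariants; used liberally in tests."""
        if self.g1 is not None:
            assert np.all(self.g1[self.delta == 0] == 0.0)
        if self.g2 is not None:
            assert np.all(self.g2[self.delta == 0] == 0.0)
        assert 0.0 <= self.pi <= 1.0
        for M in (self.G0, self.Re):
            M = np.atleast_2d(M)
            assert np.allclose(M, M.T)
            assert np.all(np.linalg.eigvalsh(M) > 0)
        if self.liability is not None and binary_trait:
            Re = np.atleast_2d(self.Re)
            assert Re[-1, -1] == 1.0
            assert self.thresholds[0] == 0.0
        if self.thresholds is not None and len(self.thresholds) > 1:
            assert np.all(np.diff(self.thresholds) >= 0)


@dataclass
class SufficientStats:
    """Cross-products entering the dispersion updates."""

    Se: np.ndarray   # residual cross-products (liability-scale e2)
    Sg: np.ndarray   # cross-products of included SNP-effect pairs
    m1: int          # number of included SNPs


@dataclass
class PosteriorSummary:
    """Posterior means and traces over kept (post-burn-in, thinned) cycles."""

    method: str
    g1_hat: np.ndarray | None
    g2_hat: np.ndarray | None
    inclusion_freq: np.ndarray
    pi_hat: float                   # posterior mean probability of zero
    G0_hat: np.ndarray
    Re_hat: np.ndarray
    traces: dict
    settings: dict
    snp_ids: list[str] | None = None

    @property
    def prop_included(self) -> float:
        """Posterior mean proportion of SNPs with non-zero effect (1 - pi)."""
        return 1.0 - self.pi_hat

    @property
    def genetic_correlation(self) -> float | None:
        G = np.atleast_2d(self.G0_hat)
        if G.shape[0] < 2:
            return None
        return float(G[0, 1] / np.sqrt(G[0, 0] * G[1, 1]))

    @property
    def residual_correlation(self) -> float | None:
        R = np.atleast_2d(self.Re_hat)
        if R.shape[0] < 2:
            return None
        return float(R[0, 1] / np.sqrt(R[0, 0] * R[1, 1]))


def initialize_state(data: TrainingData, priors: Priors, seed: int,
                     method: str = "lt-bayescpi") -> ModelState:
    """Deterministic-given-seed starting values.

    Intercepts start at the trait mean (probit of the observed incidence for
    the liability trait); SNP effects at zero with all indicators off;
    pi = 0.5; G0 small positive diagonal; Re identity with the liability
    residual variance fixed at 1; liabilities drawn from standard normals
    truncated to each individual's category interval.
    """
    rng = np.random.default_rng(seed)
    q = data.q
    has1 = method in ("lt-bayescpi", "bayescpi")
    has2 = method in ("lt-bayescpi", "bayestcpi")
    dim = 2 if (has1 and has2) else 1

    beta1 = beta2 = g1 = g2 = liability = thresholds = None
    if has1:
        beta1 = np.zeros(data.X1.shape[1])
        beta1[0] = data.y1.mean()
        g1 = np.zeros(q)
    if has2:
        k = data.k
        thresholds = np.zeros(k - 1)
        if k >= 3:
            thresholds[1] = 1.0
            for j in range(2, k - 1):
                thresholds[j] = 1.0 + (j - 1)   # ordered start
        beta2 = np.zeros(data.X2.shape[1])
        incidence = float(np.mean(data.y2 > 0))
        incidence = min(max(incidence, 1e-3), 1 - 1e-3)
        beta2[0] = stats.norm.ppf(incidence) if k == 2 else 0.0
        g2 = np.zeros(q)
        seed_kernel_rng(int(rng.integers(2 ** 31)))
        lo, hi = category_bounds(data.y2, thresholds)
        mu0 = beta2[0]
        liability = np.array(
            [mu0 + rtnorm_std(lo[i] - mu0, hi[i] - mu0)
             for i in range(data.n)])

    G0 = np.eye(dim) * 0.01
    Re = np.eye(dim)
    if has1 and not has2:
        Re[0, 0] = max(np.var(data.y1), 1e-8)
    state = ModelState(
        beta1=beta1, beta2=beta2, g1=g1, g2=g2,
        delta=np.zeros(q, dtype=np.int8), liability=liability,
        G0=G0, Re=Re, pi=0.5, thresholds=thresholds)
    return state


def category_bounds(y2: np.ndarray, thresholds: np.ndarray):
    """Per-individual liability truncation interval (lo, hi] from thresholds.

    Category j occupies (t_{j-1}, t_j] with t_0 = -inf and t_k = +inf
    conceptually; with the convention used here category 0 is below t_1 = 0
    and the top category above t_{k-1}.
    """
    t = np.concatenate(([-np.inf], thresholds, [np.inf]))
    y2 = np.asarray(y2, dtype=np.int64)
    return t[y2], t[y2 + 1]


# ---------------------------------------------------------------------------
# pure-python inclusion odds (reference route, mirrored by the kernels)
# ---------------------------------------------------------------------------


def log_inclusion_bf_bivariate(c: float, s1: float, s2: float,
                               G0: np.ndarray, Re: np.ndarray) -> float:
    """Log Bayes factor of slab vs spike for one SNP, effect pair
    integrated out.

    c = z'z; s1, s2 = z'r per trait with the SNP's effect added back.
    BF = |I + c Re^{-1} G0|^{-1/2} exp(b' (c Re^{-1} + G0^{-1})^{-1} b / 2)
    with b = Re^{-1} (s1, s2)'.
    """
    W = np.linalg.inv(Re)
    b = W @ np.array([s1, s2])
    P = c * W + np.linalg.inv(G0)
    quad = b @ np.linalg.solve(P, b)
    _, logdet = np.linalg.slogdet(np.eye(2) + c * W @ G0)
    return -0.5 * logdet + 0.5 * quad


def log_inclusion_bf_single(c: float, s: float, sg2: float,
                            se2: float) -> float:
    """Single-trait analogue of :func:`log_inclusion_bf_bivariate`."""
    b = s / se2
    var_post = 1.0 / (c / se2 + 1.0 / sg2)
    return 0.5 * np.log(var_post / sg2) + 0.5 * b * b * var_post
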
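"""Gibbs engine: conditional distributions, bookkeeping, invariants."""

import numpy as np
import pytest
from scipy import stats

from ltbayes import _kernels
from ltbayes.gibbs import (BivariateChain, ChainConfig, SingleTraitChain,
                           run_chain, sample_g0, sample_location, sample_pi,
                           sample_re_conditional, sample_re_full)
from ltbayes.model import (Priors, SufficientStats, TrainingData,
                           initialize_state)

PHI0 = float(stats.norm.pdf(0) / stats.norm.sf(0))   # 0.7978845608


def _binary_data(n, q, seed=0, p_one=0.5):
    rng = np.random.default_rng(seed)
    return TrainingData(
        y1=rng.normal(size=n), y2=(rng.random(n) < p_one).astype(int),
        Z=rng.integers(0, 3, size=(n, q)).astype(float), k=2)


class TestLiabilities:
    def test_truncated_conditional_moments(self):
        """With Re = [[2,1],[1,1]] the conditional liability variance is
        1 - 1/2 = 0.5; for individuals in category 1 with zero fitted values
        and zero co-trait residual the draws are half-normal above 0 with
        sd sqrt(0.5)."""
        n = 2000
        data = _binary_data(n, 3, seed=1)
        data.y2 = np.ones(n, dtype=int)
        data.y1 = np.zeros(n)
        chain = BivariateChain(data, Priors(),
                               ChainConfig(n_cycles=10, burn_in=0, seed=4))
        s = chain.state
        s.beta1[:] = 0
        s.beta2[:] = 0
        s.g1[:] = 0
        s.g2[:] = 0
        s.delta[:] = 0
        s.Re = np.array([[2.0, 1.0], [1.0, 1.0]])
        chain.e1, chain.e2 = chain._residuals_from_scratch()
        draws = []
        for _ in range(50):
            chain.step_liabilities()
            draws.append(s.liability.copy())
        draws = np.concatenate(draws)
        sd = np.sqrt(0.5)
        assert np.all(draws > 0)
        assert draws.mean() == pytest.approx(sd * PHI0, abs=0.01 * sd)
        assert draws.var() == pytest.approx(0.5 * (1 - PHI0 ** 2),
                                            rel=0.05)


class TestLocation:
    def test_two_coordinate_toy_system(self):
        C = np.array([[2.0, 0.5], [0.5, 1.0]])
        r = np.array([1.0, 0.7])
        theta = np.zeros(2)
        rng = np.random.default_rng(0)
        draws = np.empty((20_000, 2))
        for it in range(20_000):
            sample_location(C, r, theta, 0, rng)
            sample_location(C, r, theta, 1, rng)
            draws[it] = theta
        assert np.allclose(draws[2000:].mean(axis=0), np.linalg.solve(C, r),
                           atol=0.05)

    def test_intercept_conditional_is_sample_mean(self):
        rng = np.random.default_rng(8)
        n = 400
        data = TrainingData(y1=rng.normal(2.0, 1.0, n), y2=None,
                            Z=rng.integers(0, 3, (n, 4)).astype(float))
        chain = SingleTraitChain(
            data, Priors(), ChainConfig(n_cycles=10, burn_in=0, seed=3,
                                        method="bayescpi"))
        chain.state.g1[:] = 0
        chain.state.delta[:] = 0
        chain.state.Re = np.array([[2.0]])
        chain.state.beta1[:] = 0
        chain.e = chain._residuals_from_scratch()[0]
        draws = []
        for _ in range(3000):
            chain.step_fixed_effects()
            draws.append(chain.state.beta1[0])
        draws = np.array(draws)
        assert draws.mean() == pytest.approx(data.y1.mean(), abs=0.005)
        assert draws.std() == pytest.approx(np.sqrt(2.0 / n), rel=0.1)

    def test_residual_bookkeeping_identity(self, tiny_training):
        for method, cls in (("lt-bayescpi", BivariateChain),
                            ("bayescpi", SingleTraitChain),
                            ("bayestcpi", SingleTraitChain)):
            chain = cls(tiny_training, Priors(),
                        ChainConfig(n_cycles=10, burn_in=0, seed=5,
                                    method=method))
            for _ in range(100):
                chain.cycle()
            assert chain.residual_drift() < 1e-8


class TestStateInvariants:
    def test_invariants_hold_every_cycle(self):
        data = _binary_data(60, 15, seed=6, p_one=0.4)
        chain = BivariateChain(data, Priors(),
                               ChainConfig(n_cycles=10, burn_in=0, seed=2))
        for _ in range(60):
            chain.cycle()
            chain.state.check(binary_trait=True)
            off = chain.state.delta == 0
            assert np.all(chain.state.g1[off] == 0)
            assert np.all(chain.state.g2[off] == 0)


class TestDispersion:
    def test_pi_beta_moments(self, rng):
        lo = np.array([sample_pi(0, 10, rng) for _ in range(20_000)])
        hi = np.array([sample_pi(10, 10, rng) for _ in range(20_000)])
        assert lo.mean() == pytest.approx(11 / 12, abs=0.01)
        assert hi.mean() == pytest.approx(1 / 12, abs=0.01)
        assert ((lo > 0) & (lo < 1)).all() and ((hi > 0) & (hi < 1)).all()

    def test_g0_concentrates_at_inverse_wishart_mean(self, rng):
        c, m1 = 5.0, 5000
        st_ = SufficientStats(Se=None, Sg=c * np.eye(2), m1=m1)
        draws = np.stack([sample_g0(st_, Priors(), rng) for _ in range(500)])
        assert np.allclose(draws.mean(axis=0), c / (m1 - 6) * np.eye(2),
                           rtol=0.05, atol=2e-5)

    def test_g0_always_positive_definite(self, rng):
        A = np.array([[0.8, 0.3], [0.3, 0.5]])
        st_ = SufficientStats(Se=None, Sg=A, m1=10)
        for _ in range(10_000):
            G = sample_g0(st_, Priors(), rng)
            assert G[0, 0] > 0 and G[0, 0] * G[1, 1] > G[0, 1] ** 2

    def test_g0_fallback_on_degenerate_count(self, rng):
        st_ = SufficientStats(Se=None, Sg=np.zeros((2, 2)), m1=0)
        G = sample_g0(st_, Priors(), rng)    # must not raise
        assert np.all(np.linalg.eigvalsh(G) > 0)

    def test_re_full_1d_is_scaled_inverse_chisquare(self, rng):
        n, sse = 200, 37.5
        st_ = SufficientStats(Se=np.array([[sse]]), Sg=None, m1=0)
        draws = np.array([sample_re_full(st_, Priors(), n, rng)[0, 0]
                          for _ in range(50_000)])
        assert draws.mean() == pytest.approx(sse / (n - 5), rel=0.02)

    def test_flat_prior_equals_explicit_zero_hyper(self):
        st_ = SufficientStats(Se=np.array([[12.0]]), Sg=None, m1=0)
        a = sample_re_full(st_, Priors(), 50, np.random.default_rng(7))
        b = sample_re_full(st_, Priors(v_e=-3.0, S_e=np.zeros((1, 1))), 50,
                           np.random.default_rng(7))
        assert a[0, 0] == b[0, 0]

    def test_korsgaard_structure(self, rng):
        Se = np.array([[150.0, 40.0], [40.0, 90.0]])
        st_ = SufficientStats(Se=Se, Sg=None, m1=0)
        for _ in range(5000):
            Re = sample_re_conditional(st_, 100, rng)
            assert Re[1, 1] == 1.0
            assert Re[0, 0] > Re[0, 1] ** 2   # PD given T22 = 1


class TestThresholds:
    @staticmethod
    def _ordinal_data(n=400, k=5, seed=3):
        rng = np.random.default_rng(seed)
        liab = rng.normal(1.5, 1.5, n)
        cuts = np.array([0.0, 1.0, 2.0, 3.0])[:k - 1]
        y2 = np.searchsorted(cuts, liab, side="left")
        return TrainingData(y1=rng.normal(size=n), y2=y2,
                            Z=rng.integers(0, 3, (n, 8)).astype(float), k=k)

    def test_binary_and_three_category_are_noop(self):
        for k in (2, 3):
            data = self._ordinal_data(k=k)
            chain = BivariateChain(data, Priors(),
                                   ChainConfig(n_cycles=5, burn_in=0,
                                               seed=1))
            before = chain.state.thresholds.copy()
            chain.step_thresholds()
            assert np.array_equal(chain.state.thresholds, before)

    def test_five_categories_ordered_and_bounded(self):
        data = self._ordinal_data(k=5)
        chain = BivariateChain(data, Priors(),
                               ChainConfig(n_cycles=5, burn_in=0, seed=1))
        for _ in range(40):
            chain.cycle()
            t = chain.state.thresholds
            assert t[0] == 0.0 and t[1] == 1.0
            assert np.all(np.diff(t) >= 0)
            l = chain.state.liability
            mu, sd = l.mean(), l.std()
            assert mu - 10 * sd <= t[2] <= mu + 10 * sd


class TestChain:
    def test_determinism_bit_identical(self, tiny_training):
        cfg = ChainConfig(n_cycles=300, burn_in=100, seed=21,
                          method="lt-bayescpi")
        a = run_chain(tiny_training, Priors(), cfg)
        b = run_chain(tiny_training, Priors(), cfg)
        assert np.array_equal(a.g1_hat, b.g1_hat)
        assert np.array_equal(a.g2_hat, b.g2_hat)
        assert a.pi_hat == b.pi_hat
        assert np.array_equal(a.traces["sigma_e12"], b.traces["sigma_e12"])

    def test_null_signal_shrinks_to_zero(self):
        rng = np.random.default_rng(12)
        n, q = 400, 500
        data = TrainingData(y1=rng.normal(size=n), y2=None,
                            Z=rng.integers(0, 3, (n, q)).astype(float))
        s = run_chain(data, Priors(),
                      ChainConfig(n_cycles=2000, burn_in=1000, seed=3,
                                  method="bayescpi"))
        assert np.mean(np.abs(s.g1_hat)) < 0.02

    def test_strong_signal_is_included(self):
        rng = np.random.default_rng(4)
        n, q = 200, 5
        Z = rng.integers(0, 3, (n, q)).astype(float)
        y = 2.0 * Z[:, 2] + rng.normal(0, 0.5, n)
        data = TrainingData(y1=y, y2=None, Z=Z)
        s = run_chain(data, Priors(),
                      ChainConfig(n_cycles=2000, burn_in=500, seed=9,
                                  method="bayescpi"))
        assert s.inclusion_freq[2] > 0.95

    def test_spike_only_limit(self):
        """As pi -> 1 the prior odds drown a null signal: nothing enters the
        model and the genome stays empty."""
        rng = np.random.default_rng(2)
        n, q = 100, 50
        Z = np.asfortranarray(rng.integers(0, 3, (n, q)).astype(float))
        e = rng.normal(size=n)
        g = np.zeros(q)
        delta = np.zeros(q, dtype=np.int8)
        _kernels.seed_kernel_rng(5)
        m1 = _kernels.sweep_snps_single(
            Z, np.einsum("ij,ij->j", Z, Z), e, g, delta,
            np.ones(q, dtype=bool), 0.1, 1.0, 1.0 - 1e-9)
        assert m1 == 0
        assert np.all(g == 0)
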
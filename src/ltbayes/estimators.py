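"""scikit-learn style estimators wrapping the Gibbs chains.

All three follow the fit/predict contract: ``X`` is the dosage matrix
(individuals x SNPs, values 0/1/2) and ``predict`` returns GEBVs (liability
scale for the threshold trait).  Fitted attributes carry the usual trailing
underscore and the estimators compose with sklearn pipelines and
``clone``/``get_params``.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .gibbs import ChainConfig, run_chain
from .model import InputError, Priors, TrainingData


class _BayesBase(BaseEstimator):
    def __init__(self, n_cycles=50_000, burn_in=30_000, thinning=1,
                 random_state=0, v_g=-3.0, S_g=None, v_e=-3.0, S_e=None,
                 g0_df_uses_total_snps=False):
        self.n_cycles = n_cycles
        self.burn_in = burn_in
        self.thinning = thinning
        self.random_state = random_state
        self.v_g = v_g
        self.S_g = S_g
        self.v_e = v_e
        self.S_e = S_e
        self.g0_df_uses_total_snps = g0_df_uses_total_snps

    def _config(self, method):
        return ChainConfig(
            n_cycles=self.n_cycles, burn_in=self.burn_in,
            thinning=self.thinning, seed=self.random_state, method=method,
            g0_df_uses_total_snps=self.g0_df_uses_total_snps)

    def _priors(self):
        return Priors(v_g=self.v_g, S_g=self.S_g, v_e=self.v_e, S_e=self.S_e)

    def _store(self, summary):
        self.posterior_ = summary
        self.pi_ = summary.pi_hat
        self.prop_included_ = summary.prop_included
        self.inclusion_freq_ = summary.inclusion_freq
        self.G0_ = summary.G0_hat
        self.Re_ = summary.Re_hat
        return self


class BayesCPi(RegressorMixin, _BayesBase):
    """Spike-and-slab whole-genome regression for one continuous trait.

    Each SNP has zero effect with probability pi (estimated) or an effect
    from a shared normal distribution whose variance is estimated.
    ``predict`` returns GEBVs: X @ snp_effects_.
    """

    def fit(self, X, y, covariates=None):
        X = np.asarray(X, dtype=np.float64)
        data = TrainingData(y1=np.asarray(y, dtype=float), y2=None, Z=X,
                            X1=self._design(covariates, X.shape[0]))
        summary = run_chain(data, self._priors(), self._config("bayescpi"))
        self._store(summary)
        self.snp_effects_ = summary.g1_hat
        self.sigma_g2_ = float(summary.G0_hat[0, 0])
        self.sigma_e2_ = float(summary.Re_hat[0, 0])
        self.n_features_in_ = X.shape[1]
        return self

    @staticmethod
    def _design(covariates, n):
        if covariates is None:
            return None
        C = np.atleast_2d(np.asarray(covariates, dtype=float))
        if C.shape[0] != n:
            C = C.T
        return np.column_stack([np.ones(n), C])

    def predict(self, X):
        check_is_fitted(self, "snp_effects_")
        return np.asarray(X, dtype=np.float64) @ self.snp_effects_


class BayesTCPi(_BayesBase):
    """Spike-and-slab regression for a threshold (binary/ordinal) trait.

    ``y`` holds category codes 0..k-1; the model operates on a latent
    liability with residual variance fixed at 1 (binary case) and threshold
    at 0.  ``predict`` returns liability-scale GEBVs; ``predict_proba`` the
    probability of the top category for a binary trait.
    """

    def __init__(self, n_cycles=50_000, burn_in=30_000, thinning=1,
                 random_state=0, v_g=-3.0, S_g=None, v_e=-3.0, S_e=None,
                 g0_df_uses_total_snps=False, k=2):
        super().__init__(n_cycles, burn_in, thinning, random_state, v_g, S_g,
                         v_e, S_e, g0_df_uses_total_snps)
        self.k = k

    def fit(self, X, y, covariates=None):
        X = np.asarray(X, dtype=np.float64)
        data = TrainingData(y1=None, y2=np.asarray(y, dtype=int), Z=X,
                            X2=BayesCPi._design(covariates, X.shape[0]),
                            k=self.k)
        summary = run_chain(data, self._priors(), self._config("bayestcpi"))
        self._store(summary)
        self.snp_effects_ = summary.g2_hat
        self.sigma_g2_ = float(summary.G0_hat[0, 0])
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "snp_effects_")
        return np.asarray(X, dtype=np.float64) @ self.snp_effects_


class LTBayesCPi(_BayesBase):
    """Joint linear-threshold model for one continuous and one binary trait.

    ``y`` is (n, 2): column 0 the continuous observations, column 1 the
    binary (or ordinal) codes.  A single inclusion indicator per SNP is
    shared by both traits with a bivariate-normal slab, so the binary trait
    borrows information from the correlated continuous one.  ``predict``
    returns an (n, 2) array of GEBVs.

    Fitted attributes include the posterior-mean genetic and residual
    correlations (``genetic_correlation_``, ``residual_correlation_``).
    """

    def __init__(self, n_cycles=50_000, burn_in=30_000, thinning=1,
                 random_state=0, v_g=-3.0, S_g=None, v_e=-3.0, S_e=None,
                 g0_df_uses_total_snps=False, k=2):
        super().__init__(n_cycles, burn_in, thinning, random_state, v_g, S_g,
                         v_e, S_e, g0_df_uses_total_snps)
        self.k = k

    def fit(self, X, y, covariates=None):
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y)
        if y.ndim != 2 or y.shape[1] != 2:
            raise InputError("y must be (n, 2): continuous, categorical")
        design = BayesCPi._design(covariates, X.shape[0])
        data = TrainingData(y1=y[:, 0].astype(float),
                            y2=y[:, 1].astype(int), Z=X,
                            X1=design, X2=None if design is None
                            else design.copy(), k=self.k)
        summary = run_chain(data, self._priors(),
                            self._config("lt-bayescpi"))
        self._store(summary)
        self.snp_effects_ = np.column_stack([summary.g1_hat, summary.g2_hat])
        self.genetic_correlation_ = summary.genetic_correlation
        self.residual_correlation_ = summary.residual_correlation
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "snp_effects_")
        return np.asarray(X, dtype=np.float64) @ self.snp_effects_
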
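"""Simulator: map function, demography, architecture, phenotyping."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ltbayes import _kernels
from ltbayes.sim import (ArchitectureConfig, ConfigurationError,
                         DemographyConfig, GenomeConfig, SimulationError,
                         empirical_threshold, expand_and_breed, group_sizes,
                         haldane, pleiotropic_correlation, run_historical,
                         sample_qtl, simulate_dataset)


class TestHaldane:
    def test_adjacent_marker_distance(self):
        # 1 Morgan / 2000 markers -> d = 0.0005
        assert haldane(0.0005) == pytest.approx(0.00049975, abs=1e-8)

    @given(st.floats(min_value=0.0, max_value=5.0))
    @settings(max_examples=50, deadline=None)
    def test_bounds_and_monotonicity(self, d):
        r = haldane(d)
        assert 0.0 <= r < 0.5
        assert haldane(d + 0.1) > r


class TestHistory:
    def test_no_mutation_stays_monomorphic(self):
        g = GenomeConfig(n_chromosomes=1, n_markers_per_chrom=50,
                         mutation_rate=0.0)
        d = DemographyConfig(base_size=20, n_historical_generations=50,
                             expansion_size=100, sires_per_generation=5,
                             dams_per_generation=50, offspring_per_dam=2)
        founders = run_historical(g, d, seed=0)
        assert founders.sum() == 0

    def test_mutation_builds_polymorphism_regression(self):
        # frozen summary of one fixed-seed history at mutation-drift
        # equilibrium scale: most loci segregate at intermediate frequency
        g = GenomeConfig(n_chromosomes=2, n_markers_per_chrom=500)
        d = DemographyConfig(n_historical_generations=400)
        h = run_historical(g, d, seed=123)
        freq = h.mean(axis=0)
        maf = np.minimum(freq, 1 - freq)
        seg = maf > 0
        assert h.shape == (200, 1998)
        assert int(seg.sum()) == 1972
        assert float(maf[seg].mean()) == pytest.approx(0.243524, abs=1e-6)

    def test_bad_config_rejected(self):
        with pytest.raises(ConfigurationError):
            DemographyConfig(base_size=0)
        with pytest.raises(ConfigurationError):
            DemographyConfig(n_historical_generations=-1)
        with pytest.raises(ConfigurationError):
            GenomeConfig(mutation_rate=-1e-3)


class TestBreeding:
    def test_generation_sizes(self, tiny_dataset):
        gens, counts = np.unique(tiny_dataset.generation,
                                 return_counts=True)
        assert gens.tolist() == [1, 2, 3, 4, 5, 6]
        assert counts.tolist() == [1000] * 6

    def test_mendelian_transmission(self):
        # without mutation every offspring allele must exist in the parent
        # it came from; gametes are built per parent so checking against the
        # union of the two parental alleles at each locus is exact
        g = GenomeConfig(n_chromosomes=2, n_markers_per_chrom=30,
                         mutation_rate=0.0)
        pos, cs, cl, _ = g.locus_layout()
        rng = np.random.default_rng(5)
        _kernels.seed_kernel_rng(7)
        par = rng.integers(0, 2, size=(4, pos.size)).astype(np.uint8)
        sire_idx = np.zeros(50, dtype=np.int64)
        dam_idx = np.ones(50, dtype=np.int64)
        off = _kernels.breed_offspring(par, sire_idx, dam_idx, pos, cs, cl,
                                       0.0)
        pat = off[0::2]   # gametes from individual 0 (rows 0, 1 of par)
        mat = off[1::2]   # gametes from individual 1 (rows 2, 3 of par)
        assert np.all((pat == par[0]) | (pat == par[1]))
        assert np.all((mat == par[2]) | (mat == par[3]))

    def test_zero_map_length_means_cosegregation(self):
        g = GenomeConfig(n_chromosomes=1, n_markers_per_chrom=40,
                         chrom_length_morgan=0.0, mutation_rate=0.0)
        pos, cs, cl, _ = g.locus_layout()
        rng = np.random.default_rng(2)
        _kernels.seed_kernel_rng(3)
        par = np.vstack([np.zeros(pos.size), np.ones(pos.size),
                         np.zeros(pos.size), np.ones(pos.size)]).astype(
            np.uint8)
        off = _kernels.breed_offspring(
            par, np.zeros(100, dtype=np.int64), np.ones(100, dtype=np.int64),
            pos, cs, cl, 0.0)
        # every gamete is entirely one parental haplotype: all 0s or all 1s
        sums = off.sum(axis=1)
        assert set(sums.tolist()) <= {0, pos.size}


class TestArchitecture:
    def test_group_sizes_zero_correlation(self):
        arch = ArchitectureConfig(n_qtl=60, r_AB=0.0)
        assert group_sizes(60, arch.resolved_group_ratio).tolist() == \
            [0, 30, 30]

    def test_group_sizes_standard(self):
        arch = ArchitectureConfig(n_qtl=60, r_AB=0.5)
        assert group_sizes(60, arch.resolved_group_ratio).tolist() == \
            [48, 6, 6]

    @given(st.integers(min_value=1, max_value=500),
           st.tuples(st.floats(0.01, 1), st.floats(0.01, 1),
                     st.floats(0.01, 1)))
    @settings(max_examples=100, deadline=None)
    def test_group_sizes_sum(self, n, raw):
        ratio = np.array(raw) / sum(raw)
        sizes = group_sizes(n, ratio)
        assert sizes.sum() == n
        assert (sizes >= 0).all()

    def test_pleiotropic_pair_correlation(self, rng):
        # with a pure-pleiotropic ratio the generating pair correlation IS
        # the target genetic correlation; check it by Monte Carlo
        arch = ArchitectureConfig(n_qtl=1000, r_AB=0.8,
                                  group_ratio=(1.0, 0.0, 0.0))
        qtl = sample_qtl(GenomeConfig(), arch, np.arange(5000), rng)
        r = np.corrcoef(qtl.effects[:, 0], qtl.effects[:, 1])[0, 1]
        assert r == pytest.approx(0.8, abs=0.04)

    def test_single_trait_groups_have_zero_cross_effects(self, rng):
        arch = ArchitectureConfig(n_qtl=60, r_AB=0.5)
        qtl = sample_qtl(GenomeConfig(), arch, np.arange(2000), rng)
        assert np.all(qtl.effects[qtl.group == 1, 1] == 0)   # A-only
        assert np.all(qtl.effects[qtl.group == 2, 0] == 0)   # B-only

    def test_dilution_compensation_feasibility(self):
        sizes = np.array([48, 6, 6])
        rho = pleiotropic_correlation(0.5, sizes)
        assert rho == pytest.approx(0.5 * 54 / 48)
        with pytest.raises(SimulationError):
            pleiotropic_correlation(0.95, sizes)

    def test_too_few_segregating_candidates(self, rng):
        with pytest.raises(SimulationError):
            sample_qtl(GenomeConfig(), ArchitectureConfig(n_qtl=60),
                       np.arange(10), rng)


class TestPhenotyping:
    def test_tbv_variance_rescaled_exactly(self, tiny_dataset):
        tr = tiny_dataset.training
        assert tiny_dataset.tbv_A[tr].var() == pytest.approx(2.0, abs=1e-9)
        assert tiny_dataset.tbv_B[tr].var() == pytest.approx(1.0, abs=1e-9)

    def test_incidence_pinned_by_quantile(self, tiny_dataset):
        tr = tiny_dataset.training
        n1 = int((tiny_dataset.pheno_B[tr] == 1).sum())
        assert abs(n1 - round(0.30 * tr.sum())) <= 1

    def test_residual_liability_variance(self):
        arch = ArchitectureConfig(h2_B=0.1, var_B=1.0)
        assert arch.residual_var_B == pytest.approx(9.0)

    def test_phenotypes_only_for_training(self, tiny_dataset):
        cand = tiny_dataset.candidates
        assert np.isnan(tiny_dataset.pheno_A[cand]).all()
        assert (tiny_dataset.pheno_B[cand] == -1).all()
        assert np.isfinite(tiny_dataset.tbv_A).all()

    def test_thresholding_conserves_ranks(self, tiny_dataset):
        tr = tiny_dataset.training
        liab = tiny_dataset.liability_B[tr]
        pb = tiny_dataset.pheno_B[tr]
        order_liab = np.argsort(liab, kind="stable")
        order_pair = np.lexsort((liab, pb))
        assert np.array_equal(order_liab, order_pair)

    def test_threshold_order_statistic(self):
        liab = np.arange(10, dtype=float)
        thr = empirical_threshold(liab, incidence=0.3)
        assert (liab > thr).sum() == 3


class TestDeterminism:
    def test_identical_seed_identical_dataset(self):
        g = GenomeConfig(n_chromosomes=1, n_markers_per_chrom=60)
        d = DemographyConfig(n_historical_generations=60)
        a = simulate_dataset(g, d, ArchitectureConfig(n_qtl=10), seed=9)
        b = simulate_dataset(g, d, ArchitectureConfig(n_qtl=10), seed=9)
        assert np.array_equal(a.genotypes, b.genotypes)
        assert np.array_equal(a.tbv_A, b.tbv_A)
        assert np.array_equal(a.pheno_B, b.pheno_B)
        assert a.threshold == b.threshold
        assert np.array_equal(a.qtl.positions, b.qtl.positions)
        assert np.array_equal(a.qtl.effects, b.qtl.effects)


def test_realized_genetic_correlation_targets_r_ab():
    """Across replicates the realized TBV correlation in the training
    generations averages close to the configured genetic correlation."""
    g = GenomeConfig(n_chromosomes=5, n_markers_per_chrom=100)
    d = DemographyConfig(n_historical_generations=1000)
    vals = [
        np.corrcoef(ds.tbv_A[ds.training], ds.tbv_B[ds.training])[0, 1]
        for ds in (simulate_dataset(g, d, ArchitectureConfig(), seed=1000 + r)
                   for r in range(20))]
    assert np.mean(vals) == pytest.approx(0.5, abs=0.06)
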
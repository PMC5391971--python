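"""Forward-in-time simulation of a two-trait (continuous + binary) population.

The design mirrors a classical livestock genomic-selection validation study:

* a base population of 100 (50 males, 50 females), all loci monomorphic;
* 1,000 non-overlapping historical generations of random monogamous mating
  at constant size, polymorphism arising by per-locus mutation (rate
  1.25e-3 per gamete) until mutation-drift equilibrium;
* generation 1 expands to 1,000 (20 offspring per generation-0 female);
* generations 2-6 each produced by 50 random sires x 10 dams x 2 offspring;
* 5 chromosomes of 1 Morgan carrying 2,000 evenly spaced markers each, with
  a candidate QTL locus midway between every pair of adjacent markers;
  recombination follows Haldane's model (Poisson crossovers, no
  interference);
* the true QTL are drawn from the segregating candidate loci and split into
  a pleiotropic group and two single-trait groups (ratio 0.8:0.1:0.1, or
  0:0.5:0.5 when the genetic correlation is zero); effects are rescaled so
  the additive-genetic variances in the training generations (1-2) hit
  their targets exactly (2.0 and 1.0 by default);
* trait A is observed directly; trait B is binary, thresholded on its
  liability at the empirical (1 - incidence) quantile of the training
  liabilities.  Phenotypes exist only for the training generations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels

GROUP_PLEIOTROPIC, GROUP_A_ONLY, GROUP_B_ONLY = 0, 1, 2
GROUP_NAMES = ("pleiotropic", "A_only", "B_only")


class ConfigurationError(ValueError):
    """Invalid simulation configuration."""


class SimulationError(RuntimeError):
    """The simulated population cannot support the requested architecture."""


def haldane(d):
    """Recombination fraction from map distance d (Morgan):
    r = (1 - exp(-2d)) / 2, so 0 <= r < 0.5."""
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d, dtype=float)))


@dataclass
class GenomeConfig:
    n_chromosomes: int = 5
    chrom_length_morgan: float = 1.0
    n_markers_per_chrom: int = 2000
    mutation_rate: float = 1.25e-3
    qtl_on_marker_loci: bool = False   # candidate QTL at marker positions
                                       # instead of interstitial midpoints

    def __post_init__(self):
        if self.n_chromosomes < 1 or self.n_markers_per_chrom < 2:
            raise ConfigurationError("need >= 1 chromosome with >= 2 markers")
        if self.mutation_rate < 0:
            raise ConfigurationError("mutation_rate must be >= 0")
        if self.chrom_length_morgan < 0:
            raise ConfigurationError("chromosome length must be >= 0")

    def locus_layout(self):
        """Positions (Morgan, within chromosome), chromosome start indices,
        chromosome lengths and a marker mask, markers and candidate QTL
        interleaved.  Markers sit at (i + 0.5) * L / m (spacing L / m); each
        candidate QTL sits at the midpoint of an adjacent-marker interval."""
        m = self.n_markers_per_chrom
        L = self.chrom_length_morgan
        marker_pos = (np.arange(m) + 0.5) * (L / m)
        if self.qtl_on_marker_loci:
            pos_c = marker_pos
            is_marker_c = np.ones(m, dtype=bool)
        else:
            qtl_pos = 0.5 * (marker_pos[:-1] + marker_pos[1:])
            pos_c = np.sort(np.concatenate([marker_pos, qtl_pos]))
            is_marker_c = np.zeros(pos_c.size, dtype=bool)
            is_marker_c[::2] = True    # markers and midpoints alternate
        nc = self.n_chromosomes
        pos = np.tile(pos_c, nc)
        is_marker = np.tile(is_marker_c, nc)
        chrom_start = np.arange(nc + 1) * pos_c.size
        chrom_len = np.full(nc, L)
        return (pos.astype(np.float64), chrom_start.astype(np.int64),
                chrom_len.astype(np.float64), is_marker)


@dataclass
class DemographyConfig:
    base_size: int = 100
    n_historical_generations: int = 1000
    expansion_size: int = 1000
    n_recent_generations: int = 6
    sires_per_generation: int = 50
    dams_per_generation: int = 500
    offspring_per_dam: int = 2
    recent_mutation: bool = False   # mutation only drives the historical
                                    # approach to drift equilibrium

    def __post_init__(self):
        if self.base_size < 2 or self.base_size % 2:
            raise ConfigurationError("base_size must be even and >= 2")
        if self.n_historical_generations < 0:
            raise ConfigurationError("generation counts must be >= 0")
        if self.n_recent_generations < 1:
            raise ConfigurationError("need at least one recent generation")
        if self.expansion_size % self.base_size:
            raise ConfigurationError(
                "expansion_size must be a multiple of base_size pairs x 2")
        if (self.sires_per_generation <= 0 or self.dams_per_generation <= 0
                or self.offspring_per_dam <= 0):
            raise ConfigurationError("breeding counts must be positive")
        if (self.dams_per_generation * self.offspring_per_dam
                != self.expansion_size):
            raise ConfigurationError(
                "dams x offspring_per_dam must equal the generation size")


@dataclass
class ArchitectureConfig:
    n_qtl: int = 60
    r_AB: float = 0.5
    group_ratio: tuple[float, float, float] | None = None
    var_A: float = 2.0
    var_B: float = 1.0
    h2_A: float = 0.3
    h2_B: float = 0.1
    incidence: float = 0.30
    env_corr: float = 0.0

    def __post_init__(self):
        if not -1.0 <= self.r_AB <= 1.0:
            raise ConfigurationError("r_AB must be in [-1, 1]")
        for h in (self.h2_A, self.h2_B):
            if not 0.0 < h <= 1.0:
                raise ConfigurationError("heritabilities must be in (0, 1]")
        if not 0.0 < self.incidence < 1.0:
            raise ConfigurationError("incidence must be in (0, 1)")
        if self.n_qtl < 1:
            raise ConfigurationError("n_qtl must be >= 1")
        if self.group_ratio is not None:
            if abs(sum(self.group_ratio) - 1.0) > 1e-9:
                raise ConfigurationError("group_ratio must sum to 1")

    @property
    def resolved_group_ratio(self) -> tuple[float, float, float]:
        if self.group_ratio is not None:
            return self.group_ratio
        if self.r_AB == 0.0:
            return (0.0, 0.5, 0.5)
        return (0.8, 0.1, 0.1)

    @property
    def residual_var_A(self) -> float:
        return self.var_A * (1.0 - self.h2_A) / self.h2_A

    @property
    def residual_var_B(self) -> float:
        """True residual variance of the liabilities (v_e2)."""
        return self.var_B * (1.0 - self.h2_B) / self.h2_B


@dataclass
class QTLModel:
    positions: np.ndarray          # locus indices into the genome layout
    group: np.ndarray              # 0 pleiotropic, 1 A-only, 2 B-only
    effects: np.ndarray            # (n_qtl, 2) allele-substitution effects


@dataclass
class SimulatedDataset:
    genotypes: np.ndarray          # (n_ind, n_panel) dosages 0/1/2, int8
    marker_ids: list[str]
    marker_loci: np.ndarray        # locus indices of the panel markers
    generation: np.ndarray         # 1..n_recent_generations per individual
    role: np.ndarray               # "training" / "candidate"
    tbv_A: np.ndarray
    tbv_B: np.ndarray
    liability_B: np.ndarray        # NaN for candidates (no phenotypes)
    pheno_A: np.ndarray            # NaN for candidates
    pheno_B: np.ndarray            # -1 for candidates
    threshold: float
    v_e2: float                    # true residual liability variance
    qtl: QTLModel
    genome: GenomeConfig
    demography: DemographyConfig
    architecture: ArchitectureConfig
    seed: int

    @property
    def training(self) -> np.ndarray:
        return self.role == "training"

    @property
    def candidates(self) -> np.ndarray:
        return self.role == "candidate"

    def to_training_data(self):
        from .model import TrainingData
        tr = self.training
        return TrainingData(
            y1=self.pheno_A[tr], y2=self.pheno_B[tr].astype(int),
            Z=self.genotypes[tr].astype(np.float64), k=2,
            snp_ids=self.marker_ids)


# ---------------------------------------------------------------------------
# population machinery
# ---------------------------------------------------------------------------


def run_historical(genome: GenomeConfig, demo: DemographyConfig,
                   seed: int) -> np.ndarray:
    """Simulate the mutation-drift history; returns generation-0 haplotypes
    (2 * base_size, n_loci) with the first half of individuals male."""
    pos, chrom_start, chrom_len, _ = genome.locus_layout()
    rng = np.random.default_rng(seed)
    _kernels.seed_kernel_rng(int(rng.integers(2 ** 31)))
    haps = np.zeros((2 * demo.base_size, pos.size), dtype=np.uint8)
    if demo.n_historical_generations == 0:
        return haps
    return _kernels.run_history(haps, demo.n_historical_generations, pos,
                                chrom_start, chrom_len, genome.mutation_rate)


def expand_and_breed(founders: np.ndarray, genome: GenomeConfig,
                     demo: DemographyConfig, seed: int):
    """Breed the recent generations 1..n from the founders.

    Returns (haplotypes, generation labels); haplotype rows 2i, 2i+1 belong
    to individual i; within each generation the first half are males.
    """
    pos, chrom_start, chrom_len, _ = genome.locus_layout()
    rng = np.random.default_rng(seed)
    _kernels.seed_kernel_rng(int(rng.integers(2 ** 31)))
    mu = genome.mutation_rate if demo.recent_mutation else 0.0
    n_base_pairs = demo.base_size // 2
    per_pair = demo.expansion_size // n_base_pairs
    if per_pair % 2:
        raise ConfigurationError("expansion must give equal sexes per pair")
    half = demo.expansion_size // 2

    # generation 1: random monogamous pairing of the founders, per_pair
    # offspring each (half male, half female)
    pm = rng.permutation(n_base_pairs)
    pf = rng.permutation(n_base_pairs) + n_base_pairs
    sire_idx = np.empty(demo.expansion_size, dtype=np.int64)
    dam_idx = np.empty(demo.expansion_size, dtype=np.int64)
    hp = per_pair // 2
    for p in range(n_base_pairs):
        sire_idx[p * hp:(p + 1) * hp] = pm[p]
        dam_idx[p * hp:(p + 1) * hp] = pf[p]
        sire_idx[half + p * hp:half + (p + 1) * hp] = pm[p]
        dam_idx[half + p * hp:half + (p + 1) * hp] = pf[p]
    gen_haps = [_kernels.breed_offspring(founders, sire_idx, dam_idx, pos,
                                         chrom_start, chrom_len, mu)]

    # generations 2..n: random sires from the males, all females as dams
    n_dams = demo.dams_per_generation
    for _ in range(1, demo.n_recent_generations):
        sires = rng.choice(half, size=demo.sires_per_generation,
                           replace=False)
        dams = rng.permutation(n_dams) + half
        dams_per_sire = n_dams // demo.sires_per_generation
        sire_of_dam = np.repeat(sires, dams_per_sire)
        # offspring_per_dam offspring per dam, alternating sex blocks
        sire_idx = np.tile(sire_of_dam, demo.offspring_per_dam)
        dam_idx = np.tile(dams, demo.offspring_per_dam)
        gen_haps.append(_kernels.breed_offspring(
            gen_haps[-1], sire_idx, dam_idx, pos, chrom_start, chrom_len,
            mu))
    haps = np.concatenate(gen_haps, axis=0)
    generation = np.repeat(np.arange(1, demo.n_recent_generations + 1),
                           demo.expansion_size)
    return haps, generation


def _largest_remainder(n: int, ratio) -> np.ndarray:
    raw = np.asarray(ratio, dtype=float) * n
    sizes = np.floor(raw).astype(int)
    rem = n - sizes.sum()
    order = np.argsort(-(raw - sizes))
    sizes[order[:rem]] += 1
    return sizes


def group_sizes(n_qtl: int, ratio) -> np.ndarray:
    """QTL counts per group: largest-remainder rounding, summing to n_qtl."""
    return _largest_remainder(n_qtl, ratio)


def pleiotropic_correlation(r_AB: float, sizes) -> float:
    """Within-pleiotropic-group effect correlation that makes the EXPECTED
    overall genetic correlation equal r_AB despite the dilution from the
    single-trait groups: rho = r_AB * sqrt((n1+n2)(n1+n3)) / n1."""
    n1, n2, n3 = int(sizes[0]), int(sizes[1]), int(sizes[2])
    if n1 == 0:
        if r_AB != 0.0:
            raise SimulationError(
                "non-zero genetic correlation needs pleiotropic QTL")
        return 0.0
    rho = r_AB * np.sqrt((n1 + n2) * (n1 + n3)) / n1
    if abs(rho) > 1.0:
        raise SimulationError(
            f"target genetic correlation {r_AB} infeasible with group sizes "
            f"{(n1, n2, n3)} (needed within-group correlation {rho:.3f})")
    return float(rho)


def sample_qtl(genome: GenomeConfig, arch: ArchitectureConfig,
               segregating_loci: np.ndarray, rng) -> QTLModel:
    """Place the true QTL on segregating candidate loci and draw effects."""
    segregating_loci = np.asarray(segregating_loci)
    if segregating_loci.size < arch.n_qtl:
        raise SimulationError(
            f"only {segregating_loci.size} segregating candidate loci for "
            f"{arch.n_qtl} QTL; rerun with another seed or a larger genome")
    positions = rng.choice(segregating_loci, size=arch.n_qtl, replace=False)
    sizes = group_sizes(arch.n_qtl, arch.resolved_group_ratio)
    group = np.repeat([GROUP_PLEIOTROPIC, GROUP_A_ONLY, GROUP_B_ONLY], sizes)
    effects = np.zeros((arch.n_qtl, 2))
    n1 = sizes[0]
    if n1:
        rho = pleiotropic_correlation(arch.r_AB, sizes)
        cov = np.array([[1.0, rho], [rho, 1.0]])
        effects[:n1] = rng.multivariate_normal([0.0, 0.0], cov, size=n1)
    effects[n1:n1 + sizes[1], 0] = rng.standard_normal(sizes[1])
    effects[n1 + sizes[1]:, 1] = rng.standard_normal(sizes[2])
    return QTLModel(positions=positions, group=group, effects=effects)


def rescale_effects(qtl_dosages_train: np.ndarray, qtl: QTLModel,
                    arch: ArchitectureConfig) -> QTLModel:
    """Scale each trait's effects so the realized TBV variance in the
    training generations equals the target exactly."""
    for t, target in enumerate((arch.var_A, arch.var_B)):
        tbv = qtl_dosages_train @ qtl.effects[:, t]
        v = tbv.var()
        if v <= 0:
            raise SimulationError(
                f"zero realized genetic variance for trait {'AB'[t]}")
        qtl.effects[:, t] *= np.sqrt(target / v)
    return qtl


def empirical_threshold(liabilities: np.ndarray, incidence: float) -> float:
    """(1 - incidence) empirical quantile as an order statistic, so that
    exactly round(n * incidence) observations lie above it."""
    n = liabilities.size
    k = int(round(n * (1.0 - incidence)))
    k = min(max(k, 1), n)
    return float(np.sort(liabilities)[k - 1])


def simulate_dataset(genome: GenomeConfig | None = None,
                     demo: DemographyConfig | None = None,
                     arch: ArchitectureConfig | None = None,
                     seed: int = 0) -> SimulatedDataset:
    """End-to-end replicate: history, expansion, architecture, phenotypes."""
    genome = genome or GenomeConfig()
    demo = demo or DemographyConfig()
    arch = arch or ArchitectureConfig()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xB10]))

    founders = run_historical(genome, demo, seed)
    haps, generation = expand_and_breed(founders, genome, demo,
                                        seed + 1_000_003)
    n_ind = generation.size
    role = np.where(generation <= 2, "training", "candidate")
    training = role == "training"

    _, _, _, is_marker = genome.locus_layout()
    # marker panel: marker loci polymorphic at the end of the history
    founder_poly = founders.min(axis=0) != founders.max(axis=0)
    panel = np.flatnonzero(is_marker & founder_poly)
    if panel.size == 0:
        raise SimulationError("no segregating markers; increase history "
                              "length or mutation rate")
    dosages_panel = (haps[0::2][:, panel] + haps[1::2][:, panel]).astype(
        np.int8)

    # QTL on candidate loci segregating in the training generations
    train_rows = np.flatnonzero(training)
    cand_loci = np.flatnonzero(~is_marker) if not genome.qtl_on_marker_loci \
        else np.flatnonzero(is_marker)
    d_tr = (haps[0::2][train_rows][:, cand_loci]
            + haps[1::2][train_rows][:, cand_loci])
    seg = np.flatnonzero(np.ptp(d_tr, axis=0) > 0)
    qtl = sample_qtl(genome, arch, cand_loci[seg], rng)

    qtl_dos = (haps[0::2][:, qtl.positions]
               + haps[1::2][:, qtl.positions]).astype(np.float64)
    qtl = rescale_effects(qtl_dos[training], qtl, arch)
    tbv = qtl_dos @ qtl.effects
    tbv_A, tbv_B = tbv[:, 0], tbv[:, 1]

    # environmental effects and phenotypes for the training individuals only
    ve1, ve2 = arch.residual_var_A, arch.residual_var_B
    cov_e = arch.env_corr * np.sqrt(ve1 * ve2)
    env = rng.multivariate_normal(
        [0.0, 0.0], [[ve1, cov_e], [cov_e, ve2]], size=train_rows.size)
    pheno_A = np.full(n_ind, np.nan)
    liability = np.full(n_ind, np.nan)
    pheno_B = np.full(n_ind, -1, dtype=np.int64)
    pheno_A[training] = tbv_A[training] + env[:, 0]
    liability[training] = tbv_B[training] + env[:, 1]
    thr = empirical_threshold(liability[training], arch.incidence)
    pheno_B[training] = (liability[training] > thr).astype(np.int64)

    ids = [f"SNP{j:06d}" for j in panel]
    return SimulatedDataset(
        genotypes=dosages_panel, marker_ids=ids, marker_loci=panel,
        generation=generation, role=role, tbv_A=tbv_A, tbv_B=tbv_B,
        liability_B=liability, pheno_A=pheno_A, pheno_B=pheno_B,
        threshold=thr, v_e2=ve2, qtl=qtl, genome=genome, demography=demo,
        architecture=arch, seed=seed)
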
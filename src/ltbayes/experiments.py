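"""Scenario grid runner: standard scenario plus one-factor-at-a-time
variations, replicated simulation -> three fitted methods -> per-generation
accuracy/bias, aggregated as mean +/- s.e. across replicates.

A ``scale_factor`` in (0, 1] shrinks markers, training individuals and chain
length proportionally (chain length floored at 3,000 cycles / 1,500 burn-in)
for desk-scale runs; 1.0 reproduces the full study design.  Scaling is an
approximation knob and is recorded in every output row.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .evaluation import evaluate_candidates
from .gibbs import ChainConfig, run_chain
from .model import Priors
from .sim import (ArchitectureConfig, DemographyConfig, GenomeConfig,
                  simulate_dataset)

logger = logging.getLogger(__name__)

STANDARD = ArchitectureConfig(h2_A=0.3, h2_B=0.1, n_qtl=60, r_AB=0.5,
                              incidence=0.30)


def default_variations() -> dict[str, ArchitectureConfig]:
    """One-factor-at-a-time variations around the standard scenario."""
    out = {"standard": STANDARD}
    for r in (0.0, 0.2, 0.8):
        out[f"rAB_{r:g}"] = replace(STANDARD, r_AB=r)
    for nq in (20, 200, 500):
        out[f"nqtl_{nq}"] = replace(STANDARD, n_qtl=nq)
    for h in (0.5, 0.8):
        out[f"h2A_{h:g}"] = replace(STANDARD, h2_A=h)
    for h in (0.3, 0.5):
        out[f"h2B_{h:g}"] = replace(STANDARD, h2_B=h)
    for inc in (0.05, 0.1, 0.5):
        out[f"incidence_{inc:g}"] = replace(STANDARD, incidence=inc)
    return out


@dataclass
class ScenarioGrid:
    scenarios: dict[str, ArchitectureConfig] = field(
        default_factory=default_variations)
    n_replicates: int = 20
    genome: GenomeConfig = field(default_factory=GenomeConfig)
    demography: DemographyConfig = field(default_factory=DemographyConfig)


def replicate_seed(base_seed: int, scenario: str, replicate: int) -> int:
    """Deterministic, collision-resistant seed below 2**31."""
    h = np.random.SeedSequence(
        [base_seed, replicate,
         int.from_bytes(scenario.encode()[:8].ljust(8, b"\0"), "little")
         % (2 ** 31)])
    return int(h.generate_state(1)[0] % (2 ** 31))


def scaled_configs(genome: GenomeConfig, chain: ChainConfig,
                   scale_factor: float):
    if not 0 < scale_factor <= 1:
        raise ValueError("scale_factor must be in (0, 1]")
    g = replace(genome, n_markers_per_chrom=max(
        2, round(genome.n_markers_per_chrom * scale_factor)))
    c = dataclasses.replace(
        chain,
        n_cycles=max(3000, round(chain.n_cycles * scale_factor)),
        burn_in=max(1500, round(chain.burn_in * scale_factor)))
    return g, c


def run_replicate(arch: ArchitectureConfig, genome: GenomeConfig,
                  demo: DemographyConfig, chain_cfg: ChainConfig,
                  seed: int, scale_factor: float = 1.0,
                  scenario: str = "standard", replicate: int = 0,
                  methods=("bayescpi", "bayestcpi", "lt-bayescpi"),
                  generations=None) -> pd.DataFrame:
    """Simulate one replicate, fit the requested methods, evaluate the
    candidate generations; returns a long-format results frame including
    variance-component rows for the joint model."""
    genome_s, chain_s = scaled_configs(genome, chain_cfg, scale_factor)
    dataset = simulate_dataset(genome_s, demo, arch, seed=seed)
    data = dataset.to_training_data()

    if scale_factor < 1.0:
        n_train = data.n
        keep_n = max(50, round(n_train * scale_factor))
        rng = np.random.default_rng(seed + 7)
        keep = np.sort(rng.choice(n_train, size=keep_n, replace=False))
        from .model import TrainingData
        data = TrainingData(y1=data.y1[keep], y2=data.y2[keep],
                            Z=data.Z[keep], k=data.k, snp_ids=data.snp_ids)

    rows = []
    for m_idx, method in enumerate(methods):
        cfg = dataclasses.replace(chain_s, method=method,
                                  seed=seed + 13 * (m_idx + 1))
        summary = run_chain(data, Priors(), cfg)
        rep = evaluate_candidates(dataset, summary, generations=generations,
                                  scenario=scenario, replicate=replicate)
        for row in rep.rows:
            rows.append({**row, "scale_factor": scale_factor})
        # generation-0 rows carry the replicate's variance components
        rows.append({
            "scenario": scenario, "replicate": replicate, "method": method,
            "trait": "both" if method == "lt-bayescpi" else
            ("A" if method == "bayescpi" else "B"),
            "generation": 0, "scale_factor": scale_factor,
            "pi_included": summary.prop_included,
            "r_g_hat": summary.genetic_correlation,
            "r_e_hat": summary.residual_correlation,
        })
    return pd.DataFrame(rows)


def run_scenario(arch: ArchitectureConfig, n_replicates: int,
                 genome: GenomeConfig | None = None,
                 demo: DemographyConfig | None = None,
                 chain_cfg: ChainConfig | None = None,
                 scale_factor: float = 1.0, base_seed: int = 0,
                 scenario: str = "standard", **kwargs) -> pd.DataFrame:
    """All replicates of one scenario; replicate failures are recorded and
    skipped so the scenario completes."""
    genome = genome or GenomeConfig()
    demo = demo or DemographyConfig()
    chain_cfg = chain_cfg or ChainConfig()
    frames, failures = [], []
    for rep in range(n_replicates):
        seed = replicate_seed(base_seed, scenario, rep)
        try:
            frames.append(run_replicate(
                arch, genome, demo, chain_cfg, seed,
                scale_factor=scale_factor, scenario=scenario,
                replicate=rep, **kwargs))
        except Exception as err:   # noqa: BLE001 — scenario must continue
            logger.error("replicate %d of %s failed: %s", rep, scenario, err)
            failures.append((rep, str(err)))
    if not frames:
        raise RuntimeError(f"all replicates of {scenario} failed: {failures}")
    df = pd.concat(frames, ignore_index=True)
    df.attrs["failures"] = failures
    return df


def aggregate(df: pd.DataFrame,
              value_cols=("accuracy", "slope", "slope_rescaled")) -> \
        pd.DataFrame:
    """Mean and standard error across replicates per
    (scenario, method, trait, generation)."""
    value_cols = [c for c in value_cols if c in df.columns]
    sub = df[df["generation"] > 0]
    g = sub.groupby(["scenario", "method", "trait", "generation"])
    out = []
    for keys, grp in g:
        row = dict(zip(["scenario", "method", "trait", "generation"], keys))
        row["n_replicates"] = grp["replicate"].nunique()
        for c in value_cols:
            v = grp[c].dropna()
            row[f"{c}_mean"] = v.mean()
            row[f"{c}_se"] = v.std(ddof=1) / np.sqrt(len(v)) if len(v) > 1 \
                else np.nan
        out.append(row)
    return pd.DataFrame(out)


def table_by_generation(agg: pd.DataFrame) -> pd.DataFrame:
    """Accuracy by method/trait across candidate generations (wide)."""
    return agg.pivot_table(index=["method", "trait"], columns="generation",
                           values="accuracy_mean")


def increments(agg: pd.DataFrame, generation: int = 3) -> pd.DataFrame:
    """Joint-minus-single accuracy increment per trait at one generation."""
    sel = agg[agg["generation"] == generation]
    rows = []
    for (scen, trait), grp in sel.groupby(["scenario", "trait"]):
        single = grp[grp["method"] != "lt-bayescpi"]["accuracy_mean"]
        joint = grp[grp["method"] == "lt-bayescpi"]["accuracy_mean"]
        if len(single) and len(joint):
            rows.append({"scenario": scen, "trait": trait,
                         "single": float(single.iloc[0]),
                         "lt_bayescpi": float(joint.iloc[0]),
                         "increment": float(joint.iloc[0]
                                            - single.iloc[0])})
    return pd.DataFrame(rows)


def variance_component_table(df: pd.DataFrame) -> pd.DataFrame:
    """Mean +/- s.e. of the joint model's estimated genetic/residual
    correlations and proportion of non-zero SNPs."""
    sub = df[(df["generation"] == 0) & (df["method"] == "lt-bayescpi")]
    rows = []
    for scen, grp in sub.groupby("scenario"):
        row = {"scenario": scen, "n_replicates": len(grp)}
        for c in ("r_g_hat", "r_e_hat", "pi_included"):
            v = grp[c].dropna()
            row[f"{c}_mean"] = v.mean()
            row[f"{c}_se"] = v.std(ddof=1) / np.sqrt(len(v)) if len(v) > 1 \
                else np.nan
        rows.append(row)
    return pd.DataFrame(rows)
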
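"""Plain-text readers and writers.

Canonical formats (all tab-delimited):

* genotypes — header row of SNP ids, first column ``id``, dosages 0/1/2;
* phenotypes — columns id, generation, role, pheno_A, pheno_B, tbv_A,
  tbv_B, liability_B (missing values empty / NaN, pheno_B -1 if unobserved);
* QTL truth — locus, group, a_A, a_B;
* scenario config — YAML holding the three config blocks, seed and
  replicate index.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .model import InputError, PosteriorSummary, TrainingData
from .sim import (ArchitectureConfig, DemographyConfig, GenomeConfig,
                  GROUP_NAMES, SimulatedDataset)

PHENO_COLUMNS = ["id", "generation", "role", "pheno_A", "pheno_B", "tbv_A",
                 "tbv_B", "liability_B"]


def write_genotypes(path, genotypes, snp_ids, ind_ids=None):
    genotypes = np.asarray(genotypes)
    if ind_ids is None:
        ind_ids = [f"ind{i:05d}" for i in range(genotypes.shape[0])]
    df = pd.DataFrame(genotypes.astype(np.int8), columns=list(snp_ids))
    df.insert(0, "id", list(ind_ids))
    df.to_csv(path, sep="\t", index=False)


def read_genotypes(path):
    df = pd.read_csv(path, sep="\t")
    if df.columns[0] != "id":
        raise InputError(f"{path}: first genotype column must be 'id', "
                         f"found {df.columns[0]!r}")
    ind_ids = df["id"].astype(str).tolist()
    snp_ids = df.columns[1:].tolist()
    Z = df.iloc[:, 1:].to_numpy()
    return ind_ids, snp_ids, Z


def write_phenotypes(path, dataset: SimulatedDataset, ind_ids=None):
    n = dataset.generation.size
    if ind_ids is None:
        ind_ids = [f"ind{i:05d}" for i in range(n)]
    pd.DataFrame({
        "id": ind_ids, "generation": dataset.generation,
        "role": dataset.role, "pheno_A": dataset.pheno_A,
        "pheno_B": dataset.pheno_B, "tbv_A": dataset.tbv_A,
        "tbv_B": dataset.tbv_B, "liability_B": dataset.liability_B,
    }).to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_phenotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in PHENO_COLUMNS[:5] if c not in df.columns]
    if missing:
        raise InputError(f"{path}: missing phenotype columns {missing}")
    return df


def write_qtl(path, qtl):
    pd.DataFrame({
        "locus": qtl.positions,
        "group": [GROUP_NAMES[g] for g in qtl.group],
        "a_A": qtl.effects[:, 0], "a_B": qtl.effects[:, 1],
    }).to_csv(path, sep="\t", index=False, float_format="%.10g")


def load_training_tables(genotype_path, phenotype_path,
                         trait_continuous: str = "pheno_A",
                         trait_binary: str = "pheno_B",
                         method: str = "lt-bayescpi") -> TrainingData:
    """Assemble TrainingData from the canonical text files; only rows with
    the required phenotypes observed are used."""
    ind_ids, snp_ids, Z = read_genotypes(genotype_path)
    df = pd.read_csv(phenotype_path, sep="\t")
    if "id" not in df.columns:
        raise InputError(f"{phenotype_path}: missing 'id' column")
    df = df.set_index("id").loc[[str(i) for i in ind_ids]].reset_index() \
        if df["id"].dtype == object else df
    need1 = method in ("lt-bayescpi", "bayescpi")
    need2 = method in ("lt-bayescpi", "bayestcpi")
    for col, needed in ((trait_continuous, need1), (trait_binary, need2)):
        if needed and col not in df.columns:
            raise InputError(f"{phenotype_path}: missing column {col!r}")
    mask = np.ones(len(df), dtype=bool)
    if need1:
        mask &= np.isfinite(df[trait_continuous].to_numpy(dtype=float))
    if need2:
        mask &= df[trait_binary].to_numpy(dtype=float) >= 0
    y1 = df.loc[mask, trait_continuous].to_numpy(dtype=float) if need1 \
        else None
    y2 = df.loc[mask, trait_binary].to_numpy(dtype=int) if need2 else None
    k = int(y2.max()) + 1 if need2 else 2
    return TrainingData(y1=y1, y2=y2, Z=Z[mask.to_numpy()
                        if hasattr(mask, "to_numpy") else mask],
                        k=max(k, 2), snp_ids=snp_ids)


def write_posterior(outdir, summary: PosteriorSummary):
    """SNP-effect table, variance-component traces and a run manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    q = summary.inclusion_freq.size
    ids = summary.snp_ids or [f"SNP{j:06d}" for j in range(q)]
    eff = pd.DataFrame({"snp": ids})
    if summary.g1_hat is not None:
        eff["g1_hat"] = summary.g1_hat
    if summary.g2_hat is not None:
        eff["g2_hat"] = summary.g2_hat
    eff["inclusion_freq"] = summary.inclusion_freq
    eff.to_csv(outdir / "snp_effects.tsv", sep="\t", index=False,
               float_format="%.8g")
    pd.DataFrame(summary.traces).to_csv(outdir / "traces.tsv", sep="\t",
                                        index=False, float_format="%.8g")
    manifest = dict(summary.settings)
    manifest.update({
        "pi_hat": summary.pi_hat, "prop_included": summary.prop_included,
        "G0_hat": np.atleast_2d(summary.G0_hat).tolist(),
        "Re_hat": np.atleast_2d(summary.Re_hat).tolist(),
        "genetic_correlation": summary.genetic_correlation,
        "residual_correlation": summary.residual_correlation,
    })
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))


def save_scenario(path, genome: GenomeConfig, demo: DemographyConfig,
                  arch: ArchitectureConfig, seed: int = 0,
                  replicate: int = 0):
    doc = {
        "genome": dataclasses.asdict(genome),
        "demography": dataclasses.asdict(demo),
        "architecture": dataclasses.asdict(arch),
        "seed": seed, "replicate": replicate,
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_scenario(path):
    doc = yaml.safe_load(Path(path).read_text())
    arch = doc.get("architecture", {})
    if arch.get("group_ratio") is not None:
        arch["group_ratio"] = tuple(arch["group_ratio"])
    return (GenomeConfig(**doc.get("genome", {})),
            DemographyConfig(**doc.get("demography", {})),
            ArchitectureConfig(**arch),
            int(doc.get("seed", 0)), int(doc.get("replicate", 0)))
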
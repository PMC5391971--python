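"""Accuracy and bias metrics for genomic prediction.

Accuracy is the Pearson correlation between true breeding values (TBV) and
genomic estimated breeding values (GEBV) in a candidate generation; bias is
the ordinary least-squares regression slope of TBV on GEBV (1 = unbiased).
For the threshold trait the GEBV lives on the liability scale of the
analysis, where the residual variance is fixed at 1, so the slope is also
reported rescaled by the true residual liability variance ``v_e2`` of the
generating process (the literal convention, slope / v_e2) and, alongside,
by its square root (standard-deviation-proportional scaling).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .model import InputError, PosteriorSummary


def compute_gebv(genotypes: np.ndarray, posterior: PosteriorSummary,
                 snp_ids: list[str] | None = None) -> dict[str, np.ndarray]:
    """GEBV per trait: the dosage-weighted sum of posterior-mean SNP effects.

    If both the posterior and the caller carry SNP ids the panels must match.
    """
    Z = np.asarray(genotypes, dtype=np.float64)
    if snp_ids is not None and posterior.snp_ids is not None:
        if list(snp_ids) != list(posterior.snp_ids):
            missing = sorted(set(posterior.snp_ids) - set(snp_ids))[:10]
            raise InputError(
                f"candidate SNP panel does not match training panel; first "
                f"missing ids: {missing}")
    out = {}
    for trait, g_hat in (("A", posterior.g1_hat), ("B", posterior.g2_hat)):
        if g_hat is None:
            continue
        if Z.shape[1] != g_hat.size:
            raise InputError(
                f"{Z.shape[1]} candidate SNPs vs {g_hat.size} fitted effects")
        out[trait] = Z @ g_hat
    return out


def accuracy(tbv: np.ndarray, gebv: np.ndarray) -> float:
    """Pearson correlation r(TBV, GEBV); NaN (with a warning) when either
    input has zero variance."""
    tbv = np.asarray(tbv, dtype=float)
    gebv = np.asarray(gebv, dtype=float)
    if tbv.size != gebv.size or tbv.size < 3:
        raise InputError("accuracy needs equal-length vectors with n >= 3")
    if np.std(tbv) == 0 or np.std(gebv) == 0:
        warnings.warn("zero-variance input: accuracy undefined",
                      RuntimeWarning, stacklevel=2)
        return float("nan")
    return float(np.corrcoef(tbv, gebv)[0, 1])


def bias_slope(tbv: np.ndarray, gebv: np.ndarray,
               threshold_trait: bool = False,
               v_e2: float | None = None) -> dict[str, float]:
    """OLS slope of TBV on GEBV; for the threshold trait also the rescaled
    slopes (slope / v_e2 as the primary convention, slope / sqrt(v_e2)
    alongside)."""
    tbv = np.asarray(tbv, dtype=float)
    gebv = np.asarray(gebv, dtype=float)
    var_g = np.var(gebv, ddof=1)
    if var_g == 0:
        warnings.warn("zero-variance GEBV: slope undefined", RuntimeWarning,
                      stacklevel=2)
        return {"slope": float("nan"), "slope_rescaled": float("nan"),
                "slope_rescaled_sd": float("nan")}
    slope = float(np.cov(tbv, gebv)[0, 1] / var_g)
    out = {"slope": slope, "slope_rescaled": float("nan"),
           "slope_rescaled_sd": float("nan")}
    if threshold_trait:
        if v_e2 is None or v_e2 <= 0:
            raise InputError("rescaling the threshold-trait slope needs "
                             "v_e2 > 0")
        out["slope_rescaled"] = slope / v_e2
        out["slope_rescaled_sd"] = slope / np.sqrt(v_e2)
    return out


def paired_test(acc_method1, acc_method2) -> tuple[float, float]:
    """Paired two-sided t-test on per-replicate accuracy differences.

    Conventions for degenerate inputs: all differences zero -> (0.0, 1.0);
    constant non-zero difference -> (inf with the sign of the difference,
    0.0)."""
    a = np.asarray(acc_method1, dtype=float)
    b = np.asarray(acc_method2, dtype=float)
    if a.size != b.size or a.size < 2:
        raise InputError("paired test needs >= 2 paired replicates")
    d = a - b
    if np.all(d == d[0]):
        if d[0] == 0:
            return 0.0, 1.0
        return float(np.sign(d[0]) * np.inf), 0.0
    t, p = stats.ttest_rel(a, b)
    return float(t), float(p)


@dataclass
class EvaluationReport:
    """Long-format accuracy/bias table for one fitted replicate."""

    rows: list[dict] = field(default_factory=list)
    v_e2: float | None = None
    scenario: str = ""
    replicate: int = 0

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame(self.rows)


def evaluate_candidates(dataset, posterior: PosteriorSummary,
                        generations=None, scenario: str = "",
                        replicate: int = 0) -> EvaluationReport:
    """Per-generation accuracy and bias of one fitted model on the candidate
    generations of a simulated dataset."""
    report = EvaluationReport(v_e2=dataset.v_e2, scenario=scenario,
                              replicate=replicate)
    if generations is None:
        generations = np.unique(dataset.generation[dataset.candidates])
    for gen in generations:
        sel = dataset.generation == gen
        gebv = compute_gebv(dataset.genotypes[sel], posterior,
                            snp_ids=dataset.marker_ids)
        for trait, tbv in (("A", dataset.tbv_A[sel]),
                           ("B", dataset.tbv_B[sel])):
            if trait not in gebv:
                continue
            thr = trait == "B"
            slopes = bias_slope(tbv, gebv[trait], threshold_trait=thr,
                                v_e2=dataset.v_e2 if thr else None)
            report.rows.append({
                "scenario": scenario, "replicate": replicate,
                "method": posterior.method, "trait": trait,
                "generation": int(gen),
                "accuracy": accuracy(tbv, gebv[trait]), **slopes})
    return report
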
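"""Summary-statistics association of genetically predicted methylation
with cancer risk.

The core statistic for CpG m with prediction model weights W is

    Z_m = sum_{s in Model_m} W_s * (sigma_s / sigma_m) * (beta_s / se_s)

where sigma_s is the reference-panel dosage standard deviation of variant
s and sigma_m is the standard deviation of the model-predicted methylation
over reference samples (computed from X @ W, so it is LD-aware). Effects
are reported as odds ratios per standard deviation of genetically
predicted methylation with normal-approximation confidence intervals.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .types import (
    AssociationRecord,
    GenotypeMatrix,
    GwasSummary,
    PALINDROMIC_PAIRS,
    PredictionModel,
    ReferenceMoments,
)

logger = logging.getLogger(__name__)


def reference_moments(geno: GenotypeMatrix,
                      model: PredictionModel) -> ReferenceMoments:
    """Compute sigma_s per model variant and sigma_m of predicted values."""
    vid = geno.variants["variant_id"]
    lookup = pd.Series(np.arange(len(vid)), index=vid)
    idx = lookup.reindex(model.weights["variant_id"]).dropna().astype(int)
    dosages = np.nan_to_num(geno.dosages[:, idx.to_numpy()],
                            nan=np.nanmean(geno.dosages))
    w = model.weights.set_index("variant_id").loc[idx.index, "weight"].to_numpy()
    sigma_s = pd.Series(dosages.std(axis=0, ddof=1), index=idx.index)
    pred = dosages @ w
    sigma_m = float(np.std(pred, ddof=1)) if len(pred) > 1 else 0.0
    return ReferenceMoments(sigma_s=sigma_s, sigma_m=sigma_m)


def harmonize(model: PredictionModel, gwas: GwasSummary
              ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Align GWAS effects to the model's effect alleles.

    Matching alleles keep beta as-is; swapped alleles negate beta and map
    freq to 1-freq; palindromic pairs and full mismatches are dropped.
    Returns (aligned pairs, drop report).
    """
    g = gwas.table.set_index("variant_id")
    kept, dropped = [], []
    for _, row in model.weights.iterrows():
        vid = row["variant_id"]
        if vid not in g.index:
            dropped.append({"variant_id": vid, "reason": "missing_in_gwas"})
            continue
        rec = g.loc[vid]
        mea, moa = row["effect_allele"], row["other_allele"]
        gea, goa = rec["effect_allele"], rec["other_allele"]
        if (mea, moa) in PALINDROMIC_PAIRS:
            dropped.append({"variant_id": vid, "reason": "palindromic"})
            continue
        if (gea, goa) == (mea, moa):
            beta, freq = rec["beta"], rec["freq"]
        elif (gea, goa) == (moa, mea):
            beta, freq = -rec["beta"], 1.0 - rec["freq"]
        else:
            dropped.append({"variant_id": vid, "reason": "allele_mismatch"})
            continue
        kept.append({"variant_id": vid, "weight": row["weight"],
                     "beta": beta, "se": rec["se"], "freq": freq,
                     "n": rec["n"]})
    return (pd.DataFrame(kept, columns=["variant_id", "weight", "beta",
                                        "se", "freq", "n"]),
            pd.DataFrame(dropped, columns=["variant_id", "reason"]))


def z_to_p(z: float) -> float:
    """Two-sided normal p-value, 2*Phi(-|z|), via the log-scale tail."""
    if not np.isfinite(z):
        raise ValueError("z must be finite")
    # exp of logsf stays accurate into the subnormal range
    return float(min(2.0 * np.exp(stats.norm.logsf(abs(z))), 1.0))


def log10_p_from_z(z: float) -> float:
    """log10 of the two-sided p, usable beyond double underflow."""
    return float((stats.norm.logsf(abs(z)) + np.log(2.0)) / np.log(10.0))


def mwas_z(model: PredictionModel, gwas: GwasSummary, ref: ReferenceMoments,
           cancer: str = "") -> AssociationRecord:
    """Evaluate the summary-statistic association for one CpG-cancer pair."""
    pairs, dropped = harmonize(model, gwas)
    if len(dropped):
        logger.info("%s: dropped %d/%d model variants", model.cpg_id,
                    len(dropped), model.n_snps)
    if pairs.empty or ref.sigma_m <= 0:
        return AssociationRecord(
            cpg_id=model.cpg_id, cancer=cancer, z=np.nan, p=np.nan,
            or_per_sd=np.nan, ci_low=np.nan, ci_high=np.nan,
            n_model_variants_used=0, n_model_variants=model.n_snps,
            status="untestable")
    sigma_s = ref.sigma_s.reindex(pairs["variant_id"]).to_numpy()
    w = pairs["weight"].to_numpy()
    zs = pairs["beta"].to_numpy() / pairs["se"].to_numpy()
    z = float(np.sum(w * (sigma_s / ref.sigma_m) * zs))
    p = z_to_p(z)
    or_sd, lo, hi = effect_or(pairs, sigma_s, ref.sigma_m, z)
    return AssociationRecord(
        cpg_id=model.cpg_id, cancer=cancer, z=z, p=p, or_per_sd=or_sd,
        ci_low=lo, ci_high=hi, n_model_variants_used=len(pairs),
        n_model_variants=model.n_snps)


def effect_or(pairs: pd.DataFrame, sigma_s: np.ndarray, sigma_m: float,
              z: float) -> tuple[float, float, float]:
    """OR per SD of predicted methylation with a 95% CI.

    gamma = sum_s W_s (sigma_s^2 / sigma_m^2) beta_s is the log-odds per
    unit of predicted methylation; lnOR per SD = gamma * sigma_m; its
    standard error is taken as |lnOR / Z| so the CI is consistent with the
    association Z score.
    """
    w = pairs["weight"].to_numpy()
    beta = pairs["beta"].to_numpy()
    gamma = float(np.sum(w * (sigma_s ** 2 / sigma_m ** 2) * beta))
    ln_or = gamma * sigma_m
    if z == 0:
        logger.warning("Z = 0: confidence interval undefined")
        return float(np.exp(ln_or)), np.nan, np.nan
    se = abs(ln_or / z)
    lo, hi = np.exp(ln_or - 1.96 * se), np.exp(ln_or + 1.96 * se)
    return float(np.exp(ln_or)), float(lo), float(hi)


def ci_from_or_z(or_value: float, z: float) -> tuple[float, float]:
    """Reconstruct the 95% CI of an OR from its value and |Z|."""
    ln_or = np.log(or_value)
    se = abs(ln_or / z)
    return float(np.exp(ln_or - 1.96 * se)), float(np.exp(ln_or + 1.96 * se))


def bonferroni_threshold(n_models: int) -> float:
    """Per-cancer Bonferroni threshold 0.05 / n_models."""
    if n_models < 1:
        raise ValueError("n_models must be >= 1")
    return 0.05 / n_models


def bonferroni_gate(records: list[AssociationRecord],
                    n_models: int) -> tuple[list[AssociationRecord], float]:
    """Flag records with p strictly below the per-cancer threshold."""
    thr = bonferroni_threshold(n_models)
    for rec in records:
        rec.bonferroni_significant = bool(
            np.isfinite(rec.p) and rec.p < thr)
    return records, thr


def records_to_frame(records: list[AssociationRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.to_dict() for r in records])
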
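"""Approximate-Bayes-factor colocalization of cis-mQTL and GWAS signals.

Single-causal-variant colocalization over a shared cis region: per-variant
Wakefield log approximate Bayes factors for each trait are combined into
posterior probabilities of five hypotheses —

    H0 no association, H1 trait 1 only, H2 trait 2 only,
    H3 two distinct causal variants, H4 one shared causal variant —

with per-configuration priors p1, p2, p12. PP.H4 > 0.80 is called a high
and 0.50 < PP.H4 <= 0.80 a moderate probability of colocalization.

Prior effect variances default to 0.15^2 for the quantitative methylation
trait and 0.2^2 for the case-control trait.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .types import GenotypeMatrix

W_QUANT = 0.15 ** 2     # prior effect variance, quantitative trait
W_CC = 0.2 ** 2         # prior effect variance, case-control trait


@dataclass
class ColocResult:
    pp: dict[str, float]          # pp_h0 .. pp_h4
    n_variants: int
    priors: tuple[float, float, float]

    @property
    def tier(self) -> str:
        return classify_tier(self.pp["pp_h4"])


def wakefield_log_abf(beta: np.ndarray, se: np.ndarray,
                      w: float) -> np.ndarray:
    """Wakefield log approximate Bayes factor per variant.

    With V = se^2, r = w/(V+w), z = beta/se:
    log ABF = 0.5 * (log(1-r) + r z^2).
    """
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise ValueError("se must be positive")
    if w <= 0:
        raise ValueError("prior variance must be positive")
    v = se ** 2
    r = w / (v + w)
    z = beta / se
    return 0.5 * (np.log1p(-r) + r * z * z)


def coloc_posteriors(labf1: np.ndarray, labf2: np.ndarray,
                     p1: float = 1e-4, p2: float = 1e-4,
                     p12: float = 1e-5) -> ColocResult:
    """Posterior probabilities of H0-H4 from per-variant log ABFs.

    Hypothesis weights are log-sum-exp accumulations over single-variant
    configurations (H1, H2, H4) and ordered variant pairs excluding the
    diagonal (H3), against an H0 weight of 1.
    """
    labf1 = np.asarray(labf1, dtype=float)
    labf2 = np.asarray(labf2, dtype=float)
    if labf1.shape != labf2.shape or labf1.ndim != 1 or len(labf1) < 1:
        raise ValueError("labf vectors must be equal-length, length >= 1")
    n = len(labf1)

    lh0 = 0.0
    lh1 = np.log(p1) + logsumexp(labf1)
    lh2 = np.log(p2) + logsumexp(labf2)
    lh4 = np.log(p12) + logsumexp(labf1 + labf2)
    # H3: sum over i != j of ABF1_i * ABF2_j = S1*S2 - sum_i ABF1_i ABF2_i
    a = logsumexp(labf1) + logsumexp(labf2)
    b = logsumexp(labf1 + labf2)
    if n == 1 or b >= a:
        lh3 = -np.inf
    else:
        lh3 = np.log(p1) + np.log(p2) + a + np.log1p(-np.exp(b - a))

    logs = np.array([lh0, lh1, lh2, lh3, lh4])
    norm = logsumexp(logs)
    pp = np.exp(logs - norm)
    return ColocResult(
        pp={f"pp_h{i}": float(pp[i]) for i in range(5)},
        n_variants=n, priors=(p1, p2, p12))


def classify_tier(pp_h4: float) -> str:
    """PP.H4 > 0.80 -> high; > 0.50 -> moderate; else none (strict)."""
    if not (0 <= pp_h4 <= 1):
        raise ValueError("pp_h4 must lie in [0, 1]")
    if pp_h4 > 0.80:
        return "high"
    if pp_h4 > 0.50:
        return "moderate"
    return "none"


def marginal_mqtl_stats(geno: GenotypeMatrix, y: np.ndarray,
                        variant_idx: np.ndarray | None = None) -> pd.DataFrame:
    """Per-variant marginal regression of a methylation trait on dosage.

    Recomputed from the reference panel (model weights are not reused):
    one simple OLS per variant, returning beta, se, z, p.
    """
    idx = np.arange(geno.n_variants) if variant_idx is None \
        else np.asarray(variant_idx)
    x = np.nan_to_num(geno.dosages[:, idx], nan=np.nanmean(geno.dosages))
    y = np.asarray(y, dtype=float)
    n = len(y)
    xc = x - x.mean(axis=0)
    yc = y - y.mean()
    sxx = np.einsum("ij,ij->j", xc, xc)
    sxx_safe = np.where(sxx <= 0, np.nan, sxx)
    beta = (xc.T @ yc) / sxx_safe
    resid_ss = yc @ yc - beta * (xc.T @ yc)
    se = np.sqrt(np.maximum(resid_ss, 0) / (n - 2) / sxx_safe)
    from scipy import stats as _st
    z = beta / se
    p = 2 * _st.t.sf(np.abs(z), df=n - 2)
    return pd.DataFrame({
        "variant_id": geno.variants["variant_id"].iloc[idx].to_numpy(),
        "beta": beta, "se": se, "z": z, "p": p, "n": n,
    })


def coloc_region(mqtl: pd.DataFrame, gwas: pd.DataFrame,
                 p1: float = 1e-4, p2: float = 1e-4, p12: float = 1e-5,
                 w1: float = W_QUANT, w2: float = W_CC) -> ColocResult:
    """Colocalize a CpG's cis-mQTL stats against GWAS stats.

    Both frames need variant_id, beta, se; only shared variants with
    finite statistics enter.
    """
    merged = mqtl.merge(gwas, on="variant_id", suffixes=("_m", "_g"))
    ok = np.isfinite(merged["beta_m"]) & np.isfinite(merged["beta_g"]) & \
        (merged["se_m"] > 0) & (merged["se_g"] > 0)
    merged = merged.loc[ok]
    if merged.empty:
        raise ValueError("no shared variants with finite statistics")
    labf1 = wakefield_log_abf(merged["beta_m"].to_numpy(),
                              merged["se_m"].to_numpy(), w1)
    labf2 = wakefield_log_abf(merged["beta_g"].to_numpy(),
                              merged["se_g"].to_numpy(), w2)
    return coloc_posteriors(labf1, labf2, p1=p1, p2=p2, p12=p12)
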
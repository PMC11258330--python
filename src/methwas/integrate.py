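"""Downstream evidence integration: tumor/normal differential methylation,
gene-level evidence gating, and assembly of direction-consistent
CpG-gene-cancer trios.

The trio rule: for a Bonferroni-significant CpG-cancer association and an
FDR-significant CpG-gene (eQTM) link, the trio is consistent when the
gene carries a significant gene-cancer evidence direction and

    sign(CpG-cancer) = sign(CpG-gene) * sign(gene-cancer).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import qc


def differential_methylation(beta_norm: np.ndarray, status: np.ndarray,
                             covariates: np.ndarray | None = None
                             ) -> pd.DataFrame:
    """Per-CpG status effect (tumor minus normal) and two-sided p.

    ``beta_norm`` is CpG x sample, already quantile-normalized between
    samples and inverse-normalized per CpG; ``status`` is 1 for tumor and
    0 for adjacent normal. The model is an ordinary linear model of
    normalized methylation on status + covariates (the status term fixed).
    """
    from scipy import stats

    y = np.atleast_2d(np.asarray(beta_norm, dtype=float))
    status = np.asarray(status, dtype=float)
    n = y.shape[1]
    if status.min() == status.max():
        raise ValueError("both tumor and normal samples are required")
    cols = [np.ones(n), status]
    if covariates is not None:
        c = np.asarray(covariates, dtype=float)
        if c.ndim == 1:
            c = c[:, None]
        cols.extend(c.T)
    design = np.column_stack(cols)
    k = design.shape[1]
    if np.linalg.matrix_rank(design) < k:
        raise ValueError("rank-deficient design")
    xtx_inv = np.linalg.inv(design.T @ design)
    coef = xtx_inv @ design.T @ y.T                       # k x n_cpg
    resid = y.T - design @ coef
    dof = n - k
    sigma2 = np.sum(resid ** 2, axis=0) / dof
    se = np.sqrt(sigma2 * xtx_inv[1, 1])
    eff = coef[1]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, eff / se, 0.0)
    p = 2 * stats.t.sf(np.abs(t), df=dof)
    return pd.DataFrame({"effect": eff, "t": t, "p": p})


def normalize_for_dm(beta: pd.DataFrame) -> pd.DataFrame:
    """Quantile normalization between samples then inverse-normal per CpG."""
    return qc.inverse_normal_rows(qc.quantile_normalize_samples(beta))


def validate_direction(dm_effect: float, dm_p: float, assoc_z: float,
                       p_threshold: float = 0.05) -> bool:
    """Differential methylation validates an association when its p < 0.05
    and the effect direction matches the association Z sign."""
    if not (np.isfinite(dm_effect) and np.isfinite(assoc_z)):
        raise ValueError("effect and z must be finite")
    return bool(dm_p < p_threshold and np.sign(dm_effect) == np.sign(assoc_z)
                and dm_effect != 0 and assoc_z != 0)


def essentiality_filter(ceres: pd.DataFrame,
                        threshold: float = -0.50) -> list[str]:
    """Genes essential for proliferation: median CERES < threshold (strict).

    ``ceres`` is gene x cell-line; missing values are excluded from each
    gene's median.
    """
    med = ceres.median(axis=1, skipna=True)
    return list(med.index[med < threshold])


def gene_expression_gate(models: pd.DataFrame,
                         method_order: tuple[str, ...] = ("elastic_net", "jti")
                         ) -> pd.DataFrame:
    """Keep, per gene, the qualifying expression model with the larger R^2.

    ``models`` needs columns gene_id, method, r2, p. A model qualifies
    when R^2 > 0.01 and p < 0.05; R^2 ties break by ``method_order``.
    """
    ok = models[(models["r2"] > 0.01) & (models["p"] < 0.05)].copy()
    if ok.empty:
        return ok
    rank = {m: i for i, m in enumerate(method_order)}
    ok["_rank"] = ok["method"].map(lambda m: rank.get(m, len(rank)))
    ok = ok.sort_values(["gene_id", "r2", "_rank"],
                        ascending=[True, False, True])
    return ok.drop_duplicates("gene_id", keep="first") \
        .drop(columns="_rank").reset_index(drop=True)


@dataclass
class GeneEvidence:
    """Direction-bearing gene-cancer evidence for one gene and cancer.

    Two optional channels: the predicted-expression association (z, q)
    and an external differential-expression table (logFC, q). The
    resolved direction is +1/-1 when at least one channel is significant
    at q < 0.05; when both are significant but discordant the direction
    is 0 and the conflict flag is set.
    """

    gene_id: str
    cancer: str = ""
    assoc_z: float | None = None
    assoc_q: float | None = None
    diffexpr_logfc: float | None = None
    diffexpr_q: float | None = None
    essential: bool = False

    @property
    def direction(self) -> int:
        sig_a = (self.assoc_q is not None and self.assoc_q < 0.05
                 and self.assoc_z not in (None, 0))
        sig_d = (self.diffexpr_q is not None and self.diffexpr_q < 0.05
                 and self.diffexpr_logfc not in (None, 0))
        if sig_a and sig_d:
            sa, sd = np.sign(self.assoc_z), np.sign(self.diffexpr_logfc)
            return int(sa) if sa == sd else 0
        if sig_a:
            return int(np.sign(self.assoc_z))
        if sig_d:
            return int(np.sign(self.diffexpr_logfc))
        return 0

    @property
    def conflict(self) -> bool:
        sig_a = (self.assoc_q is not None and self.assoc_q < 0.05
                 and self.assoc_z not in (None, 0))
        sig_d = (self.diffexpr_q is not None and self.diffexpr_q < 0.05
                 and self.diffexpr_logfc not in (None, 0))
        return bool(sig_a and sig_d
                    and np.sign(self.assoc_z) != np.sign(self.diffexpr_logfc))


def assemble_trios(cpg_cancer: pd.DataFrame, cpg_gene: pd.DataFrame,
                   gene_evidence: dict[str, GeneEvidence]) -> pd.DataFrame:
    """Emit one trio per (significant CpG-cancer) x (q<0.05 CpG-gene) pair.

    ``cpg_cancer`` needs cpg_id, cancer, zscore, pvalue, significant;
    ``cpg_gene`` needs cpg_id, gene_id, beta, q. Consistency requires a
    nonzero gene evidence direction and exact sign parity
    sign_cpg_cancer == sign_cpg_gene * sign_gene_cancer.
    """
    sig_cc = cpg_cancer[cpg_cancer["significant"].astype(bool)]
    sig_cg = cpg_gene[cpg_gene["q"] < 0.05]
    rows = []
    for _, cc in sig_cc.iterrows():
        links = sig_cg[sig_cg["cpg_id"] == cc["cpg_id"]]
        for _, cg in links.iterrows():
            ev = gene_evidence.get(cg["gene_id"])
            s_cc = int(np.sign(cc["zscore"]))
            s_cg = int(np.sign(cg["beta"]))
            s_gc = ev.direction if ev is not None else 0
            consistent = (s_gc != 0 and s_cc == s_cg * s_gc
                          and s_cc != 0 and s_cg != 0)
            rows.append({
                "cpg_id": cc["cpg_id"], "gene_id": cg["gene_id"],
                "cancer": cc["cancer"],
                "sign_cpg_cancer": s_cc, "sign_cpg_gene": s_cg,
                "sign_gene_cancer": s_gc,
                "p_cpg_cancer": cc["pvalue"], "q_cpg_gene": cg["q"],
                "consistent": bool(consistent),
            })
    return pd.DataFrame(rows, columns=[
        "cpg_id", "gene_id", "cancer", "sign_cpg_cancer", "sign_cpg_gene",
        "sign_gene_cancer", "p_cpg_cancer", "q_cpg_gene", "consistent"])
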
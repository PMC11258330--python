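"""Cis expression-quantitative-trait-methylation (eQTM) scan.

Links cancer-associated CpGs to genes whose transcription start site lies
within the CpG's +/-500 kb cis window: per pair, an OLS of
inverse-normalized expression on inverse-normalized methylation adjusting
for 5 methylation + 5 expression hidden factors, with per-tissue
Benjamini-Hochberg FDR control at q < 0.05.

Gene inclusion follows the expression filter (reads >= 6 and TPM > 0.10,
required in at least 20% of samples by default).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from . import qc
from .types import ExpressionMatrix, MethylationMatrix

EQTM_WINDOW = 500_000


def filter_genes(read_counts: pd.DataFrame, tpm: pd.DataFrame,
                 min_reads: int = 6, min_tpm: float = 0.10,
                 min_frac: float = 0.2) -> list[str]:
    """Genes with reads >= min_reads AND TPM > min_tpm in enough samples.

    The per-sample condition uses >= for reads and a strict > for TPM; a
    gene passes when the fraction of samples meeting both is at least
    ``min_frac``.
    """
    if not read_counts.index.equals(tpm.index) or \
            not read_counts.columns.equals(tpm.columns):
        raise ValueError("read_counts and tpm must share genes and samples")
    ok = (read_counts.to_numpy() >= min_reads) & (tpm.to_numpy() > min_tpm)
    frac = ok.mean(axis=1)
    return list(read_counts.index[frac >= min_frac])


def bh_fdr(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order-preserving."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def eqtm_scan(meth: MethylationMatrix, expr: ExpressionMatrix,
              window: int = EQTM_WINDOW,
              k_factors: tuple[int, int] = (5, 5)) -> pd.DataFrame:
    """Scan all cis CpG-gene pairs in one tissue.

    Inputs are expected pre-normalized (quantile between samples,
    inverse-normal per feature). Hidden factors are computed here from the
    normalized matrices; both matrices are residualized on the combined
    factor block + intercept, and each pair is then a simple regression of
    residual expression on residual methylation with degrees of freedom
    adjusted for the projected-out covariates.
    """
    shared = [s for s in meth.samples if s in set(expr.samples)]
    if len(shared) < 10:
        raise ValueError("need at least 10 shared samples")
    m = meth.beta[shared]
    e = expr.expr[shared]
    n = len(shared)

    km, ke = k_factors
    covs = []
    if km > 0:
        covs.append(qc.hidden_factors(m.to_numpy(), km))
    if ke > 0:
        covs.append(qc.hidden_factors(e.to_numpy(), ke))
    if covs:
        c = np.column_stack(covs)
        m_res = qc.residualize(m.to_numpy(), c)
        e_res = qc.residualize(e.to_numpy(), c)
        dof = n - c.shape[1] - 2
    else:
        m_res = m.to_numpy() - m.to_numpy().mean(axis=1, keepdims=True)
        e_res = e.to_numpy() - e.to_numpy().mean(axis=1, keepdims=True)
        dof = n - 2
    if dof < 3:
        raise ValueError("too few samples for the covariate block")

    cpg_pos = meth.cpg_annot.set_index("cpg_id")
    gene_pos = expr.gene_annot.set_index("gene_id")
    cpg_index = {c: i for i, c in enumerate(m.index)}
    gene_index = {g: i for i, g in enumerate(e.index)}

    rows = []
    for cpg_id, crow in cpg_pos.iterrows():
        if cpg_id not in cpg_index:
            continue
        genes = gene_pos[
            (gene_pos["chrom"].astype(str) == str(crow["chrom"])) &
            (gene_pos["tss"] >= crow["pos"] - window) &
            (gene_pos["tss"] <= crow["pos"] + window)]
        mv = m_res[cpg_index[cpg_id]]
        smm = float(mv @ mv)
        if smm == 0:
            continue
        for gene_id in genes.index:
            if gene_id not in gene_index:
                continue
            ev = e_res[gene_index[gene_id]]
            beta = float(mv @ ev) / smm
            resid = ev - beta * mv
            sigma2 = float(resid @ resid) / dof
            se = np.sqrt(sigma2 / smm) if sigma2 > 0 else np.nan
            if not np.isfinite(se) or se == 0:
                continue
            t = beta / se
            p = 2 * stats.t.sf(abs(t), df=dof)
            rows.append({"cpg_id": cpg_id, "gene_id": gene_id,
                         "tissue": meth.tissue, "beta": beta, "se": se,
                         "p": max(p, np.finfo(float).tiny), "n": n})
    out = pd.DataFrame(rows, columns=["cpg_id", "gene_id", "tissue",
                                      "beta", "se", "p", "n"])
    if len(out):
        out["q"] = bh_fdr(out["p"].to_numpy())
    else:
        out["q"] = pd.Series(dtype=float)
    return out
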
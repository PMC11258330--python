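"""Conditional analysis of GWAS summary statistics with an LD reference.

Stepwise forward selection of independently associated variants at a
locus, conditional re-estimation of per-variant effects given the
selected set, re-evaluation of the CpG-cancer association from the
conditional statistics, and classification of loci as known or putative
novel by the >1 Mb distance rule.

All conditional quantities are computed on the z-score / LD-correlation
scale: with marginal z-scores z and reference LD correlation matrix R,

    z_t|S = (z_t - R_tS R_SS^-1 z_S) / sqrt(1 - R_tS R_SS^-1 R_St)

which matches the z statistic of an individual-level regression that
includes the selected genotypes as covariates. Effect sizes are
reconstructed through the marginal standard errors. The selected-set LD
matrix carries a small ridge (1e-6) for numerical invertibility.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .assoc import mwas_z
from .types import (
    AssociationRecord,
    GenotypeMatrix,
    GwasSummary,
    PredictionModel,
    ReferenceMoments,
)

logger = logging.getLogger(__name__)

RIDGE = 1e-6
N_HETEROGENEITY_TOL = 0.2   # drop variants with N off the locus median by >20%


@dataclass
class ConditionalStats:
    """Per-variant statistics conditional on a selected variant set."""

    table: pd.DataFrame            # variant_id, beta, se, z, p (conditional)
    selected: list[str] = field(default_factory=list)
    ld_source: str = "reference_panel"


def ld_matrix(geno: GenotypeMatrix,
              variant_idx: np.ndarray | None = None) -> pd.DataFrame:
    """Reference-panel dosage correlation matrix (mean-imputed)."""
    idx = np.arange(geno.n_variants) if variant_idx is None \
        else np.asarray(variant_idx)
    x = np.nan_to_num(geno.dosages[:, idx], nan=np.nanmean(geno.dosages))
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    xs = (x - x.mean(axis=0)) / sd
    r = (xs.T @ xs) / len(xs)
    ids = geno.variants["variant_id"].iloc[idx]
    return pd.DataFrame(r, index=ids, columns=ids)


def filter_n_heterogeneity(gwas: GwasSummary,
                           tol: float = N_HETEROGENEITY_TOL) -> GwasSummary:
    """Drop variants whose sample size differs >tol from the locus median."""
    n = gwas.table["n"].to_numpy(dtype=float)
    med = np.median(n)
    keep = np.abs(n - med) <= tol * med
    if (~keep).any():
        logger.info("N-heterogeneity guard dropped %d variants",
                    int((~keep).sum()))
    return gwas.subset(keep)


def _conditional_z(z: np.ndarray, r_ts: np.ndarray,
                   r_ss_inv: np.ndarray, z_s: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Conditional z and the explained fraction h = R_tS R^-1 R_St."""
    proj = r_ts @ r_ss_inv
    num = z - proj @ z_s
    h = np.einsum("ij,ij->i", proj, r_ts)
    h = np.clip(h, 0.0, 1.0 - 1e-10)
    return num / np.sqrt(1.0 - h), h


def _inv_selected(ld: pd.DataFrame, selected: list[str]) -> np.ndarray:
    r_ss = ld.loc[selected, selected].to_numpy()
    r_ss = r_ss + RIDGE * np.eye(len(selected))
    try:
        return np.linalg.inv(r_ss)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular selected-set LD submatrix") from exc


def stepwise_select(gwas: GwasSummary, ld: pd.DataFrame,
                    p_enter: float = 5e-8,
                    r2_collinear: float = 0.9) -> list[str]:
    """Forward selection of independently associated variants.

    Starts from the smallest-p variant below ``p_enter`` and iteratively
    adds the candidate with the smallest conditional p below ``p_enter``,
    skipping candidates with r^2 > ``r2_collinear`` against any selected
    variant. Returns the selected variant ids (possibly empty).
    """
    g = filter_n_heterogeneity(gwas).table
    g = g[g["variant_id"].isin(ld.index)].reset_index(drop=True)
    if g.empty:
        return []
    ids = g["variant_id"].to_numpy()
    z = (g["beta"] / g["se"]).to_numpy()
    p = 2 * stats.norm.sf(np.abs(z))

    first = int(np.argmin(p))
    if p[first] >= p_enter:
        return []
    selected = [ids[first]]

    while True:
        r_ss_inv = _inv_selected(ld, selected)
        z_s = pd.Series(z, index=ids).loc[selected].to_numpy()
        cand_mask = ~np.isin(ids, selected)
        r_cs = ld.loc[ids[cand_mask], selected].to_numpy()
        # collinearity guard against every selected variant
        ok = (r_cs ** 2 <= r2_collinear).all(axis=1)
        cand_ids = ids[cand_mask][ok]
        if len(cand_ids) == 0:
            break
        zc = pd.Series(z, index=ids).loc[cand_ids].to_numpy()
        z_cond, _ = _conditional_z(zc, ld.loc[cand_ids, selected].to_numpy(),
                                   r_ss_inv, z_s)
        p_cond = 2 * stats.norm.sf(np.abs(z_cond))
        j = int(np.argmin(p_cond))
        if p_cond[j] >= p_enter:
            break
        selected.append(cand_ids[j])
    return selected


def conditional_stats(targets: list[str], selected: list[str],
                      gwas: GwasSummary, ld: pd.DataFrame) -> ConditionalStats:
    """Conditional beta/se/z/p for target variants given a selected set.

    An empty selected set returns the marginal statistics unchanged; a
    target that is itself selected has conditional z exactly 0.
    """
    g = gwas.table.set_index("variant_id")
    targets = [t for t in targets if t in g.index]
    rows = []
    if not selected:
        for t in targets:
            rec = g.loc[t]
            z = rec["beta"] / rec["se"]
            rows.append({"variant_id": t, "beta": rec["beta"],
                         "se": rec["se"], "z": z,
                         "p": 2 * stats.norm.sf(abs(z)), "n": rec["n"]})
        return ConditionalStats(table=pd.DataFrame(rows), selected=[])

    sel = [s for s in selected if s in g.index and s in ld.index]
    r_ss_inv = _inv_selected(ld, sel)
    z_s = (g.loc[sel, "beta"] / g.loc[sel, "se"]).to_numpy()
    for t in targets:
        rec = g.loc[t]
        se_marg = rec["se"]
        if t in sel:
            rows.append({"variant_id": t, "beta": 0.0, "se": se_marg,
                         "z": 0.0, "p": 1.0, "n": rec["n"]})
            continue
        if t not in ld.index:
            z = rec["beta"] / se_marg
            rows.append({"variant_id": t, "beta": rec["beta"], "se": se_marg,
                         "z": z, "p": 2 * stats.norm.sf(abs(z)),
                         "n": rec["n"]})
            continue
        r_ts = ld.loc[[t], sel].to_numpy()
        z_t = np.array([rec["beta"] / se_marg])
        z_cond, h = _conditional_z(z_t, r_ts, r_ss_inv, z_s)
        h0 = float(h[0])
        if h0 >= 1.0 - 1e-9:
            z_c, se_c, beta_c = 0.0, se_marg, 0.0
        else:
            z_c = float(z_cond[0])
            se_c = float(se_marg / np.sqrt(1.0 - h0))
            beta_c = z_c * se_c
        rows.append({"variant_id": t, "beta": beta_c, "se": se_c,
                     "z": z_c, "p": 2 * stats.norm.sf(abs(z_c)),
                     "n": rec["n"]})
    return ConditionalStats(table=pd.DataFrame(rows), selected=list(sel))


def conditional_mwas(model: PredictionModel, cond: ConditionalStats,
                     ref: ReferenceMoments, gwas: GwasSummary,
                     cancer: str = "") -> AssociationRecord:
    """Re-evaluate the CpG-cancer association with conditional statistics.

    Conditional beta/se replace the marginal ones for every model variant
    covered by ``cond``; allele metadata is carried over from the original
    GWAS table so harmonization behaves identically.
    """
    g = gwas.table.set_index("variant_id")
    ct = cond.table.set_index("variant_id")
    shared = [v for v in ct.index if v in g.index]
    rows = []
    for v in shared:
        rec = g.loc[v]
        c = ct.loc[v]
        se = c["se"] if c["se"] > 0 else rec["se"]
        z = c["z"]
        rows.append({
            "variant_id": v, "chrom": rec["chrom"], "pos": rec["pos"],
            "effect_allele": rec["effect_allele"],
            "other_allele": rec["other_allele"], "freq": rec["freq"],
            "beta": c["beta"], "se": se,
            "p": 2 * stats.norm.sf(abs(z)), "n": rec["n"],
        })
    cond_gwas = GwasSummary(pd.DataFrame(rows))
    return mwas_z(model, cond_gwas, ref, cancer=cancer)


# ---------------------------------------------------------------------------
# novelty classification


@dataclass
class NoveltyCall:
    cpg_id: str
    nearest_known_variant: str | None
    distance_bp: float
    classification: str        # known_locus | putative_novel

    NOVEL_DISTANCE = 1_000_000


def classify_novelty(cpg_id: str, cpg_chrom: str, cpg_pos: int,
                     known_hits: pd.DataFrame) -> NoveltyCall:
    """Classify a CpG as known-locus or putative-novel by the 1 Mb rule.

    ``known_hits`` needs columns chrom, pos (optionally variant_id);
    distance is the minimum |pos difference| over hits on the CpG's
    chromosome, +inf when there are none.
    """
    chrom = str(cpg_chrom).removeprefix("chr")
    if known_hits is None or known_hits.empty:
        return NoveltyCall(cpg_id, None, np.inf, "putative_novel")
    hits = known_hits.copy()
    hits["chrom"] = hits["chrom"].astype(str).str.removeprefix("chr")
    same = hits[hits["chrom"] == chrom]
    if same.empty:
        return NoveltyCall(cpg_id, None, np.inf, "putative_novel")
    dist = (same["pos"].astype(int) - int(cpg_pos)).abs()
    i = dist.idxmin()
    d = int(dist.loc[i])
    vid = same.loc[i, "variant_id"] if "variant_id" in same.columns else None
    cls = "putative_novel" if d > NoveltyCall.NOVEL_DISTANCE else "known_locus"
    return NoveltyCall(cpg_id, vid, d, cls)
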
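"""End-to-end orchestration on synthetic data.

Runs simulate -> qc -> train -> associate -> coloc -> conditional -> eqtm
-> integrate in order, writing each stage's TSV outputs before the next
starts and a manifest with the seed, thresholds, and per-stage row counts.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import assoc as assoc_mod
from . import cojo, coloc, eqtm, io, models, qc, synthio
from .integrate import GeneEvidence, assemble_trios
from .types import PredictionModel

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All inputs, labels and thresholds of one pipeline run.

    Threshold defaults equal the analysis defaults throughout the
    package (QC cutoffs, the R > 0.10 & P < 0.05 reliability gate, coloc
    priors, the 5e-8 stepwise entry threshold, 500 kb windows).
    """

    out_dir: str = "methwas_run"
    seed: int = 0
    cancer: str = "synthetic_cancer"
    scenario: str = "mediated_trio"
    n_ref: int = 300
    n_gwas: int = 20_000
    n_blocks: int = 8
    block_size: int = 25
    rho: float = 0.9
    h2_meth: float = 0.4
    k_causal: int = 3
    share_frac: float = 0.5
    alpha_med: float = 0.1
    gamma_eqtm: float = 0.75
    n_tissues: int = 2
    n_decoys_per_cpg: int = 2
    miss_max: float = 0.05
    maf_min: float = 0.05
    hwe_min: float = 1e-4
    drop_palindromic: bool = True
    cis_window: int = 500_000
    coloc_p1: float = 1e-4
    coloc_p2: float = 1e-4
    coloc_p12: float = 1e-5
    p_enter: float = 5e-8
    r2_collinear: float = 0.9
    eqtm_k_factors: tuple[int, int] = (5, 5)
    train_cross_tissue: bool = False

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["eqtm_k_factors"] = list(self.eqtm_k_factors)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "eqtm_k_factors" in d:
            d["eqtm_k_factors"] = tuple(d["eqtm_k_factors"])
        return cls(**d)

    def to_scenario(self) -> synthio.SimScenario:
        return synthio.SimScenario(
            name=self.scenario, n_ref=self.n_ref, n_gwas=self.n_gwas,
            n_blocks=self.n_blocks, block_size=self.block_size, rho=self.rho,
            h2_meth=self.h2_meth, k_causal=self.k_causal,
            share_frac=self.share_frac, alpha_med=self.alpha_med,
            gamma_eqtm=self.gamma_eqtm, seed=self.seed)


def prepare_residuals(meth, n_factors: int = 0) -> pd.DataFrame:
    """Inverse-normalize each CpG and residualize on the covariate table."""
    inv = qc.inverse_normal_rows(meth.beta)
    cov = meth.covariates.loc[meth.samples].to_numpy()
    if n_factors > 0 and len(meth.beta) > n_factors + 1:
        fac = qc.hidden_factors(inv.to_numpy(), n_factors)
        cov = np.column_stack([cov, fac])
    res = qc.residualize(inv.to_numpy(), cov)
    return pd.DataFrame(res, index=inv.index, columns=inv.columns)


def train_tissue_models(geno, meth, seed: int,
                        cis_window: int = 500_000,
                        with_cross_tissue: bool = False,
                        meth_by_tissue: dict | None = None
                        ) -> dict[str, PredictionModel]:
    """Train and select a model per CpG for one tissue.

    Elastic net is always trained; the cross-tissue fit is added when
    requested and other tissues are available. Returns the selected
    (reliable) model per CpG id.
    """
    resid = prepare_residuals(meth)
    sample_idx = [geno.samples.index(s) for s in meth.samples]
    dos = qc.mean_impute(geno.dosages)[sample_idx, :]
    selected = {}
    for ci, row in meth.cpg_annot.iterrows():
        cis = models.cis_variants(geno, row["chrom"], int(row["pos"]),
                                  window=cis_window)
        if cis.size == 0:
            continue
        y = resid.loc[row["cpg_id"]].to_numpy()
        x = dos[:, cis]
        vmeta = geno.variants.iloc[cis].reset_index(drop=True)
        cands = [models.train_elastic_net(y, x, vmeta, cpg_id=row["cpg_id"],
                                          tissue=meth.tissue, seed=seed)]
        if with_cross_tissue and meth_by_tissue and len(meth_by_tissue) > 1:
            ybt, xbt = {}, {}
            for t, mm in meth_by_tissue.items():
                rr = prepare_residuals(mm)
                si = [geno.samples.index(s) for s in mm.samples]
                ybt[t] = rr.loc[row["cpg_id"]].to_numpy()
                xbt[t] = qc.mean_impute(geno.dosages)[si, :][:, cis]
            ct = models.train_cross_tissue(ybt, xbt, vmeta,
                                           cpg_id=row["cpg_id"], seed=seed)
            if meth.tissue in ct:
                cands.append(ct[meth.tissue])
        pick = models.select_model(cands)
        if pick is not None:
            selected[row["cpg_id"]] = pick
    return selected


def gene_cancer_evidence(y: np.ndarray, expr_cohort: pd.DataFrame,
                         cancer: str = "") -> dict[str, GeneEvidence]:
    """Per-gene association of cohort expression with the phenotype.

    Simple OLS per gene with BH-FDR across genes; forms the
    predicted-expression evidence channel for trio assembly.
    """
    y = np.asarray(y, dtype=float)
    e = expr_cohort.to_numpy()
    n = len(y)
    ec = e - e.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    sxx = np.einsum("ij,ij->i", ec, ec)
    sxx_safe = np.where(sxx <= 0, np.nan, sxx)
    beta = (ec @ yc) / sxx_safe
    resid_ss = yc @ yc - beta * (ec @ yc)
    se = np.sqrt(np.maximum(resid_ss, 0) / (n - 2) / sxx_safe)
    z = beta / se
    p = 2 * stats.t.sf(np.abs(z), df=n - 2)
    p = np.where(np.isfinite(p), np.maximum(p, np.finfo(float).tiny), 1.0)
    q = eqtm.bh_fdr(p)
    out = {}
    for gid, zi, qi in zip(expr_cohort.index, z, q):
        out[gid] = GeneEvidence(gene_id=gid, cancer=cancer,
                                assoc_z=float(zi) if np.isfinite(zi) else 0.0,
                                assoc_q=float(qi))
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full synthetic-data analysis; returns the result bundle."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"seed": config.seed, "config": config.to_dict(), "stages": {}}
    stage = "simulate"
    try:
        sc = config.to_scenario()
        bundle = synthio.simulate_bundle(
            sc, n_tissues=config.n_tissues,
            n_decoys_per_cpg=config.n_decoys_per_cpg)
        geno, meth, truth = bundle["geno"], bundle["meth"], bundle["truth"]
        gwas, expr = bundle["gwas"], bundle["expr"]
        io.write_dosage_tsv(geno, out / "genotypes.tsv")
        io.write_gwas(gwas, out / "gwas.tsv")
        truth.causal.to_csv(out / "truth_causal.tsv", sep="\t", index=False)
        io.write_config(config.to_dict(), out / "config.yaml")
        manifest["stages"][stage] = {"n_variants": geno.n_variants,
                                     "n_cpgs": len(truth.mediation)}

        stage = "qc"
        geno_qc, qc_log = qc.filter_variants(
            geno, miss_max=config.miss_max, maf_min=config.maf_min,
            hwe_min=config.hwe_min, drop_palindromic=config.drop_palindromic)
        qc_log.to_csv(out / "qc_log.tsv", sep="\t", index=False)
        manifest["stages"][stage] = {"n_retained": geno_qc.n_variants}

        stage = "train"
        tissue0 = sorted(meth)[0]
        selected = train_tissue_models(
            geno_qc, meth[tissue0], seed=config.seed,
            cis_window=config.cis_window,
            with_cross_tissue=config.train_cross_tissue,
            meth_by_tissue=meth)
        io.write_model_store(list(selected.values()), out / "models", tissue0)
        manifest["stages"][stage] = {"n_selected_models": len(selected)}

        stage = "associate"
        records = []
        moments = {}
        for cpg_id, model in selected.items():
            ref = assoc_mod.reference_moments(geno_qc, model)
            moments[cpg_id] = ref
            records.append(assoc_mod.mwas_z(model, gwas, ref,
                                            cancer=config.cancer))
        n_models = max(len(selected), 1)
        records, thr = assoc_mod.bonferroni_gate(records, n_models)
        assoc_df = assoc_mod.records_to_frame(records)
        assoc_df.to_csv(out / "associations.tsv", sep="\t", index=False)
        manifest["stages"][stage] = {
            "n_tested": len(records), "bonferroni_threshold": thr,
            "n_significant": int(assoc_df["significant"].sum())
            if len(assoc_df) else 0}

        stage = "coloc"
        resid0 = prepare_residuals(meth[tissue0])
        sample_idx = [geno_qc.samples.index(s) for s in meth[tissue0].samples]
        geno_sub = geno_qc.subset_samples(np.array(sample_idx))
        coloc_rows = []
        cpg_pos = meth[tissue0].cpg_annot.set_index("cpg_id")
        for rec in records:
            if not rec.bonferroni_significant:
                continue
            row = cpg_pos.loc[rec.cpg_id]
            cis = models.cis_variants(geno_qc, row["chrom"], int(row["pos"]),
                                      window=config.cis_window)
            mq = coloc.marginal_mqtl_stats(
                geno_sub, resid0.loc[rec.cpg_id].to_numpy(), cis)
            res = coloc.coloc_region(
                mq, gwas.table[["variant_id", "beta", "se"]],
                p1=config.coloc_p1, p2=config.coloc_p2, p12=config.coloc_p12)
            coloc_rows.append({"cpg_id": rec.cpg_id, **res.pp,
                               "n_variants": res.n_variants,
                               "tier": res.tier})
        coloc_df = pd.DataFrame(coloc_rows)
        coloc_df.to_csv(out / "coloc.tsv", sep="\t", index=False)
        manifest["stages"][stage] = {"n_pairs": len(coloc_df)}

        stage = "conditional"
        known = gwas.table[gwas.table["p"] < config.p_enter][
            ["variant_id", "chrom", "pos"]].reset_index(drop=True)
        cond_rows, novelty_rows = [], []
        for rec in records:
            if not rec.bonferroni_significant:
                continue
            row = cpg_pos.loc[rec.cpg_id]
            call = cojo.classify_novelty(rec.cpg_id, row["chrom"],
                                         int(row["pos"]), known)
            novelty_rows.append({
                "cpg_id": rec.cpg_id,
                "nearest_known_variant": call.nearest_known_variant,
                "distance_bp": call.distance_bp,
                "class": call.classification})
            if not len(known) or not np.isfinite(call.distance_bp):
                cond_rows.append({"cpg_id": rec.cpg_id,
                                  "zscore_conditional": rec.z,
                                  "pvalue_conditional": rec.p,
                                  "n_selected": 0,
                                  "significant": rec.p < thr})
                continue
            hit_pos = int(known.set_index("variant_id")
                          .loc[call.nearest_known_variant, "pos"]) \
                if call.nearest_known_variant else int(row["pos"])
            locus = np.flatnonzero(
                (geno_qc.variants["pos"].to_numpy() >= hit_pos - 1_000_000) &
                (geno_qc.variants["pos"].to_numpy() <= hit_pos + 1_000_000))
            ld = cojo.ld_matrix(geno_qc, locus)
            locus_ids = set(geno_qc.variants["variant_id"].iloc[locus])
            gl = gwas.subset(gwas.table["variant_id"].isin(locus_ids))
            sel = cojo.stepwise_select(gl, ld, p_enter=config.p_enter,
                                       r2_collinear=config.r2_collinear)
            model = selected[rec.cpg_id]
            targets = list(model.weights["variant_id"])
            ld_all = cojo.ld_matrix(
                geno_qc,
                np.flatnonzero(geno_qc.variants["variant_id"]
                               .isin(set(targets) | set(sel)).to_numpy()))
            cond = cojo.conditional_stats(targets, sel, gwas, ld_all)
            crec = cojo.conditional_mwas(model, cond, moments[rec.cpg_id],
                                         gwas, cancer=config.cancer)
            cond_rows.append({"cpg_id": rec.cpg_id,
                              "zscore_conditional": crec.z,
                              "pvalue_conditional": crec.p,
                              "n_selected": len(sel),
                              "significant": bool(np.isfinite(crec.p)
                                                  and crec.p < thr)})
        pd.DataFrame(cond_rows).to_csv(out / "conditional.tsv", sep="\t",
                                       index=False)
        pd.DataFrame(novelty_rows).to_csv(out / "novelty.tsv", sep="\t",
                                          index=False)
        manifest["stages"][stage] = {"n_pairs": len(cond_rows)}

        stage = "eqtm"
        kept_genes = eqtm.filter_genes(expr.counts, expr.tpm)
        # between-sample quantile normalization is degenerate on very few
        # features (a single row forces every column constant); skip below 10
        mraw = meth[tissue0].beta
        if len(mraw) >= 10:
            mraw = qc.quantile_normalize_samples(mraw)
        eraw = expr.expr.loc[kept_genes]
        if len(eraw) >= 10:
            eraw = qc.quantile_normalize_samples(eraw)
        mnorm = qc.inverse_normal_rows(mraw)
        enorm = qc.inverse_normal_rows(eraw)
        meth_n = dataclasses.replace(meth[tissue0], beta=mnorm,
                                     normalized=True)
        expr_n = dataclasses.replace(expr, expr=enorm)
        # hidden-factor counts follow the study defaults but are clipped on
        # small matrices, where k approaching the feature count would absorb
        # the signal itself rather than broad nuisance variation
        kf = config.eqtm_k_factors
        kf = (min(kf[0], len(mnorm) // 10),
              min(kf[1], len(enorm) // 10))
        eqtm_df = eqtm.eqtm_scan(meth_n, expr_n, window=config.cis_window,
                                 k_factors=kf)
        eqtm_df.to_csv(out / "eqtm.tsv", sep="\t", index=False)
        manifest["stages"][stage] = {
            "n_pairs": len(eqtm_df),
            "n_significant": int((eqtm_df["q"] < 0.05).sum())
            if len(eqtm_df) else 0}

        stage = "integrate"
        cohort = synthio.simulate_cohort(geno, truth, sc, n=sc.n_gwas)
        expr_cohort = synthio.cohort_expression(cohort, truth,
                                                expr.gene_annot, sc)
        evidence = gene_cancer_evidence(cohort.y, expr_cohort,
                                        cancer=config.cancer)
        trios = assemble_trios(assoc_df, eqtm_df, evidence)
        trios.to_csv(out / "trios.tsv", sep="\t", index=False)
        manifest["stages"][stage] = {
            "n_trios": len(trios),
            "n_consistent": int(trios["consistent"].sum())
            if len(trios) else 0}
    except Exception:
        manifest["failed_stage"] = stage
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                      default=str))
        raise

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  default=str))
    return {"manifest": manifest, "associations": assoc_df,
            "coloc": coloc_df, "conditional": pd.DataFrame(cond_rows),
            "novelty": pd.DataFrame(novelty_rows), "eqtm": eqtm_df,
            "trios": trios, "selected_models": selected, "truth": truth}
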
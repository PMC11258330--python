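"""Study-level evaluation routines.

Each function runs the package end to end on synthetic data at a stated
problem size and measures a statistical property of the method: agreement
of summary-statistic results with individual-level oracles, calibration
under null scenarios, power and FDR of the eQTM scan, and recovery of
planted CpG-gene-cancer trios. They are used both by the test suite and
by the reproducibility script.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import stats

from . import assoc, cojo, coloc, eqtm, models, qc, synthio
from .pipeline import RunConfig, prepare_residuals, run_pipeline
from .types import GenotypeMatrix


def _seed_offset(seed: int, k: int) -> int:
    return int((seed * 1_000_003 + k) % (2 ** 31 - 7))


def eq1_oracle(seed: int, n_cpgs: int = 100, n_cohort: int = 20_000) -> dict:
    """Correlation of the summary-statistic association Z with the
    individual-level regression Z of predicted methylation on phenotype.

    One CpG per LD block; models trained on a QC'd reference panel of 300
    donors; GWAS summary statistics computed by per-variant OLS in a
    fresh cohort of ``n_cohort`` individuals drawn from the same genotype
    model.
    """
    sc = synthio.SimScenario(
        name="mediated_trio", seed=_seed_offset(seed, 1), n_ref=300,
        n_blocks=n_cpgs, block_size=20, n_gwas=n_cohort, h2_meth=0.4)
    g0 = synthio.simulate_genotypes(sc)
    g, _ = qc.filter_variants(g0)
    meth, truth = synthio.simulate_methylation(g0, sc, n_tissues=1)
    cohort = synthio.simulate_cohort(g0, truth, sc, n=n_cohort)
    resid = prepare_residuals(meth["tissue0"])
    lookup = {v: i for i, v in enumerate(g0.variants["variant_id"])}

    z_summary, z_individual = [], []
    for _, row in meth["tissue0"].cpg_annot.iterrows():
        cis = models.cis_variants(g, row["chrom"], int(row["pos"]))
        if cis.size == 0:
            continue
        model = models.train_elastic_net(
            resid.loc[row["cpg_id"]].to_numpy(),
            qc.mean_impute(g.dosages)[:, cis],
            g.variants.iloc[cis].reset_index(drop=True),
            cpg_id=row["cpg_id"], tissue="tissue0", seed=seed)
        if model.n_snps == 0:
            continue
        ref = assoc.reference_moments(g, model)
        rec = assoc.mwas_z(model, cohort.gwas, ref)
        if rec.status != "ok":
            continue
        idx = [lookup[v] for v in model.weights["variant_id"]]
        pred = cohort.dosages[:, idx].astype(float) \
            @ model.weights["weight"].to_numpy()
        if pred.std() == 0:
            continue
        r = stats.pearsonr(pred, cohort.y)[0]
        n = len(pred)
        z_summary.append(rec.z)
        z_individual.append(r * np.sqrt((n - 2) / (1 - r * r)))
    z_summary = np.asarray(z_summary)
    z_individual = np.asarray(z_individual)
    corr = float(np.corrcoef(z_summary, z_individual)[0, 1])
    return {"correlation": corr, "n_cpgs": len(z_summary)}


def coloc_scenario_rates(seed: int, n_reps: int = 50) -> dict:
    """Colocalization behavior under the shared-causal and LD-distinct
    ground truths: fraction of replicates with PP.H4 > 0.8 (shared) and
    with PP.H3 > PP.H4 (distinct)."""
    h4_hits = 0
    h3_hits = 0
    for rep in range(n_reps):
        for name in ("shared_causal", "ld_distinct"):
            sc = synthio.SimScenario(
                name=name, seed=_seed_offset(seed, 100 + rep), n_ref=400,
                n_blocks=1, block_size=40, n_gwas=50_000, h2_meth=0.4,
                k_causal=1, alpha_med=0.15)
            g = synthio.simulate_genotypes(sc)
            meth, truth = synthio.simulate_methylation(g, sc, n_tissues=1)
            gwas = synthio.simulate_gwas(g, truth, sc)
            resid = prepare_residuals(meth["tissue0"])
            mq = coloc.marginal_mqtl_stats(g, resid.iloc[0].to_numpy())
            res = coloc.coloc_region(
                mq, gwas.table[["variant_id", "beta", "se"]])
            if name == "shared_causal":
                h4_hits += res.pp["pp_h4"] > 0.8
            else:
                h3_hits += res.pp["pp_h3"] > res.pp["pp_h4"]
    return {"shared_causal_pp_h4_rate": h4_hits / n_reps,
            "ld_distinct_h3_gt_h4_rate": h3_hits / n_reps,
            "n_reps": n_reps}


def conditional_oracle(seed: int, n_cohort: int = 20_000) -> dict:
    """Summary-statistic conditional Z against the individual-level
    regression that includes the selected genotypes as covariates.

    LD is taken from the cohort itself so the comparison isolates the
    conditional decomposition rather than reference-panel sampling noise.
    """
    sc = synthio.SimScenario(
        name="shared_causal", seed=_seed_offset(seed, 2), n_ref=400,
        n_blocks=5, block_size=50, n_gwas=n_cohort, h2_meth=0.4,
        k_causal=2, alpha_med=0.15)
    g = synthio.simulate_genotypes(sc)
    meth, truth = synthio.simulate_methylation(g, sc, n_tissues=1)
    cohort = synthio.simulate_cohort(g, truth, sc, n=n_cohort)
    cohort_panel = GenotypeMatrix(
        dosages=cohort.dosages.astype(float),
        samples=[f"i{i}" for i in range(len(cohort.y))],
        variants=g.variants)
    ld = cojo.ld_matrix(cohort_panel)
    selected = cojo.stepwise_select(cohort.gwas, ld)
    targets = [v for v in cohort.gwas.table["variant_id"]
               if v not in selected]
    cond = cojo.conditional_stats(targets, selected, cohort.gwas, ld)

    lookup = {v: i for i, v in enumerate(g.variants["variant_id"])}
    x_sel = cohort.dosages[:, [lookup[s] for s in selected]].astype(float)
    y = cohort.y
    z_summary, z_individual = [], []
    for _, row in cond.table.iterrows():
        x = cohort.dosages[:, lookup[row["variant_id"]]].astype(float)
        design = np.column_stack([np.ones(len(y)), x, x_sel])
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        resid = y - design @ coef
        sigma2 = resid @ resid / (len(y) - design.shape[1])
        cov = np.linalg.inv(design.T @ design) * sigma2
        z_summary.append(row["z"])
        z_individual.append(coef[1] / np.sqrt(cov[1, 1]))
    z_summary = np.asarray(z_summary)
    z_individual = np.asarray(z_individual)
    corr = float(np.corrcoef(z_summary, z_individual)[0, 1])
    slope = float(np.polyfit(z_individual, z_summary, 1)[0])
    return {"correlation": corr, "slope": slope,
            "n_targets": len(z_summary), "n_selected": len(selected)}


def model_recovery(seed: int, n_cpgs: int = 100) -> dict:
    """Mean cv_R of elastic-net models at h2 = 0.4, k = 3, n = 400
    (the attainable ceiling is sqrt(h2) ~ 0.632)."""
    rs = []
    for rep in range(n_cpgs):
        sc = synthio.SimScenario(
            seed=_seed_offset(seed, 200 + rep), n_ref=400, n_blocks=1,
            block_size=30, h2_meth=0.4, k_causal=3)
        g = synthio.simulate_genotypes(sc)
        meth, _ = synthio.simulate_methylation(g, sc, n_tissues=1)
        resid = prepare_residuals(meth["tissue0"])
        model = models.train_elastic_net(
            resid.iloc[0].to_numpy(), qc.mean_impute(g.dosages),
            g.variants, seed=rep)
        rs.append(model.cv_R)
    return {"mean_cv_r": float(np.mean(rs)), "n_cpgs": n_cpgs}


def null_calibration(seed: int, n_cpgs: int = 500) -> dict:
    """Reliability-gate calibration on pure-noise methylation."""
    sig = reliable = 0
    for rep in range(n_cpgs):
        rng = np.random.default_rng(_seed_offset(seed, 400 + rep))
        sc = synthio.SimScenario(
            seed=_seed_offset(seed, 300 + rep), n_ref=200, n_blocks=1,
            block_size=20, h2_meth=0.0)
        g = synthio.simulate_genotypes(sc)
        y = rng.standard_normal(sc.n_ref)
        model = models.train_elastic_net(
            y, qc.mean_impute(g.dosages), g.variants, seed=rep)
        sig += model.cv_P < 0.05
        reliable += model.reliable
    return {"cv_p_rate": sig / n_cpgs, "reliable_rate": reliable / n_cpgs,
            "n_cpgs": n_cpgs}


def cross_tissue_gain(seed: int, n_reps: int = 50,
                      n_tissues: int = 4) -> dict:
    """Paired comparison of cross-tissue vs single-tissue cv_R on
    shared-causal simulations with small per-tissue n (50)."""
    diffs = []
    for rep in range(n_reps):
        sc = synthio.SimScenario(
            name="shared_causal", seed=_seed_offset(seed, 500 + rep),
            n_ref=300, n_blocks=1, block_size=16, h2_meth=0.3,
            k_causal=2, share_frac=1.0)
        g = synthio.simulate_genotypes(sc)
        meth, _ = synthio.simulate_methylation(
            g, sc, n_tissues=n_tissues, n_per_tissue=50)
        x_full = qc.mean_impute(g.dosages)
        ybt, xbt = {}, {}
        for t, m in meth.items():
            resid = prepare_residuals(m)
            si = [g.samples.index(s) for s in m.samples]
            ybt[t] = resid.iloc[0].to_numpy()
            xbt[t] = x_full[si]
        ct = models.train_cross_tissue(ybt, xbt, g.variants, seed=rep)
        for t in ybt:
            st = models.train_elastic_net(ybt[t], xbt[t], g.variants,
                                          seed=rep)
            diffs.append(ct[t].cv_R - st.cv_R)
    diffs = np.asarray(diffs)
    tstat, p_two = stats.ttest_rel(diffs, np.zeros_like(diffs))
    p_one = p_two / 2 if diffs.mean() > 0 else 1 - p_two / 2
    return {"mean_gain": float(diffs.mean()), "p_one_sided": float(p_one),
            "n_pairs": len(diffs)}


def eqtm_power(seed: int, n_reps: int = 50, n_samples: int = 150) -> dict:
    """Detection rate of a single planted CpG-gene link (generative
    correlation 0.6) at q < 0.05 among 20 decoy genes, and the sign
    agreement of detected links with the generative direction."""
    detected = 0
    signs_ok = signs_total = 0
    for rep in range(n_reps):
        cfg_sc = synthio.SimScenario(
            name="mediated_trio", seed=_seed_offset(seed, 600 + rep),
            n_ref=n_samples, n_blocks=1, block_size=20, h2_meth=0.4,
            gamma_eqtm=0.75)
        g = synthio.simulate_genotypes(cfg_sc)
        meth, truth = synthio.simulate_methylation(g, cfg_sc, n_tissues=1)
        expr = synthio.simulate_expression(meth["tissue0"], truth,
                                           n_decoys_per_cpg=20)
        mnorm = qc.inverse_normal_rows(meth["tissue0"].beta)
        enorm = qc.inverse_normal_rows(expr.expr)
        import dataclasses as dc
        meth_n = dc.replace(meth["tissue0"], beta=mnorm, normalized=True)
        expr_n = dc.replace(expr, expr=enorm)
        res = eqtm.eqtm_scan(meth_n, expr_n, k_factors=(0, 2))
        hits = res[res["q"] < 0.05]
        planted = truth.eqtm.iloc[0]
        hit = hits[(hits["cpg_id"] == planted["cpg_id"]) &
                   (hits["gene_id"] == planted["gene_id"])]
        detected += len(hit) > 0
        for _, h in hits.iterrows():
            link = truth.eqtm[(truth.eqtm["cpg_id"] == h["cpg_id"]) &
                              (truth.eqtm["gene_id"] == h["gene_id"])]
            if len(link):
                signs_total += 1
                signs_ok += np.sign(h["beta"]) == np.sign(
                    link["gamma"].iloc[0])
    return {"power": detected / n_reps,
            "sign_agreement": signs_ok / max(signs_total, 1),
            "n_reps": n_reps}


def eqtm_fdr(seed: int, n_reps: int = 10) -> dict:
    """Empirical FDR of q < 0.05 calls in a mixed simulation where 20%
    of cis pairs carry a true link."""
    false = true = 0
    for rep in range(n_reps):
        sc = synthio.SimScenario(
            name="mediated_trio", seed=_seed_offset(seed, 700 + rep),
            n_ref=200, n_blocks=10, block_size=15, h2_meth=0.4,
            gamma_eqtm=0.75)
        g = synthio.simulate_genotypes(sc)
        meth, truth = synthio.simulate_methylation(g, sc, n_tissues=1)
        expr = synthio.simulate_expression(meth["tissue0"], truth,
                                           n_decoys_per_cpg=4)
        mnorm = qc.inverse_normal_rows(meth["tissue0"].beta)
        enorm = qc.inverse_normal_rows(expr.expr)
        import dataclasses as dc
        meth_n = dc.replace(meth["tissue0"], beta=mnorm, normalized=True)
        expr_n = dc.replace(expr, expr=enorm)
        res = eqtm.eqtm_scan(meth_n, expr_n, k_factors=(1, 3))
        hits = res[res["q"] < 0.05]
        linked = set(zip(truth.eqtm["cpg_id"], truth.eqtm["gene_id"]))
        for _, h in hits.iterrows():
            if (h["cpg_id"], h["gene_id"]) in linked:
                true += 1
            else:
                false += 1
    total = true + false
    return {"empirical_fdr": false / max(total, 1), "n_calls": total,
            "n_reps": n_reps}


def trio_recovery(seed: int, n_reps: int = 50) -> dict:
    """End-to-end recovery of the planted trio (with 20 decoy genes) and
    absence of false trios, via the full pipeline."""
    recovered = clean = 0
    for rep in range(n_reps):
        cfg = RunConfig(
            out_dir=f"scratch/eval_trio_{rep}",
            seed=_seed_offset(seed, 800 + rep), scenario="mediated_trio",
            n_blocks=1, block_size=25, n_ref=300, n_gwas=50_000,
            n_decoys_per_cpg=20)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = run_pipeline(cfg)
        truth = res["truth"].eqtm
        planted = set(zip(truth["cpg_id"], truth["gene_id"]))
        trios = res["trios"]
        got = set(zip(trios.loc[trios["consistent"], "cpg_id"],
                      trios.loc[trios["consistent"], "gene_id"]))
        recovered += planted <= got
        clean += len(got - planted) == 0
    return {"recovery_rate": recovered / n_reps,
            "no_false_trio_rate": clean / n_reps, "n_reps": n_reps}


def null_pipeline(seed: int, n_reps: int = 20) -> dict:
    """Fraction of null-scenario pipeline runs with zero significant
    CpG-cancer associations."""
    zero = 0
    for rep in range(n_reps):
        cfg = RunConfig(
            out_dir=f"scratch/eval_null_{rep}",
            seed=_seed_offset(seed, 900 + rep), scenario="null",
            n_blocks=6, block_size=20, n_ref=300, n_gwas=20_000)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = run_pipeline(cfg)
        zero += res["manifest"]["stages"]["associate"]["n_significant"] == 0
    return {"zero_hit_rate": zero / n_reps, "n_reps": n_reps}
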
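"""Readers and writers for the pipeline's file formats.

Formats: VCF v4.2 (DS dosage FORMAT field preferred, GT fallback) for
genotype panels, TSV matrices (rows = features, columns = samples), GWAS
summary TSV with case-insensitive header aliases, PredictDB-style model
store TSVs, and a flat key:value config file. Chromosome names are
normalized by stripping any "chr" prefix on read; all positions are
1-based.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .types import GenotypeMatrix, GwasSummary, PredictionModel

logger = logging.getLogger(__name__)

GWAS_ALIASES = {
    "variant_id": {"variant_id", "variant", "id", "snp", "rsid", "marker"},
    "chrom": {"chrom", "chr", "chromosome"},
    "pos": {"pos", "position", "bp", "base_pair_location"},
    "effect_allele": {"effect_allele", "a1", "ea", "allele1", "alt"},
    "other_allele": {"other_allele", "a2", "oa", "allele2", "ref",
                     "non_effect_allele"},
    "freq": {"freq", "af", "eaf", "frq", "effect_allele_frequency", "maf"},
    "beta": {"beta", "b", "effect", "effect_size"},
    "se": {"se", "stderr", "standard_error", "sebeta"},
    "p": {"p", "pval", "pvalue", "p_value"},
    "n": {"n", "samplesize", "sample_size", "neff"},
}


# ---------------------------------------------------------------------------
# VCF


def read_vcf_dosages(path: str | Path) -> GenotypeMatrix:
    """Read a VCF into a dosage panel (DS field preferred, GT fallback).

    Multi-allelic records and records without usable genotype data are
    skipped with a log message; an all-skipped file is an error.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, meta = [], []
    n_skipped = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_skipped += 1
            continue
        ds = None
        try:
            arr = var.format("DS")
            if arr is not None:
                ds = np.asarray(arr, dtype=float).reshape(len(samples))
        except Exception:
            ds = None
        if ds is None:
            gts = np.asarray(var.genotypes, dtype=object)
            ds = np.empty(len(samples))
            for i, g in enumerate(gts):
                a, b = g[0], g[1]
                ds[i] = np.nan if (a < 0 or b < 0) else float(a + b)
        if not np.any(np.isfinite(ds)):
            n_skipped += 1
            continue
        ds = np.where(np.isfinite(ds), ds, np.nan)
        rows.append(ds)
        meta.append({
            "variant_id": var.ID or f"{var.CHROM}:{var.POS}",
            "chrom": str(var.CHROM).removeprefix("chr"),
            "pos": var.POS,
            "effect_allele": var.ALT[0],
            "other_allele": var.REF,
        })
    if n_skipped:
        logger.info("skipped %d VCF records", n_skipped)
    if not rows:
        raise ValueError(f"no usable variant records in {path}")
    return GenotypeMatrix(dosages=np.asarray(rows).T, samples=samples,
                          variants=pd.DataFrame(meta))


def write_vcf_dosages(geno: GenotypeMatrix, path: str | Path) -> None:
    """Write the panel as a minimal VCF v4.2 with a DS FORMAT field."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,'
                 'Description="Estimated alternate allele dosage">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(geno.samples) + "\n")
        v = geno.variants
        for j in range(geno.n_variants):
            vals = geno.dosages[:, j]
            fields = [
                str(v["chrom"].iloc[j]), str(int(v["pos"].iloc[j])),
                str(v["variant_id"].iloc[j]),
                str(v["other_allele"].iloc[j]), str(v["effect_allele"].iloc[j]),
                ".", "PASS", ".", "DS",
            ] + ["." if not np.isfinite(x) else f"{x:g}" for x in vals]
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# TSV matrices and dosage tables


def write_dosage_tsv(geno: GenotypeMatrix, path: str | Path) -> None:
    meta = geno.variants[["variant_id", "chrom", "pos", "effect_allele",
                          "other_allele"]].copy()
    dos = pd.DataFrame(geno.dosages.T, columns=geno.samples)
    pd.concat([meta.reset_index(drop=True), dos], axis=1) \
        .to_csv(path, sep="\t", index=False)


def read_dosage_tsv(path: str | Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t")
    meta_cols = ["variant_id", "chrom", "pos", "effect_allele", "other_allele"]
    samples = [c for c in df.columns if c not in meta_cols]
    variants = df[meta_cols].copy()
    variants["chrom"] = variants["chrom"].astype(str).str.removeprefix("chr")
    return GenotypeMatrix(dosages=df[samples].to_numpy(dtype=float).T,
                          samples=samples, variants=variants)


def write_matrix_tsv(mat: pd.DataFrame, path: str | Path,
                     index_label: str = "feature_id") -> None:
    mat.to_csv(path, sep="\t", index_label=index_label)


def read_matrix_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


# ---------------------------------------------------------------------------
# GWAS summary


def read_gwas(path: str | Path) -> GwasSummary:
    """Read a GWAS summary TSV, resolving case-insensitive header aliases.

    Rows with se <= 0 or p outside (0, 1] are dropped with a logged count.
    """
    df = pd.read_csv(path, sep="\t")
    rename = {}
    lower = {c.lower(): c for c in df.columns}
    for canonical, aliases in GWAS_ALIASES.items():
        for alias in aliases:
            if alias in lower:
                rename[lower[alias]] = canonical
                break
    df = df.rename(columns=rename)
    missing = [c for c in GWAS_ALIASES if c not in df.columns]
    if missing:
        raise ValueError(f"GWAS file missing columns: {missing}")
    df["chrom"] = df["chrom"].astype(str).str.removeprefix("chr")
    for c in ("freq", "beta", "se", "p", "n", "pos"):
        df[c] = pd.to_numeric(df[c], errors="coerce")
    ok = (df["se"] > 0) & (df["p"] > 0) & (df["p"] <= 1) & \
        df["beta"].notna() & df["se"].notna()
    n_bad = int((~ok).sum())
    if n_bad:
        logger.info("dropped %d invalid GWAS rows", n_bad)
    return GwasSummary(df.loc[ok].reset_index(drop=True))


def write_gwas(gwas: GwasSummary, path: str | Path) -> None:
    gwas.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# model store (PredictDB-like: weights + extra per tissue)


def write_model_store(models: list[PredictionModel], out_dir: str | Path,
                      tissue: str) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    wrows, erows = [], []
    for m in models:
        for _, r in m.weights.iterrows():
            wrows.append({"cpg_id": m.cpg_id, "variant_id": r["variant_id"],
                          "effect_allele": r["effect_allele"],
                          "other_allele": r["other_allele"],
                          "weight": r["weight"]})
        erows.append({"cpg_id": m.cpg_id, "method": m.method,
                      "cv_R": m.cv_R, "cv_P": m.cv_P, "n_snps": m.n_snps,
                      "n_train": m.n_train})
    pd.DataFrame(wrows, columns=["cpg_id", "variant_id", "effect_allele",
                                 "other_allele", "weight"]) \
        .to_csv(out_dir / f"{tissue}.weights.tsv", sep="\t", index=False)
    pd.DataFrame(erows, columns=["cpg_id", "method", "cv_R", "cv_P",
                                 "n_snps", "n_train"]) \
        .to_csv(out_dir / f"{tissue}.extra.tsv", sep="\t", index=False)


def read_model_store(store_dir: str | Path,
                     tissue: str) -> list[PredictionModel]:
    store_dir = Path(store_dir)
    weights = pd.read_csv(store_dir / f"{tissue}.weights.tsv", sep="\t")
    extra = pd.read_csv(store_dir / f"{tissue}.extra.tsv", sep="\t")
    models = []
    for _, e in extra.iterrows():
        w = weights[weights["cpg_id"] == e["cpg_id"]]
        models.append(PredictionModel(
            cpg_id=e["cpg_id"], tissue=tissue, method=e["method"],
            weights=w[["variant_id", "effect_allele", "other_allele",
                       "weight"]].reset_index(drop=True),
            cv_R=float(e["cv_R"]), cv_P=float(e["cv_P"]),
            n_train=int(e["n_train"])))
    return models


# ---------------------------------------------------------------------------
# config


def write_config(config: dict, path: str | Path) -> None:
    """Write a flat key:value config file (YAML-compatible)."""
    with Path(path).open("w") as fh:
        yaml.safe_dump(config, fh, default_flow_style=False, sort_keys=True)


def read_config(path: str | Path) -> dict:
    with Path(path).open() as fh:
        return yaml.safe_load(fh)
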
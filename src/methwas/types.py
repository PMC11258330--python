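"""Shared in-memory containers for the methylome-wide association pipeline.

Conventions
-----------
* Genotypes are stored as effect-allele dosages in [0, 2]; ``np.nan`` marks
  missing calls. Positions are 1-based and strictly increasing within a
  chromosome.
* Methylation and expression matrices are feature x sample DataFrames.
* GWAS summary statistics are per-variant effect-allele log-odds with
  standard errors; a ``GwasSummary`` is a validated DataFrame wrapper.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

GWAS_COLUMNS = [
    "variant_id", "chrom", "pos", "effect_allele", "other_allele",
    "freq", "beta", "se", "p", "n",
]

PALINDROMIC_PAIRS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


@dataclass
class GenotypeMatrix:
    """Sample x variant dosage panel with variant annotation.

    Attributes
    ----------
    dosages : (n_samples, n_variants) float array, values in [0, 2] or NaN.
    samples : sample identifiers, length n_samples.
    variants : DataFrame with columns variant_id, chrom, pos,
        effect_allele, other_allele; row order matches dosage columns.
    """

    dosages: np.ndarray
    samples: list[str]
    variants: pd.DataFrame

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (samples x variants)")
        if self.dosages.shape[0] != len(self.samples):
            raise ValueError("sample count mismatch")
        if self.dosages.shape[1] != len(self.variants):
            raise ValueError("variant count mismatch")
        self.variants = self.variants.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    @property
    def variant_ids(self) -> np.ndarray:
        return self.variants["variant_id"].to_numpy()

    def effect_allele_freq(self) -> np.ndarray:
        """Effect-allele frequency ignoring missing calls."""
        return np.nanmean(self.dosages, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        """Minor-allele frequency (folded effect-allele frequency)."""
        f = self.effect_allele_freq()
        return np.minimum(f, 1.0 - f)

    def missing_rate(self) -> np.ndarray:
        return np.mean(np.isnan(self.dosages), axis=0)

    def sd(self, ddof: int = 1) -> np.ndarray:
        return np.nanstd(self.dosages, axis=0, ddof=ddof)

    def subset_variants(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            dosages=self.dosages[:, idx],
            samples=list(self.samples),
            variants=self.variants.iloc[idx].reset_index(drop=True),
        )

    def subset_samples(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            dosages=self.dosages[idx, :],
            samples=[self.samples[i] for i in idx],
            variants=self.variants.copy(),
        )

    def is_palindromic(self) -> np.ndarray:
        pairs = zip(self.variants["effect_allele"], self.variants["other_allele"])
        return np.array([(a, b) in PALINDROMIC_PAIRS for a, b in pairs])


@dataclass
class MethylationMatrix:
    """CpG x sample beta-value matrix for one tissue, with covariates."""

    beta: pd.DataFrame            # CpG x sample, values in [0, 1]
    tissue: str
    cpg_annot: pd.DataFrame       # cpg_id, chrom, pos (1-based)
    covariates: pd.DataFrame      # sample x covariate
    normalized: bool = False      # True once values are transformed

    def __post_init__(self) -> None:
        vals = self.beta.to_numpy(dtype=float)
        finite = vals[np.isfinite(vals)]
        if not self.normalized and finite.size and \
                (finite.min() < 0 or finite.max() > 1):
            raise ValueError("methylation beta values must lie in [0, 1]")
        missing = set(self.beta.columns) - set(self.covariates.index)
        if missing:
            raise ValueError(f"samples without covariates: {sorted(missing)[:5]}")

    @property
    def samples(self) -> list[str]:
        return list(self.beta.columns)

    @property
    def cpg_ids(self) -> list[str]:
        return list(self.beta.index)


@dataclass
class ExpressionMatrix:
    """Gene x sample expression for one tissue (normalized, counts, TPM)."""

    expr: pd.DataFrame       # gene x sample, continuous values
    counts: pd.DataFrame     # gene x sample, read counts
    tpm: pd.DataFrame        # gene x sample, TPM-like values
    gene_annot: pd.DataFrame  # gene_id, chrom, tss (1-based)
    tissue: str = ""

    @property
    def samples(self) -> list[str]:
        return list(self.expr.columns)


class GwasSummary:
    """Per-variant GWAS summary statistics for one cancer.

    Thin validated wrapper around a DataFrame with columns
    variant_id, chrom, pos, effect_allele, other_allele, freq, beta, se, p, n.
    """

    def __init__(self, table: pd.DataFrame):
        missing = [c for c in GWAS_COLUMNS if c not in table.columns]
        if missing:
            raise ValueError(f"GWAS table missing columns: {missing}")
        table = table.reset_index(drop=True)
        if (table["se"] <= 0).any():
            raise ValueError("GWAS se must be positive")
        self.table = table

    def __len__(self) -> int:
        return len(self.table)

    @property
    def z(self) -> np.ndarray:
        return (self.table["beta"] / self.table["se"]).to_numpy()

    def subset(self, mask) -> "GwasSummary":
        return GwasSummary(self.table.loc[mask].reset_index(drop=True))


@dataclass
class PredictionModel:
    """A cis-genetic prediction model for one CpG in one tissue.

    ``weights`` carries one row per retained variant with columns
    variant_id, effect_allele, other_allele, weight (dosage scale).
    ``cv_R`` / ``cv_P`` are the correlation of pooled out-of-fold
    predictions with the observed residuals and its two-sided p-value.
    """

    cpg_id: str
    tissue: str
    method: str                       # elastic_net | cross_tissue | best_mqtl
    weights: pd.DataFrame
    cv_R: float
    cv_P: float
    n_train: int

    def __post_init__(self) -> None:
        if self.method not in {"elastic_net", "cross_tissue", "best_mqtl"}:
            raise ValueError(f"unknown method {self.method!r}")

    @property
    def reliable(self) -> bool:
        return bool(self.cv_R > 0.10 and self.cv_P < 0.05)

    @property
    def n_snps(self) -> int:
        return len(self.weights)


@dataclass
class ReferenceMoments:
    """Reference-panel moments entering the summary association statistic.

    sigma_s: per-variant dosage standard deviation;
    sigma_m: standard deviation of the model-predicted methylation
    (LD-aware: computed from X @ W over reference samples).
    """

    sigma_s: pd.Series      # indexed by variant_id
    sigma_m: float
    ld: pd.DataFrame | None = None   # cis correlation matrix (optional)


@dataclass
class AssociationRecord:
    """One CpG-cancer association from the summary-statistic test."""

    cpg_id: str
    cancer: str
    z: float
    p: float
    or_per_sd: float
    ci_low: float
    ci_high: float
    n_model_variants_used: int
    n_model_variants: int
    status: str = "ok"                # ok | untestable
    bonferroni_significant: bool = False

    def to_dict(self) -> dict:
        return {
            "cpg_id": self.cpg_id, "cancer": self.cancer, "zscore": self.z,
            "pvalue": self.p, "or_per_sd": self.or_per_sd,
            "ci_low": self.ci_low, "ci_high": self.ci_high,
            "n_snps_used": self.n_model_variants_used,
            "n_snps_in_model": self.n_model_variants,
            "status": self.status,
            "significant": self.bonferroni_significant,
        }


@dataclass
class TruthLedger:
    """Ground truth recorded by the synthetic generator.

    causal : DataFrame (cpg_id, tissue, variant_id, effect) — per-tissue
        causal cis effects on the methylation latent scale.
    mediation : per-CpG methylation -> liability effect (0 under null).
    eqtm : DataFrame (cpg_id, gene_id, gamma) — methylation -> expression.
    gwas_direct : DataFrame (variant_id, effect) — direct liability effects
        (used by the ld_distinct scenario).
    """

    causal: pd.DataFrame
    mediation: dict[str, float]
    eqtm: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["cpg_id", "gene_id", "gamma"]))
    gwas_direct: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["variant_id", "effect"]))
    scenario: object | None = None
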
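"""Synthetic data generator for the methylome-wide association pipeline.

Generates LD-block genotype panels, multi-tissue methylation with
tissue-shared and tissue-specific cis-genetic effects, case-control style
GWAS summary statistics, and methylation-driven gene expression, under
named scenarios whose ground truth is recorded in a :class:`TruthLedger`.

Scenarios
---------
shared_causal
    The same cis variant drives both CpG methylation and disease liability
    (methylation mediates the genetic effect).
ld_distinct
    Two distinct variants in LD (|r| >= 0.7) drive methylation and disease;
    the CpG itself has no causal effect on disease.
null
    Methylation has cis-genetic effects but no variant affects disease.
mediated_trio
    shared_causal plus a downstream methylation -> expression link, so a
    full variant -> CpG -> gene -> disease chain exists.

Randomness: one scenario seed expands into per-component child streams via
``numpy.random.SeedSequence(seed, spawn_key=(k,))`` with fixed component
keys (0 genotypes, 1 methylation, 2 GWAS, 3 expression, 4 cohort), so a
fixed scenario yields byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy import stats

from .types import (
    ExpressionMatrix,
    GenotypeMatrix,
    GwasSummary,
    MethylationMatrix,
    TruthLedger,
)

SCENARIO_NAMES = ("shared_causal", "ld_distinct", "null", "mediated_trio")

# spawn keys of the per-component child random streams
_KEY_GENO, _KEY_METH, _KEY_GWAS, _KEY_EXPR, _KEY_COHORT = 0, 1, 2, 3, 4

_BLOCK_SPACING = 2_000_000   # bp between LD-block start positions
_BLOCK_START = 10_000


@dataclass(frozen=True)
class SimScenario:
    """Parameters of one synthetic study.

    Defaults emulate a modest reference panel (hundreds of donors, common
    variants, moderately heritable CpGs) with a large-N GWAS.
    """

    name: str = "shared_causal"
    n_ref: int = 400            # reference-panel sample count
    n_gwas: int = 50_000        # effective GWAS sample count
    n_blocks: int = 10          # LD block count (one CpG per block)
    block_size: int = 30        # variants per block
    rho: float = 0.9            # within-block adjacent latent correlation
    maf_range: tuple[float, float] = (0.05, 0.5)
    h2_meth: float = 0.4        # cis-heritability of the methylation latent
    k_causal: int = 3           # causal variants per CpG
    share_frac: float = 0.5     # fraction of causal effects shared across tissues
    alpha_med: float = 0.1      # methylation -> liability effect
    gamma_eqtm: float = 0.75    # methylation -> expression effect (corr 0.6)
    seed: int = 0
    palindromic_frac: float = 0.1
    missing_rate: float = 0.0

    def __post_init__(self):
        if self.name not in SCENARIO_NAMES:
            raise ValueError(f"unknown scenario {self.name!r}")
        if not (0 <= self.rho < 1):
            raise ValueError("rho must lie in [0, 1)")
        if not (0 <= self.h2_meth < 1):
            raise ValueError("h2_meth must lie in [0, 1)")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if self.n_ref <= 0 or self.n_blocks <= 0 or self.block_size <= 0:
            raise ValueError("dimensions must be positive")
        if self.n_gwas <= 0:
            raise ValueError("n_gwas must be positive")

    def with_(self, **kw) -> "SimScenario":
        return replace(self, **kw)

    def child_rng(self, key: int) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence(self.seed, spawn_key=(key,)))


@dataclass
class Cohort:
    """Individual-level GWAS cohort drawn from the same genotype model.

    Dosages are stored as int8 to keep large cohorts cheap; ``y`` is the
    continuous liability phenotype; ``gwas`` holds per-variant OLS summary
    statistics computed from this cohort.
    """

    dosages: np.ndarray          # (n, n_variants) int8
    variants: pd.DataFrame
    y: np.ndarray
    gwas: GwasSummary


# ---------------------------------------------------------------------------
# genotypes


def _latent_ar1(rng: np.random.Generator, n: int, m: int, rho: float) -> np.ndarray:
    """n x m latent Gaussian with corr(z_i, z_j) = rho^|i-j|."""
    z = np.empty((n, m))
    z[:, 0] = rng.standard_normal(n)
    if m > 1:
        eps = rng.standard_normal((n, m - 1)) * np.sqrt(1.0 - rho * rho)
        for j in range(1, m):
            z[:, j] = rho * z[:, j - 1] + eps[:, j - 1]
    return z


def _discretize(z: np.ndarray, freq: np.ndarray) -> np.ndarray:
    """Threshold latent normals into {0,1,2} dosages at HWE genotype freqs."""
    q = 1.0 - freq
    c0 = stats.norm.ppf(q * q)                    # below: homozygous other
    c1 = stats.norm.ppf(q * q + 2 * freq * q)     # between: heterozygous
    return (z >= c0).astype(np.int8) + (z >= c1).astype(np.int8)


def _draw_alleles(rng: np.random.Generator, m: int, palindromic_frac: float):
    bases = np.array(list("ACGT"))
    pal = rng.random(m) < palindromic_frac
    ea = np.empty(m, dtype="<U1")
    oa = np.empty(m, dtype="<U1")
    comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
    for i in range(m):
        a = bases[rng.integers(4)]
        if pal[i]:
            ea[i], oa[i] = a, comp[a]
        else:
            choices = [b for b in bases if b != a and b != comp[a]]
            ea[i], oa[i] = a, choices[rng.integers(2)]
    return ea, oa


def simulate_genotypes(scenario: SimScenario) -> GenotypeMatrix:
    """Generate the reference dosage panel.

    Dosages come from a thresholded latent Gaussian with within-block
    AR(1) correlation ``rho^|i-j|`` and HWE genotype frequencies at the
    drawn effect-allele frequencies. Positions are 1-based, strictly
    increasing, with blocks far enough apart that cis windows never span
    two blocks. The simulated effect-allele frequency is stored in the
    variant table (column ``freq``) so cohorts can be redrawn from the
    identical model.
    """
    sc = scenario
    rng = sc.child_rng(_KEY_GENO)
    m_total = sc.n_blocks * sc.block_size
    freq = rng.uniform(sc.maf_range[0], sc.maf_range[1], size=m_total)

    dosages = np.empty((sc.n_ref, m_total), dtype=float)
    pos = np.empty(m_total, dtype=int)
    for b in range(sc.n_blocks):
        sl = slice(b * sc.block_size, (b + 1) * sc.block_size)
        z = _latent_ar1(rng, sc.n_ref, sc.block_size, sc.rho)
        dosages[:, sl] = _discretize(z, freq[sl])
        start = _BLOCK_START + b * _BLOCK_SPACING
        steps = rng.integers(500, 2500, size=sc.block_size)
        pos[sl] = start + np.cumsum(steps)

    ea, oa = _draw_alleles(rng, m_total, sc.palindromic_frac)
    if sc.missing_rate > 0:
        mask = rng.random(dosages.shape) < sc.missing_rate
        dosages[mask] = np.nan

    variants = pd.DataFrame({
        "variant_id": [f"var{i:05d}" for i in range(m_total)],
        "chrom": "1",
        "pos": pos,
        "effect_allele": ea,
        "other_allele": oa,
        "freq": freq,
        "block": np.repeat(np.arange(sc.n_blocks), sc.block_size),
    })
    samples = [f"ref{i:04d}" for i in range(sc.n_ref)]
    return GenotypeMatrix(dosages=dosages, samples=samples, variants=variants)


# ---------------------------------------------------------------------------
# methylation


def _cpg_positions(geno: GenotypeMatrix, n_blocks: int) -> pd.DataFrame:
    rows = []
    for b in range(n_blocks):
        sub = geno.variants[geno.variants["block"] == b]
        center = int(sub["pos"].to_numpy().mean())
        rows.append({"cpg_id": f"cg{b:06d}", "chrom": "1", "pos": center,
                     "block": b})
    return pd.DataFrame(rows)


def simulate_methylation(
    geno: GenotypeMatrix,
    scenario: SimScenario,
    n_tissues: int = 2,
    n_per_tissue: int | None = None,
) -> tuple[dict[str, MethylationMatrix], TruthLedger]:
    """Generate per-tissue methylation beta values plus the truth ledger.

    Per tissue, the latent trait is causal-dosage effects + covariate
    effects + noise, scaled so the cis-genetic fraction of latent variance
    equals ``h2_meth`` (covariates absorb 10% of the residual variance).
    Beta values are the inverse-logit of the latent shifted by a per-CpG
    baseline. A ``share_frac`` fraction of each CpG's causal effects is
    identical across tissues; the rest are redrawn per tissue.
    """
    sc = scenario
    if geno.n_variants == 0 or geno.n_samples == 0:
        raise ValueError("genotype panel is empty")
    rng = sc.child_rng(_KEY_METH)
    cpgs = _cpg_positions(geno, sc.n_blocks)
    dos = np.nan_to_num(geno.dosages, nan=np.nanmean(geno.dosages))

    n_shared = int(round(sc.share_frac * sc.k_causal))
    tissues = [f"tissue{t}" for t in range(n_tissues)]

    # per-tissue sample subsets (full panel unless n_per_tissue given)
    subsets = {}
    for t in tissues:
        if n_per_tissue is None or n_per_tissue >= geno.n_samples:
            subsets[t] = np.arange(geno.n_samples)
        else:
            subsets[t] = np.sort(rng.choice(geno.n_samples, n_per_tissue,
                                            replace=False))

    causal_rows = []
    mediation: dict[str, float] = {}
    latents = {t: np.empty((len(cpgs), len(subsets[t]))) for t in tissues}
    betas = {t: np.empty_like(latents[t]) for t in tissues}

    mediated = sc.name in ("shared_causal", "mediated_trio")
    c_var = 0.1 * (1.0 - sc.h2_meth)   # covariate share of latent variance
    noise_var = max(1.0 - sc.h2_meth - c_var, 1e-12)

    # covariates per tissue (shared columns: sex, platform, batch)
    cov_tables = {}
    for t in tissues:
        ns = len(subsets[t])
        cov = pd.DataFrame({
            "sex": rng.integers(0, 2, ns).astype(float),
            "platform": rng.integers(0, 2, ns).astype(float),
            "batch": rng.integers(0, 3, ns).astype(float),
        }, index=[geno.samples[i] for i in subsets[t]])
        cov_tables[t] = cov

    for ci, row in cpgs.iterrows():
        block_idx = np.flatnonzero(
            geno.variants["block"].to_numpy() == row["block"])
        k = min(sc.k_causal, len(block_idx))
        causal_idx = rng.choice(block_idx, size=k, replace=False)
        raw_shared = rng.standard_normal(k)
        m0 = rng.uniform(0.2, 0.8)
        for t in tissues:
            raw = raw_shared.copy()
            if n_shared < k:
                raw[n_shared:] = rng.standard_normal(k - n_shared)
            g_full = dos[:, causal_idx] @ raw
            v = g_full.var()
            if sc.h2_meth > 0 and v > 0:
                b = raw * np.sqrt(sc.h2_meth / v)
            else:
                b = np.zeros(k)
            idx = subsets[t]
            genetic = dos[np.ix_(idx, causal_idx)] @ b
            cov = cov_tables[t]
            cstd = (cov - cov.mean()) / cov.std(ddof=0).replace(0, 1.0)
            ccoef = rng.standard_normal(cov.shape[1])
            ccoef *= np.sqrt(c_var / max(cov.shape[1], 1))
            cov_comp = cstd.to_numpy() @ ccoef
            noise = rng.standard_normal(len(idx)) * np.sqrt(noise_var)
            latent = genetic + cov_comp + noise
            latents[t][ci] = latent
            betas[t][ci] = expit(logit(m0) + latent)
            for vi, eff in zip(causal_idx, b):
                causal_rows.append({
                    "cpg_id": row["cpg_id"], "tissue": t,
                    "variant_id": geno.variants["variant_id"].iloc[vi],
                    "variant_index": int(vi), "effect": eff,
                })
        mediation[row["cpg_id"]] = sc.alpha_med if mediated else 0.0

    out = {}
    for t in tissues:
        sample_names = [geno.samples[i] for i in subsets[t]]
        beta_df = pd.DataFrame(betas[t], index=cpgs["cpg_id"],
                               columns=sample_names)
        out[t] = MethylationMatrix(
            beta=beta_df, tissue=t,
            cpg_annot=cpgs[["cpg_id", "chrom", "pos"]].copy(),
            covariates=cov_tables[t],
        )

    truth = TruthLedger(
        causal=pd.DataFrame(causal_rows),
        mediation=mediation,
        scenario=sc,
    )
    return out, truth


# ---------------------------------------------------------------------------
# GWAS summary statistics


def _direct_effects(geno: GenotypeMatrix, truth: TruthLedger,
                    sc: SimScenario, rng: np.random.Generator) -> np.ndarray:
    """Per-variant direct liability effects implied by the scenario."""
    m = geno.n_variants
    d = np.zeros(m)
    causal = truth.causal
    if causal.empty:
        return d
    t0 = causal["tissue"].iloc[0]
    c0 = causal[causal["tissue"] == t0]
    if sc.name in ("shared_causal", "mediated_trio"):
        for cpg_id, grp in c0.groupby("cpg_id"):
            alpha = truth.mediation.get(cpg_id, 0.0)
            d[grp["variant_index"].to_numpy()] += alpha * grp["effect"].to_numpy()
    elif sc.name == "ld_distinct":
        if len(truth.gwas_direct):
            prev = truth.gwas_direct
            d[prev["variant_index"].to_numpy()] += prev["effect"].to_numpy()
            return d
        dos = np.nan_to_num(geno.dosages, nan=np.nanmean(geno.dosages))
        blocks = geno.variants["block"].to_numpy()
        rows = []
        for cpg_id, grp in c0.groupby("cpg_id"):
            top = grp.iloc[grp["effect"].abs().argmax()]
            vi = int(top["variant_index"])
            block_idx = np.flatnonzero(blocks == blocks[vi])
            x = dos[:, vi]
            r = np.array([
                np.corrcoef(x, dos[:, j])[0, 1] if j != vi else 1.0
                for j in block_idx])
            cand = block_idx[(np.abs(r) >= 0.7)
                             & ~np.isin(block_idx,
                                        grp["variant_index"].to_numpy())]
            if len(cand) == 0:
                others = block_idx[~np.isin(
                    block_idx, grp["variant_index"].to_numpy())]
                if len(others) == 0:
                    continue
                rr = r[np.isin(block_idx, others)]
                cand = np.array([others[np.argmax(np.abs(rr))]])
            pick = int(rng.choice(cand))
            eff = sc.alpha_med * float(top["effect"])
            d[pick] += eff
            rows.append({"variant_id": geno.variants["variant_id"].iloc[pick],
                         "variant_index": pick, "effect": eff,
                         "cpg_id": cpg_id})
        truth.gwas_direct = pd.DataFrame(rows)
    return d


def marginal_liability_effects(geno: GenotypeMatrix, d: np.ndarray) -> np.ndarray:
    """LD-propagated marginal slope per variant: beta_s = cov(g_s, G d)/var(g_s)."""
    dos = np.nan_to_num(geno.dosages, nan=np.nanmean(geno.dosages))
    beta = np.zeros(geno.n_variants)
    blocks = geno.variants["block"].to_numpy() if "block" in geno.variants \
        else np.zeros(geno.n_variants, dtype=int)
    for b in np.unique(blocks):
        idx = np.flatnonzero(blocks == b)
        if not np.any(d[idx]):
            continue
        x = dos[:, idx] - dos[:, idx].mean(axis=0)
        cov = (x.T @ x) / len(x)
        var = np.diag(cov).copy()
        var[var == 0] = 1.0
        beta[idx] = (cov @ d[idx]) / var
    return beta


def simulate_gwas(geno: GenotypeMatrix, truth: TruthLedger,
                  scenario: SimScenario | None = None) -> GwasSummary:
    """Analytic case-control style GWAS summary statistics.

    Marginal effects (log-odds scale) are the LD-propagated projections of
    the scenario's direct liability effects; standard errors follow
    ``1/sqrt(N * 2 p (1-p))``; observed effects add Gaussian noise whose
    correlation across variants equals the panel LD (marginal estimates
    from one cohort share subjects, so their errors are LD-correlated —
    without this the null distribution of LD-aware weighted-sum statistics
    would be miscalibrated).
    """
    sc = scenario or truth.scenario
    rng = sc.child_rng(_KEY_GWAS)
    d = _direct_effects(geno, truth, sc, rng)
    beta_true = marginal_liability_effects(geno, d)
    freq = np.clip(geno.effect_allele_freq(), 1e-3, 1 - 1e-3)
    se = 1.0 / np.sqrt(sc.n_gwas * 2.0 * freq * (1.0 - freq))
    dos = np.nan_to_num(geno.dosages, nan=np.nanmean(geno.dosages))
    blocks = geno.variants["block"].to_numpy() if "block" in geno.variants \
        else np.zeros(geno.n_variants, dtype=int)
    noise = np.empty(geno.n_variants)
    for b in np.unique(blocks):
        idx = np.flatnonzero(blocks == b)
        x = dos[:, idx]
        sd = x.std(axis=0)
        sd[sd == 0] = 1.0
        xs = (x - x.mean(axis=0)) / sd
        r = (xs.T @ xs) / len(xs) + 1e-6 * np.eye(len(idx))
        chol = np.linalg.cholesky(r)
        noise[idx] = chol @ rng.standard_normal(len(idx))
    beta_hat = beta_true + noise * se
    z = beta_hat / se
    table = pd.DataFrame({
        "variant_id": geno.variants["variant_id"],
        "chrom": geno.variants["chrom"],
        "pos": geno.variants["pos"],
        "effect_allele": geno.variants["effect_allele"],
        "other_allele": geno.variants["other_allele"],
        "freq": freq,
        "beta": beta_hat,
        "se": se,
        "p": 2.0 * stats.norm.sf(np.abs(z)),
        "n": sc.n_gwas,
    })
    return GwasSummary(table)


# ---------------------------------------------------------------------------
# expression


def simulate_expression(
    meth: MethylationMatrix,
    truth: TruthLedger,
    n_decoys_per_cpg: int = 2,
    low_expr_frac: float = 0.1,
    n_nuisance: int = 3,
) -> ExpressionMatrix:
    """Methylation-driven gene expression for the tissue of ``meth``.

    For each CpG one linked gene follows gamma_eqtm * standardized CpG
    latent + nuisance + unit noise (gamma 0 outside the mediated_trio
    scenario and whenever the scenario's gamma is 0); decoy genes carry
    nuisance + noise only. ``n_nuisance`` latent per-sample factors load
    on every gene (the shared technical/biological structure that
    hidden-factor correction is meant to remove). Read counts and
    TPM-like values are emitted so gene-level expression filters can be
    exercised; a ``low_expr_frac`` fraction of decoy genes is nearly
    silent and should fail those filters (linked genes are always
    expressed, as the ground truth requires them testable).
    """
    sc = truth.scenario
    rng = sc.child_rng(_KEY_EXPR)
    lat = logit(np.clip(meth.beta.to_numpy(), 1e-9, 1 - 1e-9))
    lat = (lat - lat.mean(axis=1, keepdims=True)) / \
        np.maximum(lat.std(axis=1, keepdims=True), 1e-12)
    n_samples = lat.shape[1]
    annot = meth.cpg_annot.reset_index(drop=True)

    gamma = sc.gamma_eqtm if sc.name == "mediated_trio" else 0.0
    nuisance = rng.standard_normal((n_nuisance, n_samples))
    gene_rows, expr_rows, eqtm_rows = [], [], []
    linked_mask = []
    gi = 0
    for ci in range(len(annot)):
        cpg_id = annot["cpg_id"].iloc[ci]
        pos = int(annot["pos"].iloc[ci])
        for j in range(1 + n_decoys_per_cpg):
            g = gamma if j == 0 else 0.0
            gid = f"gene{gi:05d}"
            tss = pos + int(rng.integers(-400_000, 400_000))
            gene_rows.append({"gene_id": gid,
                              "chrom": annot["chrom"].iloc[ci],
                              "tss": max(tss, 1)})
            loadings = rng.normal(0.0, 0.5, size=n_nuisance)
            e = g * lat[ci] + loadings @ nuisance \
                + rng.standard_normal(n_samples)
            expr_rows.append(e)
            linked_mask.append(g != 0.0)
            if g != 0.0:
                eqtm_rows.append({"cpg_id": cpg_id, "gene_id": gid,
                                  "gamma": g})
            gi += 1

    expr = np.asarray(expr_rows)
    gene_annot = pd.DataFrame(gene_rows)
    n_genes = len(gene_annot)
    linked_mask = np.asarray(linked_mask)

    # counts / TPM scaffolding for the gene filters
    base = rng.lognormal(mean=4.0, sigma=1.0, size=n_genes)
    low = (rng.random(n_genes) < low_expr_frac) & ~linked_mask
    base[low] = rng.uniform(0.0, 0.4, size=low.sum())
    lam = base[:, None] * np.exp(0.1 * expr)
    counts = rng.poisson(lam).astype(float)
    tpm = counts / np.maximum(counts.sum(axis=0, keepdims=True), 1.0) * 1e6 / n_genes

    cols = meth.samples
    truth.eqtm = pd.DataFrame(eqtm_rows, columns=["cpg_id", "gene_id", "gamma"])
    return ExpressionMatrix(
        expr=pd.DataFrame(expr, index=gene_annot["gene_id"], columns=cols),
        counts=pd.DataFrame(counts, index=gene_annot["gene_id"], columns=cols),
        tpm=pd.DataFrame(tpm, index=gene_annot["gene_id"], columns=cols),
        gene_annot=gene_annot,
        tissue=meth.tissue,
    )


# ---------------------------------------------------------------------------
# individual-level cohort (oracle surface)


def simulate_cohort(geno: GenotypeMatrix, truth: TruthLedger,
                    scenario: SimScenario | None = None,
                    n: int | None = None) -> Cohort:
    """Draw an individual-level cohort from the same genotype model.

    Returns int8 dosages, a continuous liability phenotype
    (genetic effects + unit Gaussian noise), and per-variant OLS summary
    statistics computed on this cohort. This is the individual-level
    oracle surface used to validate the summary-statistic methods.
    """
    sc = scenario or truth.scenario
    n = n or sc.n_gwas
    rng = sc.child_rng(_KEY_COHORT)
    freq = geno.variants["freq"].to_numpy()
    blocks = geno.variants["block"].to_numpy()

    dosages = np.empty((n, geno.n_variants), dtype=np.int8)
    for b in range(sc.n_blocks):
        idx = np.flatnonzero(blocks == b)
        z = _latent_ar1(rng, n, len(idx), sc.rho)
        dosages[:, idx] = _discretize(z, freq[idx])

    d = _direct_effects(geno, truth, sc, rng)
    y = dosages.astype(float) @ d + rng.standard_normal(n)

    # vectorized per-variant OLS
    x = dosages.astype(float)
    xm = x.mean(axis=0)
    ym = y.mean()
    sxx = np.einsum("ij,ij->j", x, x) - n * xm * xm
    sxy = x.T @ y - n * xm * ym
    syy = float(y @ y - n * ym * ym)
    sxx_safe = np.where(sxx <= 0, np.nan, sxx)
    beta = sxy / sxx_safe
    resid_ss = syy - beta * sxy
    se = np.sqrt(np.maximum(resid_ss, 0) / (n - 2) / sxx_safe)
    z_stat = beta / se
    p = 2.0 * stats.t.sf(np.abs(z_stat), df=n - 2)

    table = pd.DataFrame({
        "variant_id": geno.variants["variant_id"],
        "chrom": geno.variants["chrom"],
        "pos": geno.variants["pos"],
        "effect_allele": geno.variants["effect_allele"],
        "other_allele": geno.variants["other_allele"],
        "freq": np.clip(xm / 2.0, 1e-6, 1 - 1e-6),
        "beta": beta,
        "se": se,
        "p": p,
        "n": n,
    })
    ok = np.isfinite(beta) & np.isfinite(se) & (se > 0)
    gwas = GwasSummary(table.loc[ok].reset_index(drop=True))
    return Cohort(dosages=dosages, variants=geno.variants.copy(), y=y,
                  gwas=gwas)


def cohort_expression(cohort: Cohort, truth: TruthLedger,
                      gene_annot: pd.DataFrame,
                      scenario: SimScenario | None = None) -> pd.DataFrame:
    """Gene expression for cohort individuals under the trio chain.

    Genes linked in ``truth.eqtm`` follow gamma * standardized CpG latent
    (cis-genetic + residual) per individual; all other genes are noise.
    Used to derive gene-cancer evidence with an individual-level footing.
    """
    sc = scenario or truth.scenario
    rng = np.random.default_rng(np.random.SeedSequence(sc.seed, spawn_key=(5,)))
    dos = cohort.dosages.astype(float)
    n = dos.shape[0]
    causal = truth.causal
    t0 = causal["tissue"].iloc[0] if len(causal) else None
    latents: dict[str, np.ndarray] = {}
    if t0 is not None:
        for cpg_id, grp in causal[causal["tissue"] == t0].groupby("cpg_id"):
            g = dos[:, grp["variant_index"].to_numpy()] @ grp["effect"].to_numpy()
            lat = g + rng.standard_normal(n) * np.sqrt(max(1 - sc.h2_meth, 0))
            sd = lat.std()
            latents[cpg_id] = (lat - lat.mean()) / (sd if sd > 0 else 1.0)
    link = truth.eqtm.set_index("gene_id") if len(truth.eqtm) else None
    rows = []
    for gid in gene_annot["gene_id"]:
        if link is not None and gid in link.index:
            rec = link.loc[gid]
            lat = latents.get(rec["cpg_id"])
            e = rec["gamma"] * lat + rng.standard_normal(n) if lat is not None \
                else rng.standard_normal(n)
        else:
            e = rng.standard_normal(n)
        rows.append(e)
    cols = [f"ind{i:05d}" for i in range(n)]
    return pd.DataFrame(rows, index=gene_annot["gene_id"], columns=cols)


def simulate_bundle(scenario: SimScenario, n_tissues: int = 2,
                    n_per_tissue: int | None = None,
                    n_decoys_per_cpg: int = 2):
    """Convenience: generate genotypes, methylation, truth, GWAS, expression."""
    geno = simulate_genotypes(scenario)
    meth, truth = simulate_methylation(geno, scenario, n_tissues=n_tissues,
                                       n_per_tissue=n_per_tissue)
    gwas = simulate_gwas(geno, truth, scenario)
    first = meth[sorted(meth)[0]]
    expr = simulate_expression(first, truth,
                               n_decoys_per_cpg=n_decoys_per_cpg)
    return {"geno": geno, "meth": meth, "truth": truth, "gwas": gwas,
            "expr": expr}
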
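"""Variant QC and normalization transforms.

Implements the variant retention rules (missingness < 5%, MAF > 5%,
HWE P > 1e-4, non-palindromic), rank-based inverse-normal transformation,
covariate residualization, PCA hidden factors (nuisance-factor proxy),
and between-sample quantile normalization. All QC inequalities are strict.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .types import GenotypeMatrix

logger = logging.getLogger(__name__)


def hwe_test(n_aa: int, n_ab: int, n_bb: int) -> float:
    """1-df chi-square goodness-of-fit p-value against Hardy-Weinberg.

    Expected genotype counts come from the sample allele frequency; a
    monomorphic sample (frequency 0 or 1) has statistic 0 and p = 1.
    """
    if min(n_aa, n_ab, n_bb) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_aa + n_ab + n_bb
    if n == 0:
        raise ValueError("no genotype observations")
    p = (2 * n_aa + n_ab) / (2 * n)
    q = 1.0 - p
    if p == 0.0 or q == 0.0:
        return 1.0
    expected = np.array([p * p, 2 * p * q, q * q]) * n
    observed = np.array([n_aa, n_ab, n_bb], dtype=float)
    chi2 = float(np.sum((observed - expected) ** 2 / expected))
    return float(stats.chi2.sf(chi2, df=1))


def _hwe_pvalues(geno: GenotypeMatrix) -> np.ndarray:
    """Per-variant HWE p from hard-call rounded dosages."""
    out = np.ones(geno.n_variants)
    for j in range(geno.n_variants):
        d = geno.dosages[:, j]
        d = d[np.isfinite(d)]
        g = np.rint(d).astype(int)
        out[j] = hwe_test(int(np.sum(g == 2)), int(np.sum(g == 1)),
                          int(np.sum(g == 0)))
    return out


def filter_variants(
    geno: GenotypeMatrix,
    miss_max: float = 0.05,
    maf_min: float = 0.05,
    hwe_min: float = 1e-4,
    drop_palindromic: bool = True,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Apply the variant QC rules; returns (filtered panel, per-rule log).

    A variant is retained iff missingness < miss_max, MAF > maf_min,
    HWE p > hwe_min, and (when requested) its allele pair is not
    palindromic — all strict inequalities. Input order is preserved.
    """
    if geno.n_variants == 0:
        log = pd.DataFrame(columns=["rule", "n_removed"])
        return geno, log

    miss = geno.missing_rate()
    maf = geno.maf()
    hwe = _hwe_pvalues(geno)
    pal = geno.is_palindromic()

    pass_miss = miss < miss_max
    pass_maf = maf > maf_min
    pass_hwe = hwe > hwe_min
    pass_pal = ~pal if drop_palindromic else np.ones_like(pal, dtype=bool)
    keep = pass_miss & pass_maf & pass_hwe & pass_pal

    log = pd.DataFrame({
        "rule": ["missingness", "maf", "hwe", "palindromic"],
        "n_removed": [int((~pass_miss).sum()), int((~pass_maf).sum()),
                      int((~pass_hwe).sum()), int((~pass_pal).sum())],
    })
    logger.info("variant QC: retained %d/%d", int(keep.sum()), len(keep))
    return geno.subset_variants(np.flatnonzero(keep)), log


def mean_impute(dosages: np.ndarray) -> np.ndarray:
    """Replace missing dosages by the per-variant mean (post-QC step)."""
    out = np.array(dosages, dtype=float)
    col_mean = np.nanmean(out, axis=0)
    nan_r, nan_c = np.where(np.isnan(out))
    out[nan_r, nan_c] = col_mean[nan_c]
    return out


def inverse_normal(x: np.ndarray) -> np.ndarray:
    """Rank-based inverse-normal transform with the Blom offset.

    Maps ranks r (ties averaged) to Phi^-1((r - 3/8) / (n + 1/4)) over
    the non-missing values; missing entries stay missing. A constant
    vector returns all zeros with a warning.
    """
    x = np.asarray(x, dtype=float)
    out = np.full_like(x, np.nan)
    ok = np.isfinite(x)
    vals = x[ok]
    n = len(vals)
    if n < 2:
        raise ValueError("need at least 2 non-missing values")
    if np.all(vals == vals[0]):
        warnings.warn("constant input to inverse_normal; returning zeros")
        out[ok] = 0.0
        return out
    ranks = stats.rankdata(vals, method="average")
    c = 3.0 / 8.0
    out[ok] = stats.norm.ppf((ranks - c) / (n - 2 * c + 1))
    return out


def inverse_normal_rows(mat: pd.DataFrame) -> pd.DataFrame:
    """Apply :func:`inverse_normal` to every row of a feature x sample matrix."""
    vals = np.vstack([inverse_normal(row) for row in mat.to_numpy()])
    return pd.DataFrame(vals, index=mat.index, columns=mat.columns)


def residualize(y_matrix: np.ndarray, covariates: np.ndarray) -> np.ndarray:
    """OLS residuals of each feature (row) on covariates + intercept.

    Raises on rank-deficient covariates (after adding the intercept).
    """
    y = np.atleast_2d(np.asarray(y_matrix, dtype=float))
    c = np.asarray(covariates, dtype=float)
    if c.ndim == 1:
        c = c[:, None]
    n = y.shape[1]
    if c.shape[0] != n:
        raise ValueError("covariate rows must match sample count")
    design = np.column_stack([np.ones(n), c])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("rank-deficient covariate matrix")
    coef, *_ = np.linalg.lstsq(design, y.T, rcond=None)
    resid = y - (design @ coef).T
    return resid if np.asarray(y_matrix).ndim > 1 else resid[0]


def hidden_factors(y_matrix: np.ndarray, k: int) -> np.ndarray:
    """Top-k principal-component scores of the feature-standardized matrix.

    A PCA stand-in for latent nuisance factors (PEER-style): features are
    standardized, the SVD taken over samples, and each component's sign is
    fixed so its largest-magnitude loading is positive. Returns a
    (n_samples, k) score matrix.
    """
    y = np.asarray(y_matrix, dtype=float)
    n_feat, n_samp = y.shape
    if k >= min(n_feat, n_samp):
        raise ValueError("k must be smaller than both matrix dimensions")
    sd = y.std(axis=1, ddof=0, keepdims=True)
    sd[sd == 0] = 1.0
    ys = (y - y.mean(axis=1, keepdims=True)) / sd
    # components over samples: right singular vectors of the feature matrix
    u, s, vt = np.linalg.svd(ys, full_matrices=False)
    scores = (vt[:k].T * s[:k])         # n_samples x k
    loadings = u[:, :k]
    for j in range(k):
        i = np.argmax(np.abs(loadings[:, j]))
        if loadings[i, j] < 0:
            scores[:, j] *= -1.0
    return scores


def quantile_normalize_samples(y_matrix: pd.DataFrame) -> pd.DataFrame:
    """Force every sample column onto the common reference distribution.

    The reference is the row-wise mean of the per-column sorted values;
    ties within a column receive the mean of the reference values they
    span (average-rank interpolation).
    """
    vals = y_matrix.to_numpy(dtype=float)
    n_feat, n_samp = vals.shape
    if n_samp < 2:
        raise ValueError("need at least 2 samples")
    order = np.sort(vals, axis=0)
    reference = order.mean(axis=1)
    out = np.empty_like(vals)
    for j in range(n_samp):
        ranks = stats.rankdata(vals[:, j], method="average")
        # interpolate reference at (possibly fractional) average ranks
        out[:, j] = np.interp(ranks, np.arange(1, n_feat + 1), reference)
    return pd.DataFrame(out, index=y_matrix.index, columns=y_matrix.columns)
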
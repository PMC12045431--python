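"""Expression filtering, normalization and covariate construction.

Expression matrices are filtered to well-expressed genes (TPM > 0.1 and
counts >= 6 in at least 20% of samples), scaled between libraries by trimmed
mean of M-values (TMM), and rank-transformed per gene to a standard normal
(inverse normal transform).  Hidden expression confounders are captured by
principal components of the normalized matrix, standing in the covariate
role the original pipeline fills with PEER factors.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd
from scipy import stats


def filter_expressed_genes(
    counts: pd.DataFrame,
    tpm: pd.DataFrame,
    tpm_threshold: float = 0.1,
    count_threshold: float = 6,
    sample_fraction: float = 0.2,
) -> list[str]:
    """Genes with TPM > 0.1 in >= 20% of samples AND counts >= 6 in >= 20%.

    The "20% of samples" count is ``ceil(0.2 * n)``.  TPM uses a strict
    inequality, the read-count rule is >=.
    """
    n = counts.shape[1]
    need = math.ceil(sample_fraction * n)
    tpm_ok = (tpm > tpm_threshold).sum(axis=1) >= need
    count_ok = (counts >= count_threshold).sum(axis=1) >= need
    return list(counts.index[tpm_ok & count_ok])


def tmm_factors(
    counts: pd.DataFrame,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
    rescale: bool = True,
) -> pd.Series:
    """Trimmed-mean-of-M-values scaling factor per library.

    The reference library is the one whose upper quartile (of counts, over
    genes with any expression) is closest to the mean upper quartile.  For
    each library, log-ratios M and average log abundances A versus the
    reference are computed over genes expressed in both; after trimming the
    top/bottom ``trim_m`` of M and ``trim_a`` of A, the factor is 2 to the
    precision-weighted mean M.  Factors are rescaled to geometric mean 1
    unless ``rescale`` is False.
    """
    x = counts.to_numpy(dtype=float)
    lib = x.sum(axis=0)
    if np.any(lib <= 0):
        bad = counts.columns[lib <= 0][0]
        raise ValueError(f"library {bad!r} has zero total counts")

    uq = np.quantile(x / lib, 0.75, axis=0)
    ref = int(np.argmin(np.abs(uq - uq.mean())))

    factors = np.ones(x.shape[1])
    for j in range(x.shape[1]):
        if j == ref:
            factors[j] = 1.0
            continue
        factors[j] = 2.0 ** _tmm_pair(x[:, j], lib[j], x[:, ref], lib[ref], trim_m, trim_a)
    if rescale:
        factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="tmm_factor")


def tmm_effective_factors(counts: pd.DataFrame, rescale: bool = True, **kwargs) -> pd.Series:
    """Effective per-library scaling: library size × TMM composition factor.

    This is the quantity CPM normalization divides by.  It is
    scale-equivariant: multiplying one library's counts by c multiplies its
    effective factor by c (the composition factor is unchanged, the library
    size carries the scaling).
    """
    f = tmm_factors(counts, rescale=False, **kwargs)
    eff = counts.sum(axis=0) * f
    if rescale:
        eff = eff / np.exp(np.mean(np.log(eff)))
    return eff.rename("effective_factor")


def _tmm_pair(
    obs: np.ndarray, n_obs: float, ref: np.ndarray, n_ref: float,
    trim_m: float, trim_a: float,
) -> float:
    keep = (obs > 0) & (ref > 0)
    o, r = obs[keep], ref[keep]
    p_o, p_r = o / n_obs, r / n_ref
    m = np.log2(p_o / p_r)
    a = 0.5 * np.log2(p_o * p_r)
    # asymptotic variance of M (delta method), used as precision weights
    w = (n_obs - o) / (n_obs * o) + (n_ref - r) / (n_ref * r)

    if np.max(np.abs(m)) < 1e-6:  # identical profiles
        return 0.0

    n = m.size
    lo_m, hi_m = math.floor(n * trim_m) + 1, n + 1 - (math.floor(n * trim_m) + 1)
    lo_a, hi_a = math.floor(n * trim_a) + 1, n + 1 - (math.floor(n * trim_a) + 1)
    rank_m = stats.rankdata(m)
    rank_a = stats.rankdata(a)
    keep2 = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not np.any(keep2):
        return 0.0
    return float(np.sum(m[keep2] / w[keep2]) / np.sum(1.0 / w[keep2]))


def inverse_normal_transform(values: np.ndarray) -> np.ndarray:
    """Rank-based inverse normal transform: Phi^-1((rank - 0.5) / n).

    Ties receive average ranks.  A constant vector maps to all zeros (every
    rank tied at the midpoint); a warning is emitted in that case.
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    if n < 3:
        raise ValueError("inverse normal transform needs n >= 3")
    if np.all(values == values[0]):
        warnings.warn("constant vector: inverse normal transform returns zeros")
        return np.zeros(n)
    ranks = stats.rankdata(values)
    return stats.norm.ppf((ranks - 0.5) / n)


def normalize_expression(
    counts: pd.DataFrame,
    tpm: pd.DataFrame,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
) -> pd.DataFrame:
    """TMM-scaled, inverse-normal-transformed expression (genes × samples).

    Counts are converted to TMM-effective-library CPM, then each gene is
    mapped to normal quantiles across samples.
    """
    factors = tmm_factors(counts, trim_m=trim_m, trim_a=trim_a)
    eff_lib = counts.sum(axis=0) * factors
    cpm = counts / eff_lib * 1e6
    normed = np.apply_along_axis(inverse_normal_transform, 1, cpm.to_numpy(dtype=float))
    return pd.DataFrame(normed, index=counts.index, columns=counts.columns)


def hidden_factors(normalized: pd.DataFrame, k: int = 30) -> pd.DataFrame:
    """Top-k principal-component scores of the samples × genes matrix.

    Genes are centered; columns are ordered by variance explained; sign is
    fixed so each component's largest-magnitude loading is positive.
    Returns samples × k.  ``k = 0`` yields an empty block.
    """
    n_samples = normalized.shape[1]
    n_genes = normalized.shape[0]
    if k < 0 or k >= min(n_genes, n_samples):
        if k != 0:
            raise ValueError(f"k={k} must be in [0, min(genes, samples))")
    if k == 0:
        return pd.DataFrame(index=normalized.columns)
    x = normalized.to_numpy(dtype=float).T  # samples × genes
    x = x - x.mean(axis=0)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    scores = u[:, :k] * s[:k]
    for j in range(k):
        i_max = int(np.argmax(np.abs(vt[j])))
        if vt[j, i_max] < 0:
            scores[:, j] *= -1.0
    return pd.DataFrame(
        scores, index=normalized.columns, columns=[f"factor_{i+1}" for i in range(k)]
    )


def genotype_pcs(dosages: np.ndarray, sample_ids: list[str], k: int = 5) -> pd.DataFrame:
    """Top-k PCs of centered, MAF-scaled dosages (samples × variants).

    Missing dosages are mean-imputed per variant before scaling.
    """
    d = np.asarray(dosages, dtype=float).copy()
    col_mean = np.nanmean(d, axis=0)
    nan_r, nan_c = np.where(np.isnan(d))
    d[nan_r, nan_c] = col_mean[nan_c]
    p = col_mean / 2.0
    scale = np.sqrt(2.0 * p * (1.0 - p))
    keep = scale > 0
    z = (d[:, keep] - col_mean[keep]) / scale[keep]
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    scores = u[:, :k] * s[:k]
    for j in range(k):
        i_max = int(np.argmax(np.abs(vt[j])))
        if vt[j, i_max] < 0:
            scores[:, j] *= -1.0
    return pd.DataFrame(scores, index=sample_ids, columns=[f"PC{i+1}" for i in range(k)])


def coefficient_of_variation(tpm: pd.DataFrame, reciprocal: bool = False) -> pd.Series:
    """Per-gene CV = SD / mean of TPM across samples (sample SD, ddof=1).

    ``reciprocal=True`` returns mean / SD instead.  Genes with zero mean are
    excluded from the result.
    """
    mean = tpm.mean(axis=1)
    sd = tpm.std(axis=1, ddof=1)
    keep = mean > 0
    cv = sd[keep] / mean[keep]
    if reciprocal:
        with np.errstate(divide="ignore"):
            cv = 1.0 / cv
    return cv.rename("cv")


def build_covariates(
    sex: pd.Series,
    batch: pd.Series,
    genotype_pcs: pd.DataFrame,
    hidden: pd.DataFrame,
) -> pd.DataFrame:
    """Assemble the eQTL covariate table: sex, one-hot batch, PCs, factors.

    Batch is one-hot encoded dropping the first level.  Raises on missing
    values or on collinear columns after encoding.
    """
    parts = [sex.rename("sex").astype(float)]
    batch_dummies = pd.get_dummies(batch.astype("category"), prefix="batch", drop_first=True)
    parts.append(batch_dummies.astype(float))
    parts.extend([genotype_pcs, hidden])
    cov = pd.concat(parts, axis=1)
    if cov.isna().any().any():
        bad = list(cov.columns[cov.isna().any()])
        raise ValueError(f"covariates contain missing values: {bad}")
    x = np.column_stack([np.ones(len(cov)), cov.to_numpy(dtype=float)])
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValueError("covariate matrix rank-deficient after encoding")
    return cov
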
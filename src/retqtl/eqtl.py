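"""Cis-eQTL mapping with permutation-calibrated gene-level FDR.

The mapper tests every variant within 1 Mb of a gene's transcription start
site against covariate-adjusted expression with ordinary least squares.
Gene-level significance is calibrated by permuting the residualized
phenotype, fitting a Beta distribution to the permutation minima of the
nominal p-value (the tail approximation introduced for fast QTL scans), and
converting each gene's best nominal p-value into an adjusted p-value.
Storey q-values over the adjusted p-values define eGenes at a given FDR, a
genome-wide adjusted-p boundary is back-transformed through each gene's
Beta fit into a per-gene nominal threshold p_t, and all cis variants at or
below p_t are reported as that gene's eQTLs.  Effect sizes are expressed as
allelic fold change: the log2 expression ratio attributable to the ALT
versus the REF allele.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .types import ExpressionBundle, GeneAnnotation, GenotypeMatrix

AFC_CAP = 6.64  # |log2 aFC| cap, = log2(100) to 2 decimals


@dataclass
class NominalAssociation:
    gene_id: str
    variant_id: str
    slope: float
    slope_se: float
    t_statistic: float
    nominal_p: float
    n_effective: int


@dataclass
class EgenePermutationResult:
    gene_id: str
    top_variant_id: str
    p_min_observed: float
    beta_a: float
    beta_b: float
    adjusted_beta_p: float
    n_permutations: int
    n_cis_variants: int
    empirical_p: float
    q_value: float = np.nan
    p_t: float = np.nan


@dataclass
class EqtlRecord:
    gene_id: str
    variant_id: str
    nominal_p: float
    slope: float
    afc_log2: float = np.nan


def cis_window(tss: int, window: int = 1_000_000) -> tuple[int, int]:
    """Inclusive 1-based interval [max(1, TSS − w), TSS + w], strand-agnostic."""
    return max(1, tss - window), tss + window


def _residualize(x: np.ndarray, covariates: np.ndarray) -> np.ndarray:
    """Residuals of the columns of x against [1, covariates] via least squares."""
    n = x.shape[0]
    c = np.column_stack([np.ones(n), covariates]) if covariates.size else np.ones((n, 1))
    q, _ = np.linalg.qr(c)
    return x - q @ (q.T @ x)


def _prepare_genotypes(g: np.ndarray) -> np.ndarray:
    """Mean-impute missing dosages per variant."""
    g = np.asarray(g, dtype=float).copy()
    if np.isnan(g).any():
        col_mean = np.nanmean(g, axis=0)
        r, c = np.where(np.isnan(g))
        g[r, c] = col_mean[c]
    return g


def covariate_rank(covariates: np.ndarray) -> int:
    n = covariates.shape[0]
    c = np.column_stack([np.ones(n), covariates]) if covariates.size else np.ones((n, 1))
    rank = np.linalg.matrix_rank(c)
    if rank < c.shape[1]:
        raise ValueError("covariate matrix rank-deficient; remove collinear columns")
    return rank


def nominal_scan(
    phenotype: np.ndarray,
    genotypes: np.ndarray,
    covariates: np.ndarray,
    gene_id: str = "",
    variant_ids: list[str] | None = None,
) -> list[NominalAssociation]:
    """OLS slope, SE, t and two-sided p for each cis variant.

    Phenotype and each (mean-imputed) genotype vector are residualized
    against the covariates plus intercept; the slope is the simple
    regression of the residualized phenotype on the residualized genotype,
    which by Frisch–Waugh equals the multiple-regression coefficient.
    Degrees of freedom are n − rank([1, covariates]) − 1.
    """
    y = np.asarray(phenotype, dtype=float)
    g = _prepare_genotypes(genotypes)
    n = y.size
    rank = covariate_rank(covariates)
    df = n - rank - 1
    if df <= 0:
        raise ValueError("not enough samples for the covariate model")

    r = _residualize(np.column_stack([y, g]), covariates)
    ry, rg = r[:, 0], r[:, 1:]
    gg = np.einsum("ij,ij->j", rg, rg)
    gg_safe = np.where(gg > 0, gg, np.nan)
    slope = rg.T @ ry / gg_safe
    rss = np.einsum("i,i->", ry, ry) - slope**2 * gg_safe
    rss = np.maximum(rss, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        se = np.sqrt(rss / df / gg_safe)
        t = slope / se
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.clip(p, np.finfo(float).tiny, 1.0)

    vids = variant_ids or [f"v{j}" for j in range(g.shape[1])]
    out = []
    for j, vid in enumerate(vids):
        out.append(
            NominalAssociation(
                gene_id=gene_id,
                variant_id=vid,
                slope=float(slope[j]),
                slope_se=float(se[j]),
                t_statistic=float(t[j]),
                nominal_p=float(p[j]) if not np.isnan(t[j]) else np.nan,
                n_effective=n,
            )
        )
    return out


def _min_p_matrix(y_mat: np.ndarray, rg: np.ndarray, df: int) -> np.ndarray:
    """Minimum nominal p across variants for each row of y_mat (pre-residualized)."""
    yn = y_mat / np.linalg.norm(y_mat, axis=1, keepdims=True)
    gn = rg / np.linalg.norm(rg, axis=0, keepdims=True)
    r = yn @ gn  # correlations of residualized vectors
    r2max = np.max(r**2, axis=1)
    r2max = np.minimum(r2max, 1.0 - 1e-14)
    tmax2 = r2max * df / (1.0 - r2max)
    pmin = 2.0 * stats.t.sf(np.sqrt(tmax2), df)
    return np.clip(pmin, np.finfo(float).tiny, 1.0)


def permutation_pass(
    phenotype: np.ndarray,
    genotypes: np.ndarray,
    covariates: np.ndarray,
    n_permutations: int = 1000,
    seed: int = 0,
    gene_id: str = "",
    variant_ids: list[str] | None = None,
) -> EgenePermutationResult:
    """Gene-level permutation pass with the Beta tail approximation.

    The covariate-residualized phenotype is permuted ``n_permutations``
    times with genotypes and covariates fixed (preserving cis LD); each
    permutation's minimum nominal p across cis variants is recorded and a
    Beta(a, b) is fitted to the minima by maximum likelihood.  The observed
    minimum p is then mapped to adjusted_beta_p = BetaCDF(p_min; a, b).
    """
    if n_permutations < 100:
        warnings.warn("fewer than 100 permutations: beta fit may be unstable")
    y = np.asarray(phenotype, dtype=float)
    if np.std(y) == 0:
        raise ValueError("phenotype has zero variance")
    g = _prepare_genotypes(genotypes)
    if g.shape[1] == 0:
        raise ValueError("no cis variants")
    rank = covariate_rank(covariates)
    df = y.size - rank - 1

    r = _residualize(np.column_stack([y, g]), covariates)
    ry, rg = r[:, 0], r[:, 1:]
    keep = np.einsum("ij,ij->j", rg, rg) > 1e-12
    if not np.any(keep):
        raise ValueError("all cis variants constant after residualization")
    rg = rg[:, keep]
    vids = variant_ids or [f"v{j}" for j in range(g.shape[1])]
    vids = [v for v, k in zip(vids, keep) if k]

    obs_p = _min_p_matrix(ry[None, :], rg, df)[0]
    # index of the top variant for reporting
    gn = rg / np.linalg.norm(rg, axis=0, keepdims=True)
    top_idx = int(np.argmax((gn.T @ (ry / np.linalg.norm(ry))) ** 2))

    rng = np.random.default_rng(seed)
    perm = np.array([rng.permutation(ry) for _ in range(n_permutations)])
    # permuted residuals are re-residualized: permutation breaks orthogonality
    perm = _residualize(perm.T, covariates).T
    minima = _min_p_matrix(perm, rg, df)

    a, b = fit_beta_mle(minima)
    adjusted = float(special.betainc(a, b, obs_p))
    empirical = (np.sum(minima <= obs_p) + 1.0) / (n_permutations + 1.0)
    return EgenePermutationResult(
        gene_id=gene_id,
        top_variant_id=vids[top_idx],
        p_min_observed=float(obs_p),
        beta_a=a,
        beta_b=b,
        adjusted_beta_p=adjusted,
        n_permutations=n_permutations,
        n_cis_variants=rg.shape[1],
        empirical_p=float(empirical),
    )


def fit_beta_mle(p_values: np.ndarray) -> tuple[float, float]:
    """Maximum-likelihood Beta(a, b) fit to p-values in (0, 1).

    Initialized from method-of-moments; optimized in log-parameter space
    with analytic gradients until the likelihood gradient norm is < 1e-8.
    Values at 0 or 1 are clamped inward with a warning.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size < 10:
        raise ValueError("need at least 10 p-values for a stable beta fit")
    if np.any(p <= 0.0) or np.any(p >= 1.0):
        warnings.warn("p-values at 0 or 1 clamped for beta fit")
        p = np.clip(p, 1e-300, 1.0 - 1e-16)

    mean, var = p.mean(), p.var()
    var = max(var, 1e-12)
    common = mean * (1.0 - mean) / var - 1.0
    a0 = max(mean * common, 1e-3)
    b0 = max((1.0 - mean) * common, 1e-3)

    s_log = np.log(p).mean()
    s_log1m = np.log1p(-p).mean()

    def neg_ll(theta: np.ndarray) -> tuple[float, np.ndarray]:
        a, b = np.exp(theta)
        ll = (a - 1.0) * s_log + (b - 1.0) * s_log1m - special.betaln(a, b)
        dig_ab = special.digamma(a + b)
        da = s_log - special.digamma(a) + dig_ab
        db = s_log1m - special.digamma(b) + dig_ab
        return -ll, -np.array([da * a, db * b])

    res = optimize.minimize(
        neg_ll, np.log([a0, b0]), jac=True, method="L-BFGS-B",
        options={"gtol": 1e-12, "ftol": 1e-15, "maxiter": 500},
    )

    def natural_grad(a: float, b: float) -> np.ndarray:
        dig_ab = special.digamma(a + b)
        return np.array([
            s_log - special.digamma(a) + dig_ab,
            s_log1m - special.digamma(b) + dig_ab,
        ])

    a, b = np.exp(res.x)
    # Newton polish: L-BFGS-B sometimes halts with a small residual gradient
    for _ in range(50):
        g = natural_grad(a, b)
        if np.linalg.norm(g) < 1e-10:
            break
        tri_ab = special.polygamma(1, a + b)
        hess = np.array([
            [special.polygamma(1, a) - tri_ab, -tri_ab],
            [-tri_ab, special.polygamma(1, b) - tri_ab],
        ])
        try:
            step = np.linalg.solve(hess, g)
        except np.linalg.LinAlgError:
            break
        a_new, b_new = a + step[0], b + step[1]
        if a_new <= 0 or b_new <= 0:
            break
        a, b = a_new, b_new
    grad = natural_grad(a, b)
    if np.linalg.norm(grad) > 1e-4:
        raise RuntimeError(f"beta MLE failed to converge: {res.message}, grad={grad}")
    return float(a), float(b)


def storey_qvalues(p_values: np.ndarray, lambda_grid: np.ndarray | None = None) -> np.ndarray:
    """Storey q-values with smoother-based pi0 estimation.

    pi0 is estimated on the lambda grid 0.05..0.95 (step 0.05) with a cubic
    polynomial smoother evaluated at the largest lambda; if the estimate
    falls outside (0, 1] the procedure falls back to pi0 = 1
    (Benjamini–Hochberg).  q-values are monotone non-decreasing in p.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if lambda_grid is None:
        lambda_grid = np.arange(0.05, 0.96, 0.05)

    if p.size < 100 or p.max() < lambda_grid.max():
        pi0 = 1.0
    else:
        pi0_lambda = np.array([np.mean(p > lam) / (1.0 - lam) for lam in lambda_grid])
        coeff = np.polyfit(lambda_grid, pi0_lambda, deg=3)
        pi0 = float(np.polyval(coeff, lambda_grid.max()))
        if not (0.0 < pi0 <= 1.0):
            pi0 = 1.0

    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order]
    q_sorted = pi0 * n * ranked / (np.arange(n) + 1.0)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(n)
    q[order] = q_sorted
    return q


def per_gene_threshold(
    results: list[EgenePermutationResult], fdr: float = 0.05
) -> dict[str, float]:
    """Per-eGene nominal p threshold p_t from the genome-wide FDR boundary.

    The boundary p* is the midpoint between the largest adjusted beta p with
    q <= fdr and the smallest with q > fdr (1.0 when every gene is
    significant); each significant gene's p_t is the Beta(a, b) quantile of
    p*.  Returns an empty dict when no gene passes.  Call after q-values
    have been assigned to the results.
    """
    qs = np.array([r.q_value for r in results])
    ps = np.array([r.adjusted_beta_p for r in results])
    if np.isnan(qs).any():
        raise ValueError("q-values not assigned; run assign_qvalues first")
    sig = qs <= fdr
    if not np.any(sig):
        return {}
    ub = ps[~sig].min() if np.any(~sig) else 1.0
    lb = ps[sig].max()
    p_star = 0.5 * (lb + ub)
    thresholds: dict[str, float] = {}
    for r in results:
        if r.q_value <= fdr:
            r.p_t = float(stats.beta.ppf(p_star, r.beta_a, r.beta_b))
            thresholds[r.gene_id] = r.p_t
    return thresholds


def assign_qvalues(results: list[EgenePermutationResult]) -> None:
    q = storey_qvalues(np.array([r.adjusted_beta_p for r in results]))
    for r, qi in zip(results, q):
        r.q_value = float(qi)


def allelic_fold_change(
    expression: np.ndarray,
    dosages: np.ndarray,
    covariates: np.ndarray | None = None,
    cap: float = AFC_CAP,
) -> float:
    """Log2 allelic fold change k of ALT versus REF expression.

    Under the additive haplotype model the expected expression of a sample
    with dosage g is c * (2 - g + g * 2^k) / 2.  Covariate effects are
    removed in log2 space, genotype-group means m0, m1, m2 are formed on the
    linear scale, and (c, k) minimize the dosage-count-weighted squared
    log2 residuals; k is clamped to ±cap.  Requires at least two genotype
    groups.
    """
    e = np.asarray(expression, dtype=float)
    g = np.asarray(dosages, dtype=float)
    valid = ~np.isnan(g) & ~np.isnan(e)
    e, g = e[valid], g[valid]
    g_round = np.clip(np.round(g), 0, 2).astype(int)

    if covariates is not None and covariates.size:
        loge = np.log2(np.maximum(e, 1e-9))
        resid = _residualize(loge[:, None], covariates[valid])[:, 0]
        e = 2.0 ** (resid + loge.mean())

    groups = sorted(set(g_round))
    if len(groups) < 2:
        raise ValueError("allelic fold change undefined with a single genotype group")
    m = {gr: float(np.mean(e[g_round == gr])) for gr in groups}
    n = {gr: int(np.sum(g_round == gr)) for gr in groups}
    if any(v <= 0 for v in m.values()):
        # degenerate mean (complete silencing in a group): cap in sign of trend
        sign = np.sign(m.get(2, m.get(1, 0.0)) - m[0]) or -1.0
        return float(sign * cap)

    log_m = np.array([np.log2(m[gr]) for gr in groups])
    w = np.array([n[gr] for gr in groups], dtype=float)
    gs = np.array(groups, dtype=float)

    def sse(k: float) -> float:
        model = np.log2((2.0 - gs + gs * 2.0**k) / 2.0)
        c = np.sum(w * (log_m - model)) / w.sum()
        return float(np.sum(w * (log_m - model - c) ** 2))

    res = optimize.minimize_scalar(sse, bounds=(-cap, cap), method="bounded",
                                   options={"xatol": 1e-10})
    return float(np.clip(res.x, -cap, cap))


@dataclass
class CisMapResult:
    """Full cohort mapping output: per-gene permutation records and eQTLs."""

    permutations: list[EgenePermutationResult]
    eqtls: list[EqtlRecord]
    nominal: pd.DataFrame | None = None

    @property
    def egenes(self) -> list[str]:
        return sorted({r.gene_id for r in self.permutations if not np.isnan(r.p_t)})

    def permutation_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "gene_id": r.gene_id,
                    "top_variant_id": r.top_variant_id,
                    "p_min_observed": r.p_min_observed,
                    "beta_a": r.beta_a,
                    "beta_b": r.beta_b,
                    "adjusted_beta_p": r.adjusted_beta_p,
                    "empirical_p": r.empirical_p,
                    "q_value": r.q_value,
                    "p_t": r.p_t,
                    "n_cis_variants": r.n_cis_variants,
                }
                for r in self.permutations
            ]
        )

    def eqtl_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "gene_id": r.gene_id,
                    "variant_id": r.variant_id,
                    "nominal_p": r.nominal_p,
                    "slope": r.slope,
                    "afc_log2": r.afc_log2,
                }
                for r in self.eqtls
            ]
        )


def map_cis(
    normalized: pd.DataFrame,
    geno: GenotypeMatrix,
    covariates: pd.DataFrame,
    gene_annot: GeneAnnotation,
    afc_expression: pd.DataFrame | None = None,
    window: int = 1_000_000,
    n_permutations: int = 1000,
    fdr: float = 0.05,
    seed: int = 0,
) -> CisMapResult:
    """Run the full cis scan: permutation pass per gene, q-values, p_t, eQTLs.

    ``normalized`` is the inverse-normal phenotype matrix (genes × samples);
    ``afc_expression`` an optional linear-scale matrix (e.g. TMM-scaled TPM)
    on which allelic fold changes are estimated (defaults to 2^normalized
    which only preserves sign, so passing TPM is recommended).
    """
    samples = list(normalized.columns)
    if list(covariates.index) != samples or geno.sample_ids != samples:
        raise ValueError("sample ordering must match across phenotype, genotypes, covariates")
    cov = covariates.to_numpy(dtype=float)
    pos = geno.pos
    chrom_arr = np.array(geno.chrom)

    rng = np.random.default_rng(seed)
    perm_results: list[EgenePermutationResult] = []
    gene_blocks: dict[str, tuple[np.ndarray, list[str]]] = {}
    skipped_no_cis: list[str] = []

    for gene_id in normalized.index:
        if gene_id not in gene_annot.table.index:
            continue
        row = gene_annot.table.loc[gene_id]
        lo, hi = cis_window(int(row.tss), window)
        in_cis = (chrom_arr == row.chrom) & (pos >= lo) & (pos <= hi)
        if not np.any(in_cis):
            skipped_no_cis.append(gene_id)
            continue
        block = geno.dosages[:, in_cis]
        vids = [geno.variant_ids[j] for j in np.flatnonzero(in_cis)]
        gene_seed = int(rng.integers(0, 2**31 - 1))
        try:
            res = permutation_pass(
                normalized.loc[gene_id].to_numpy(dtype=float),
                block, cov,
                n_permutations=n_permutations, seed=gene_seed,
                gene_id=gene_id, variant_ids=vids,
            )
        except ValueError:
            continue
        perm_results.append(res)
        gene_blocks[gene_id] = (block, vids)

    if not perm_results:
        return CisMapResult(permutations=[], eqtls=[])

    assign_qvalues(perm_results)
    thresholds = per_gene_threshold(perm_results, fdr=fdr)

    eqtls: list[EqtlRecord] = []
    vindex = geno.variant_index()
    for res in perm_results:
        p_t = thresholds.get(res.gene_id)
        if p_t is None:
            continue
        block, vids = gene_blocks[res.gene_id]
        nominals = nominal_scan(
            normalized.loc[res.gene_id].to_numpy(dtype=float),
            block, cov, gene_id=res.gene_id, variant_ids=vids,
        )
        if afc_expression is not None and res.gene_id in afc_expression.index:
            afc_pheno = afc_expression.loc[res.gene_id].to_numpy(dtype=float)
        else:
            afc_pheno = 2.0 ** normalized.loc[res.gene_id].to_numpy(dtype=float)
        for assoc in nominals:
            if np.isnan(assoc.nominal_p) or assoc.nominal_p > p_t:
                continue
            dos = geno.dosages[:, vindex[assoc.variant_id]]
            try:
                afc = allelic_fold_change(afc_pheno, dos, cov)
            except ValueError:
                afc = np.nan
            eqtls.append(
                EqtlRecord(
                    gene_id=res.gene_id,
                    variant_id=assoc.variant_id,
                    nominal_p=assoc.nominal_p,
                    slope=assoc.slope,
                    afc_log2=afc,
                )
            )
    return CisMapResult(permutations=perm_results, eqtls=eqtls)
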
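"""Expression-outlier detection and cross-tissue outlier accounting.

A self-contained aberrant-expression caller standing in for autoencoder
pipelines: counts are median-of-ratios size-factor normalized, log2(x+1)
transformed, the leading principal components are regressed out as a
confounder proxy, and per-gene robust z-scores (median/MAD) yield normal
p-values adjusted per sample by Benjamini–Hochberg.  Events are reported at
p_adj < 0.05, the published cutoff; genes below a cohort-mean expression
cutoff of 1 (FPKM-like, fixed gene length) are excluded.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class OutlierEvent:
    sample_id: str
    gene_id: str
    tissue: str
    z: float
    log2_fold: float
    p: float
    p_adj: float


def size_factors(counts: np.ndarray) -> np.ndarray:
    """Median-of-ratios size factor per sample (genes × samples input).

    Only genes expressed in every sample contribute to the geometric-mean
    reference; falls back to library-size ratios if no such gene exists.
    """
    x = np.asarray(counts, dtype=float)
    expressed = np.all(x > 0, axis=1)
    if not expressed.any():
        lib = x.sum(axis=0)
        return lib / np.exp(np.mean(np.log(lib)))
    ref = np.exp(np.mean(np.log(x[expressed]), axis=1))
    sf = np.median(x[expressed] / ref[:, None], axis=0)
    return sf / np.exp(np.mean(np.log(sf)))


def _remove_pcs(mat: np.ndarray, n_pcs: int) -> np.ndarray:
    """Remove the top n_pcs sample-space principal components (genes × samples)."""
    if n_pcs <= 0:
        return mat.copy()
    centered = mat - mat.mean(axis=1, keepdims=True)
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    k = min(n_pcs, s.size)
    approx = (u[:, :k] * s[:k]) @ vt[:k]
    return mat - approx


def call_expression_outliers(
    counts: pd.DataFrame,
    tissue: str = "NSR",
    expression_cutoff: float = 1.0,
    gene_length_kb: float = 2.0,
    n_remove_pcs: int | None = None,
    alpha: float = 0.05,
) -> list[OutlierEvent]:
    """Call expression outliers per (sample, gene) in one tissue.

    ``expression_cutoff`` excludes genes whose cohort-mean FPKM-like value
    (reads per kb per million, fixed gene length) is below 1.
    ``n_remove_pcs`` defaults to ceil(n_samples / 20).
    """
    n_samples = counts.shape[1]
    if n_samples < 3:
        raise ValueError("need at least 3 samples")
    if n_remove_pcs is None:
        n_remove_pcs = math.ceil(n_samples / 20)

    x = counts.to_numpy(dtype=float)
    lib = x.sum(axis=0)
    fpkm_like = x / lib * 1e6 / gene_length_kb
    keep = fpkm_like.mean(axis=1) >= expression_cutoff
    genes = list(counts.index[keep])
    x = x[keep]

    sf = size_factors(x)
    logx = np.log2(x / sf + 1.0)
    resid = _remove_pcs(logx, n_remove_pcs)

    events: list[OutlierEvent] = []
    med = np.median(resid, axis=1, keepdims=True)
    mad = stats.median_abs_deviation(resid, axis=1, scale=1.0)[:, None]
    zero_mad = mad[:, 0] == 0
    if zero_mad.any():
        warnings.warn(f"{int(zero_mad.sum())} genes with zero MAD skipped")
    scale = 1.4826 * mad
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (resid - med) / scale
    z[zero_mad] = np.nan
    p = 2.0 * stats.norm.sf(np.abs(z))

    log_med = np.median(logx, axis=1, keepdims=True)
    log2_fold = logx - log_med

    sample_ids = list(counts.columns)
    for j, sid in enumerate(sample_ids):
        col_p = p[:, j]
        ok = ~np.isnan(col_p)
        if not ok.any():
            continue
        p_adj = np.full(col_p.shape, np.nan)
        p_adj[ok] = _bh(col_p[ok])
        hits = np.flatnonzero(ok & (p_adj < alpha))
        for i in hits:
            events.append(
                OutlierEvent(
                    sample_id=sid,
                    gene_id=genes[i],
                    tissue=tissue,
                    z=float(z[i, j]),
                    log2_fold=float(log2_fold[i, j]),
                    p=float(col_p[i]),
                    p_adj=float(p_adj[i]),
                )
            )
    return events


def _bh(p: np.ndarray) -> np.ndarray:
    n = p.size
    order = np.argsort(p, kind="mergesort")
    adj = p[order] * n / (np.arange(n) + 1.0)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out


def events_frame(events: list[OutlierEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample_id": e.sample_id,
                "gene_id": e.gene_id,
                "tissue": e.tissue,
                "z": e.z,
                "log2_fold": e.log2_fold,
                "p": e.p,
                "p_adj": e.p_adj,
            }
            for e in events
        ],
        columns=["sample_id", "gene_id", "tissue", "z", "log2_fold", "p", "p_adj"],
    )


def cross_tissue_share(
    events_a: list[OutlierEvent], events_b: list[OutlierEvent]
) -> tuple[int, int, int]:
    """Unique (sample, gene) outlier pairs: (A-only, B-only, shared)."""
    a = {(e.sample_id, e.gene_id) for e in events_a}
    b = {(e.sample_id, e.gene_id) for e in events_b}
    return len(a - b), len(b - a), len(a & b)
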
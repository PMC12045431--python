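"""Bootstrap enrichment of eVariants in candidate cis-regulatory elements.

Each bootstrap iteration subsamples eVariants with replacement, draws one
non-eQTL control per eVariant matched on allele frequency and local gene
density (TSS count within 1 Mb), and records the ratio of eVariant to
control overlaps with each cCRE class.  Significance comes from a Z-score
of the mean ratio against a null with mean 1 and the bootstrap standard
deviation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .types import CcreSet


def gene_density(
    position: int, chrom: str, tss_table: pd.DataFrame, window: int = 1_000_000
) -> int:
    """Number of gene TSSs within 1 Mb (inclusive) of a variant position."""
    sub = tss_table[tss_table["chrom"] == chrom]
    return int(np.sum(np.abs(sub["tss"].to_numpy() - position) <= window))


def gene_density_vector(
    positions: np.ndarray, chroms: np.ndarray, tss_table: pd.DataFrame,
    window: int = 1_000_000,
) -> np.ndarray:
    """Vectorized gene density for many variants."""
    out = np.zeros(len(positions), dtype=int)
    for chrom, sub in tss_table.groupby("chrom"):
        mask = chroms == chrom
        if not mask.any():
            continue
        tss = np.sort(sub["tss"].to_numpy())
        pos = positions[mask]
        lo = np.searchsorted(tss, pos - window, side="left")
        hi = np.searchsorted(tss, pos + window, side="right")
        out[mask] = hi - lo
    return out


DENSITY_BIN_EDGES = np.array([0, 5, 10, 20, 50, np.inf])  # 0–5, 6–10, 11–20, 21–50, >50


def _density_bin(density: np.ndarray) -> np.ndarray:
    return np.searchsorted(DENSITY_BIN_EDGES[1:], density, side="left")


def af_bin_edges(af_pool: np.ndarray, n_bins: int = 10) -> np.ndarray:
    """Decile edges of the pooled allele-frequency distribution."""
    return np.unique(np.quantile(af_pool, np.linspace(0, 1, n_bins + 1)))


def _af_bin(af: np.ndarray, edges: np.ndarray) -> np.ndarray:
    b = np.searchsorted(edges[1:-1], af, side="right")
    return np.clip(b, 0, len(edges) - 2)


def match_controls(
    evariants: pd.DataFrame,
    control_pool: pd.DataFrame,
    seed: int | np.random.Generator = 0,
    af_edges: np.ndarray | None = None,
) -> pd.DataFrame:
    """One matched control per eVariant (AF decile × gene-density bin).

    Sampling is uniform with replacement within the joint bin; if a bin has
    no controls, the nearest non-empty bin by combined bin distance is used
    and the fallback is recorded in the ``fallback`` column.  Both frames
    need columns variant_id, af, density.
    """
    if control_pool.empty:
        raise ValueError("control pool is empty")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    if af_edges is None:
        pooled = np.concatenate([evariants["af"].to_numpy(), control_pool["af"].to_numpy()])
        af_edges = af_bin_edges(pooled)

    e_af = _af_bin(evariants["af"].to_numpy(), af_edges)
    e_dn = _density_bin(evariants["density"].to_numpy())
    c_af = _af_bin(control_pool["af"].to_numpy(), af_edges)
    c_dn = _density_bin(control_pool["density"].to_numpy())

    pool_idx: dict[tuple[int, int], np.ndarray] = {}
    for key in set(zip(c_af, c_dn)):
        pool_idx[key] = np.flatnonzero((c_af == key[0]) & (c_dn == key[1]))

    chosen = np.empty(len(evariants), dtype=int)
    fallback = np.zeros(len(evariants), dtype=bool)
    keys = sorted(pool_idx)
    for i, key in enumerate(zip(e_af, e_dn)):
        members = pool_idx.get(key)
        if members is None:
            # nearest non-empty bin by L1 distance in (AF bin, density bin)
            dists = [abs(k[0] - key[0]) + abs(k[1] - key[1]) for k in keys]
            members = pool_idx[keys[int(np.argmin(dists))]]
            fallback[i] = True
        chosen[i] = members[rng.integers(len(members))]

    out = control_pool.iloc[chosen].reset_index(drop=True)
    out["fallback"] = fallback
    return out


def build_ccre_trees(ccres: CcreSet) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for chrom, sub in ccres.table.groupby("chrom"):
        t = IntervalTree()
        for s, e in zip(sub["start"], sub["end"]):
            t.addi(int(s), int(e))
        trees[str(chrom)] = t
    return trees


def variant_interval_overlap(
    positions: np.ndarray,
    chroms: np.ndarray,
    trees: dict[str, IntervalTree],
    spans: np.ndarray | None = None,
) -> np.ndarray:
    """Overlap flags for variants against an interval set.

    A SNV at 1-based position p overlaps a 0-based half-open interval
    [start, end) iff start < p <= end.  Spanning variants (``spans`` gives
    1-based inclusive (start, end) rows) overlap iff the ranges intersect.
    Chromosome names are normalized by stripping any "chr" prefix.
    """
    norm = {k.removeprefix("chr"): v for k, v in trees.items()}
    flags = np.zeros(len(positions), dtype=bool)
    for i in range(len(positions)):
        t = norm.get(str(chroms[i]).removeprefix("chr"))
        if t is None:
            continue
        if spans is None:
            flags[i] = bool(t.overlap(positions[i] - 1, positions[i]))
        else:
            s, e = spans[i]
            flags[i] = bool(t.overlap(s - 1, e))
    return flags


@dataclass
class EnrichmentResult:
    ccre_label: str
    mean_enrichment: float
    ci_low: float
    ci_high: float
    z: float
    p: float  # NaN when undefined (single iteration)
    n_iterations: int
    subsample_size: int
    n_excluded_iterations: int = 0


def bootstrap_enrichment(
    evariants: pd.DataFrame,
    control_pool: pd.DataFrame,
    ccre_sets: dict[str, CcreSet],
    n_iter: int = 1000,
    subsample: int = 100_000,
    seed: int = 0,
) -> list[EnrichmentResult]:
    """Matched-control bootstrap enrichment, one result per cCRE label.

    Frames need variant_id, chrom, pos (1-based), af, density columns.
    Per iteration the ratio (#subsampled eVariants in the cCRE set) /
    (#matched controls in it) is recorded; iterations with zero control
    overlaps are excluded and counted.  The p-value is two-sided normal on
    Z = (mean − 1) / sd of the bootstrap ratios.
    """
    if evariants.empty or not ccre_sets:
        raise ValueError("need non-empty eVariant and cCRE sets")
    rng = np.random.default_rng(seed)
    sub_n = min(subsample, 10 * len(evariants))

    trees = {label: build_ccre_trees(cs) for label, cs in ccre_sets.items()}
    pooled = np.concatenate([evariants["af"].to_numpy(), control_pool["af"].to_numpy()])
    edges = af_bin_edges(pooled)

    e_pos = evariants["pos"].to_numpy()
    e_chrom = evariants["chrom"].to_numpy()
    e_flags = {
        label: variant_interval_overlap(e_pos, e_chrom, tr) for label, tr in trees.items()
    }
    c_pos = control_pool["pos"].to_numpy()
    c_chrom = control_pool["chrom"].to_numpy()
    c_flags = {
        label: variant_interval_overlap(c_pos, c_chrom, tr) for label, tr in trees.items()
    }

    c_af = _af_bin(control_pool["af"].to_numpy(), edges)
    c_dn = _density_bin(control_pool["density"].to_numpy())
    e_af = _af_bin(evariants["af"].to_numpy(), edges)
    e_dn = _density_bin(evariants["density"].to_numpy())
    pool_idx: dict[tuple[int, int], np.ndarray] = {}
    for key in set(zip(c_af, c_dn)):
        pool_idx[key] = np.flatnonzero((c_af == key[0]) & (c_dn == key[1]))
    keys = sorted(pool_idx)

    # resolve each eVariant's control bin (nearest non-empty fallback) once;
    # controls are exchangeable within a bin, so draws are grouped per bin
    bin_members: list[np.ndarray] = []
    bin_key_of = np.empty(len(evariants), dtype=int)
    key_to_slot: dict[tuple[int, int], int] = {}
    for i, key in enumerate(zip(e_af, e_dn)):
        key = tuple(int(x) for x in key)
        if key not in key_to_slot:
            members = pool_idx.get(key)
            if members is None:
                dists = [abs(k[0] - key[0]) + abs(k[1] - key[1]) for k in keys]
                members = pool_idx[keys[int(np.argmin(dists))]]
            key_to_slot[key] = len(bin_members)
            bin_members.append(members)
        bin_key_of[i] = key_to_slot[key]

    ratios: dict[str, list[float]] = {label: [] for label in ccre_sets}
    excluded: dict[str, int] = {label: 0 for label in ccre_sets}
    n_ev = len(evariants)
    n_bins = len(bin_members)
    for _ in range(n_iter):
        pick = rng.integers(0, n_ev, size=sub_n)
        per_bin = np.bincount(bin_key_of[pick], minlength=n_bins)
        ctrl_parts = [
            bin_members[s][rng.integers(0, len(bin_members[s]), size=c)]
            for s, c in enumerate(per_bin) if c > 0
        ]
        ctrl = np.concatenate(ctrl_parts)
        for label in ccre_sets:
            n_e = int(e_flags[label][pick].sum())
            n_c = int(c_flags[label][ctrl].sum())
            if n_c == 0:
                excluded[label] += 1
                continue
            ratios[label].append(n_e / n_c)

    results = []
    for label in ccre_sets:
        r = np.array(ratios[label])
        if r.size == 0:
            results.append(
                EnrichmentResult(label, np.nan, np.nan, np.nan, np.nan, np.nan,
                                 n_iter, sub_n, excluded[label])
            )
            continue
        mean = float(r.mean())
        if r.size == 1:
            results.append(
                EnrichmentResult(label, mean, mean, mean, np.nan, np.nan,
                                 n_iter, sub_n, excluded[label])
            )
            continue
        sd = float(r.std(ddof=1))
        ci_low, ci_high = np.percentile(r, [2.5, 97.5])
        if sd > 0:
            z = (mean - 1.0) / sd
            p = float(min(max(2.0 * stats.norm.sf(abs(z)), np.finfo(float).tiny), 1.0))
        else:
            z, p = np.inf if mean != 1.0 else 0.0, np.nan
        results.append(
            EnrichmentResult(label, mean, float(ci_low), float(ci_high), float(z), p,
                             n_iter, sub_n, excluded[label])
        )
    return results
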
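"""Site-level genotype quality control.

Implements the WGS site-filter cascade used upstream of cis-eQTL mapping:
hard-filter flags, low-complexity-region overlap, inbreeding coefficient,
per-genotype GQ/allelic-balance masking, monomorphic removal, an exact
Hardy-Weinberg equilibrium test, and a missingness cap — plus the
common-variant eligibility gate (MAF > 2.5%, MAC > 10) and the
singleton-concordance sample-matching check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np

from .types import GenotypeMatrix, VariantRecord


class SiteFilterStatus(str, Enum):
    PASS = "pass"
    FAIL_FILTER_FLAG = "fail_filter_flag"
    FAIL_LCR = "fail_lcr"
    FAIL_INBREEDING = "fail_inbreeding"
    FAIL_MONOMORPHIC = "fail_monomorphic"
    FAIL_HWE = "fail_hwe"
    FAIL_MISSINGNESS = "fail_missingness"


@dataclass
class SiteQcRecord:
    """Per-site QC outcome: terminal status plus the statistics that decided it."""

    variant_id: str
    filter_status: SiteFilterStatus
    inbreeding_F: float = math.nan
    hwe_p: float = math.nan
    missingness: float = math.nan
    maf: float = math.nan
    mac: int = 0


@dataclass
class SiteFilterParams:
    """Thresholds for the site cascade; defaults follow the published filter set."""

    min_inbreeding_f: float = -0.3
    min_gq: int = 20
    ab_low: float = 0.2
    ab_high: float = 0.8
    hwe_p_cutoff: float = 1e-8
    max_missingness: float = 0.20
    lcr_slop: int = 0


def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact two-sided Hardy-Weinberg test (Wigginton-style).

    Conditional on the observed allele counts, sums the probabilities of all
    heterozygote counts whose conditional probability does not exceed that of
    the observed count.  Returns a p-value in (0, 1].
    """
    if n_hom_ref < 0 or n_het < 0 or n_hom_alt < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_hom_ref + n_het + n_hom_alt
    if n == 0:
        raise ValueError("at least one genotype required")

    n_rare = min(2 * n_hom_ref + n_het, 2 * n_hom_alt + n_het)
    if n_rare == 0:
        return 1.0  # monomorphic: single possible configuration

    # heterozygote counts share the parity of the rare-allele count
    het_values = np.arange(n_rare % 2, n_rare + 1, 2)
    # unnormalized log conditional probability of each het count:
    # P(het) ∝ n_rare! n_common! n! 2^het / (hom_rare! het! hom_common! (2n)!)
    hom_rare = (n_rare - het_values) // 2
    hom_common = n - het_values - hom_rare
    log_probs = (
        het_values * math.log(2.0)
        - _lgamma_arr(hom_rare + 1)
        - _lgamma_arr(het_values + 1)
        - _lgamma_arr(hom_common + 1)
    )
    log_probs -= log_probs.max()
    probs = np.exp(log_probs)
    probs /= probs.sum()

    obs_idx = np.flatnonzero(het_values == n_het)
    if obs_idx.size == 0:
        raise ValueError("observed het count inconsistent with allele counts")
    p_obs = probs[obs_idx[0]]
    # small relative slack so ties in floating point are counted as ties
    p = probs[probs <= p_obs * (1.0 + 1e-12)].sum()
    return float(min(p, 1.0))


def _lgamma_arr(x: np.ndarray) -> np.ndarray:
    from scipy.special import gammaln

    return gammaln(x)


def inbreeding_coefficient(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """F = 1 − observed het fraction / expected het fraction (2p̂q̂).

    Undefined for monomorphic sites (raises ValueError); those are removed by
    the monomorphic rule instead.
    """
    n = n_hom_ref + n_het + n_hom_alt
    if n <= 0:
        raise ValueError("empty site")
    p_hat = (2 * n_hom_ref + n_het) / (2 * n)
    expected_het = 2.0 * p_hat * (1.0 - p_hat)
    if expected_het == 0.0:
        raise ValueError("inbreeding coefficient undefined for monomorphic site")
    return 1.0 - (n_het / n) / expected_het


def _genotype_counts(dosages: np.ndarray) -> tuple[int, int, int]:
    valid = dosages[~np.isnan(dosages)]
    return (
        int(np.sum(valid == 0)),
        int(np.sum(valid == 1)),
        int(np.sum(valid == 2)),
    )


def _overlaps_lcr(chrom: str, pos: int, lcr: dict[str, np.ndarray], slop: int) -> bool:
    intervals = lcr.get(chrom)
    if intervals is None or intervals.size == 0:
        return False
    # intervals: (k, 2) array of 0-based half-open [start, end); SNV position is 1-based
    p0 = pos - 1
    return bool(np.any((intervals[:, 0] - slop <= p0) & (p0 < intervals[:, 1] + slop)))


def apply_site_filters(
    records: Iterable[VariantRecord],
    lcr_intervals: dict[str, np.ndarray] | None = None,
    params: SiteFilterParams | None = None,
) -> tuple[GenotypeMatrix, list[SiteQcRecord]]:
    """Run the full site-filter cascade over biallelic VCF records.

    The cascade order is fixed: (1) non-PASS filter flag; (2) low-complexity
    region overlap; (3) inbreeding F < −0.3; (4) genotypes with GQ < 20 set
    missing; (5) heterozygous genotypes with allelic balance outside (0.2, 0.8)
    set missing; (6) monomorphic after masking; (7) HWE exact p < 1e-8;
    (8) site missingness > 20%.  Every dropped site gets a QC record with the
    rule that removed it; survivors get a PASS record.
    """
    params = params or SiteFilterParams()
    lcr = lcr_intervals or {}

    qc_records: list[SiteQcRecord] = []
    kept: list[VariantRecord] = []
    kept_dosages: list[np.ndarray] = []
    sample_ids: list[str] | None = None

    for rec in records:
        if sample_ids is None:
            sample_ids = list(rec.sample_ids)
        vid = rec.variant_id

        if rec.filter_flag not in (None, "", ".", "PASS"):
            qc_records.append(SiteQcRecord(vid, SiteFilterStatus.FAIL_FILTER_FLAG))
            continue
        if _overlaps_lcr(rec.chrom, rec.pos, lcr, params.lcr_slop):
            qc_records.append(SiteQcRecord(vid, SiteFilterStatus.FAIL_LCR))
            continue

        dosages = rec.dosages.astype(float).copy()
        counts = _genotype_counts(dosages)
        if counts[0] + counts[1] + counts[2] > 0 and not (
            counts[1] == 0 and (counts[0] == 0 or counts[2] == 0)
        ):
            f_coef = inbreeding_coefficient(*counts)
            if f_coef < params.min_inbreeding_f:
                qc_records.append(
                    SiteQcRecord(vid, SiteFilterStatus.FAIL_INBREEDING, inbreeding_F=f_coef)
                )
                continue
        else:
            f_coef = math.nan

        # per-genotype masking: GQ, then heterozygous allelic balance
        if rec.gq is not None:
            dosages[rec.gq < params.min_gq] = np.nan
        if rec.allelic_balance is not None:
            ab = rec.allelic_balance
            het = dosages == 1
            bad_ab = het & ~np.isnan(ab) & ((ab > params.ab_high) | (ab < params.ab_low))
            dosages[bad_ab] = np.nan

        counts = _genotype_counts(dosages)
        n_called = sum(counts)
        missingness = 1.0 - n_called / dosages.size if dosages.size else 1.0

        alt_alleles = counts[1] + 2 * counts[2]
        total_alleles = 2 * n_called
        if n_called == 0:
            # fully masked site: nothing left to test, removed as missing
            qc_records.append(
                SiteQcRecord(vid, SiteFilterStatus.FAIL_MISSINGNESS, missingness=missingness)
            )
            continue
        if alt_alleles == 0 or alt_alleles == total_alleles:
            qc_records.append(
                SiteQcRecord(vid, SiteFilterStatus.FAIL_MONOMORPHIC, missingness=missingness)
            )
            continue

        hwe_p = hwe_exact_test(*counts)
        af = alt_alleles / total_alleles
        maf = min(af, 1.0 - af)
        mac = min(alt_alleles, total_alleles - alt_alleles)
        if hwe_p < params.hwe_p_cutoff:
            qc_records.append(
                SiteQcRecord(
                    vid, SiteFilterStatus.FAIL_HWE,
                    hwe_p=hwe_p, missingness=missingness, maf=maf, mac=mac,
                )
            )
            continue
        if missingness > params.max_missingness:
            qc_records.append(
                SiteQcRecord(
                    vid, SiteFilterStatus.FAIL_MISSINGNESS,
                    hwe_p=hwe_p, missingness=missingness, maf=maf, mac=mac,
                )
            )
            continue

        qc_records.append(
            SiteQcRecord(
                vid, SiteFilterStatus.PASS,
                inbreeding_F=f_coef, hwe_p=hwe_p,
                missingness=missingness, maf=maf, mac=mac,
            )
        )
        kept.append(rec)
        kept_dosages.append(dosages)

    if sample_ids is None:
        sample_ids = []
    geno = GenotypeMatrix(
        dosages=np.array(kept_dosages, dtype=float).reshape(len(kept), len(sample_ids)).T,
        variant_ids=[r.variant_id for r in kept],
        sample_ids=sample_ids,
        chrom=[r.chrom for r in kept],
        pos=np.array([r.pos for r in kept], dtype=int),
    )
    return geno, qc_records


def eqtl_eligible_variants(
    geno: GenotypeMatrix, maf_threshold: float = 0.025, mac_threshold: int = 10
) -> set[str]:
    """Variants eligible for eQTL mapping: MAF > 2.5% and MAC > 10, strict.

    Frequencies are computed over non-missing genotypes only.
    """
    eligible: set[str] = set()
    d = geno.dosages
    for j, vid in enumerate(geno.variant_ids):
        col = d[:, j]
        called = col[~np.isnan(col)]
        if called.size == 0:
            continue
        alt = int(called.sum())
        total = 2 * called.size
        mac = min(alt, total - alt)
        maf = mac / total
        if maf > maf_threshold and mac > mac_threshold:
            eligible.add(vid)
    return eligible


def singleton_concordance(
    wgs_singletons: set[str],
    rna_calls: dict[str, float],
    rna_depth: dict[str, float],
    min_depth: float = 15.0,
    assessable_denominator: bool = True,
) -> float:
    """Fraction of a sample's WGS singleton variants also called from RNA-seq.

    By default the denominator is restricted to singletons assessable in the
    RNA data, i.e. sites where RNA read depth exceeds ``min_depth``; with
    ``assessable_denominator=False`` all singletons count.  The numerator
    requires the variant to have been called from RNA with that depth.
    Raises ValueError if the denominator is empty.
    """
    assessable = {v for v in wgs_singletons if rna_depth.get(v, 0.0) > min_depth}
    denominator = assessable if assessable_denominator else wgs_singletons
    if not denominator:
        raise ValueError("no singleton site assessable at the required RNA depth")
    called = {v for v in assessable if rna_calls.get(v, 0.0) > min_depth}
    return len(called) / len(denominator)


def split_multiallelic(
    chrom: str,
    pos: int,
    ref: str,
    alts: Sequence[str],
    genotypes: np.ndarray,
) -> list[tuple[str, np.ndarray]]:
    """Split a multiallelic record into one biallelic record per ALT.

    ``genotypes`` holds per-sample allele index pairs (n, 2); for each ALT k
    the dosage counts alleles equal to k+1, with any call involving a
    *different* ALT set to missing (the compound-het removal contract).
    Returns (variant_id, dosage vector) per ALT.
    """
    out = []
    for k, alt in enumerate(alts):
        allele = k + 1
        a = genotypes.astype(float)
        other_alt = (a > 0) & (a != allele)
        dos = (a == allele).sum(axis=1).astype(float)
        dos[np.any(other_alt, axis=1)] = np.nan
        dos[np.any(np.isnan(a) | (a < 0), axis=1)] = np.nan
        out.append((f"{chrom}_{pos}_{ref}_{alt}", dos))
    return out
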
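"""Hierarchical prioritization of candidate variants driving expression outliers.

For each outlier (sample, gene, tissue) the workflow searches the sample's
variants near the gene and assigns exactly one category by first match, in
fixed precedence: coding structural variants (whole gene, then any exon),
high-impact loss-of-function SNVs, then regulatory candidates within 10 kb
of the gene body (SV/CNV or rare SNV in an eye cCRE, then in a non-eye
cCRE), then non-coding structural variants (intronic, then any within
10 kb), and finally the no-candidate categories.  Output is a JSON-ready
mapping from outlier id to category, tier and candidate list.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

from .outliers import OutlierEvent
from .types import CcreSet, GeneAnnotation

HIGH_IMPACT_CONSEQUENCES = {
    "stop_gained",
    "frameshift_variant",
    "start_lost",
    "stop_lost",
    "splice_donor_variant",
    "splice_acceptor_variant",
}

RARE_AF_THRESHOLD = 0.01
GENE_PAD_BP = 10_000


class Category(str, Enum):
    SV_CNV_WHOLE_GENE = "SV_CNV_intersect_whole_gene"
    SV_CNV_EXON = "SV_CNV_intersect_exon"
    HIGH_IMPACT_SNV = "High_impact_SNV_disrupt_gene"
    SV_CNV_EYE_CCRE = "SV_CNV_intersect_Eye_cCRE"
    RARE_SNV_EYE_CCRE = "Rare_SNV_Intersect_Eye_cCRE"
    SV_CNV_EPIMAP_CCRE = "SV_CNV_intersect_EpiMap_cCRE"
    RARE_SNV_EPIMAP_CCRE = "Rare_SNV_Intersect_EpiMap_cCRE"
    SV_CNV_INTRON = "SV_CNV_intersect_intron"
    SV_CNV_NEAR_GENE = "SV_CNV_within_10Kb_gene_body"
    COMMON_SNV_CCRE = "Common_SNV_Intersect_cCRE"
    NO_CANDIDATE = "No_SV_or_SNV_of_interest"


TIER_OF_CATEGORY = {
    Category.SV_CNV_WHOLE_GENE: "pLoF variant",
    Category.SV_CNV_EXON: "pLoF variant",
    Category.HIGH_IMPACT_SNV: "pLoF variant",
    Category.SV_CNV_EYE_CCRE: "Regulatory variant",
    Category.RARE_SNV_EYE_CCRE: "Regulatory variant",
    Category.SV_CNV_EPIMAP_CCRE: "Regulatory variant",
    Category.RARE_SNV_EPIMAP_CCRE: "Regulatory variant",
    Category.SV_CNV_INTRON: "Non-coding structural variant",
    Category.SV_CNV_NEAR_GENE: "Non-coding structural variant",
    Category.COMMON_SNV_CCRE: "No candidate variant",
    Category.NO_CANDIDATE: "No candidate variant",
}


@dataclass
class AnnotatedVariant:
    """A sample-carried variant with the annotations the workflow consumes."""

    variant_id: str
    kind: str  # snv_indel | sv | cnv
    chrom: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive (== start for a SNV)
    consequence: str = "unknown"
    population_af: float | None = None
    sample_genotype: str = "0/1"

    @property
    def is_rare(self) -> bool:
        """Rare iff population AF < 1% or absent from the reference table."""
        return self.population_af is None or self.population_af < RARE_AF_THRESHOLD

    def to_dict(self) -> dict:
        return {
            "variant_id": self.variant_id,
            "kind": self.kind,
            "chrom": self.chrom,
            "start": self.start,
            "end": self.end,
            "consequence": self.consequence,
            "population_af": self.population_af,
            "sample_genotype": self.sample_genotype,
        }


@dataclass
class PrioritizationResult:
    outlier_id: str
    category: Category
    candidate_variants: list[AnnotatedVariant] = field(default_factory=list)
    outlier_metrics: dict = field(default_factory=dict)

    @property
    def tier(self) -> str:
        return TIER_OF_CATEGORY[self.category]


def extract_sample_rare_variants(
    variant_table: pd.DataFrame,
    sample_id: str,
    gene_body: tuple[str, int, int],
    pad: int = GENE_PAD_BP,
    af_threshold: float = RARE_AF_THRESHOLD,
) -> list[AnnotatedVariant]:
    """Sample-carried SNV/indels within gene body ± pad, flagged rare by AF.

    ``variant_table`` columns: variant_id, sample_id, chrom, pos, consequence
    (optional), population_af (optional, NaN = absent).  Variants lacking an
    annotation row keep consequence "unknown".  The window is inclusive at
    both padded bounds.  Raises if the sample has no rows at all.
    """
    if sample_id not in set(variant_table["sample_id"]):
        raise ValueError(f"sample {sample_id!r} absent from variant table")
    chrom, body_start, body_end = gene_body
    sub = variant_table[
        (variant_table["sample_id"] == sample_id)
        & (variant_table["chrom"].astype(str) == str(chrom))
        & (variant_table["pos"] >= body_start - pad)
        & (variant_table["pos"] <= body_end + pad)
    ]
    out = []
    for row in sub.itertuples():
        af = getattr(row, "population_af", None)
        if af is not None and (isinstance(af, float) and np.isnan(af)):
            af = None
        consequence = getattr(row, "consequence", "unknown") or "unknown"
        out.append(
            AnnotatedVariant(
                variant_id=row.variant_id,
                kind="snv_indel",
                chrom=str(row.chrom),
                start=int(row.pos),
                end=int(row.pos),
                consequence=str(consequence),
                population_af=None if af is None else float(af),
            )
        )
    return out


def _spans_overlap(a_start: int, a_end: int, b_start: int, b_end: int) -> bool:
    """1-based inclusive range intersection."""
    return a_start <= b_end and b_start <= a_end


def _overlaps_ccres(var: AnnotatedVariant, ccres: CcreSet, near: tuple[str, int, int]) -> bool:
    """Variant overlaps any cCRE interval that lies within the padded window."""
    chrom, win_start, win_end = near
    t = ccres.table
    sub = t[t["chrom"].astype(str) == str(chrom)]
    for s0, e0 in zip(sub["start"], sub["end"]):
        s1, e1 = int(s0) + 1, int(e0)  # 0-based half-open -> 1-based inclusive
        if not _spans_overlap(s1, e1, win_start, win_end):
            continue
        if var.chrom == str(chrom) and _spans_overlap(var.start, var.end, s1, e1):
            return True
    return False


def _introns(body_start: int, body_end: int, exons: list[tuple[int, int]]) -> list[tuple[int, int]]:
    if not exons:
        return []
    exons = sorted(exons)
    introns = []
    for (s1, e1), (s2, _) in zip(exons, exons[1:]):
        if s2 > e1 + 1:
            introns.append((e1 + 1, s2 - 1))
    return introns


def prioritize(
    outlier: OutlierEvent,
    sample_svs: list[AnnotatedVariant],
    sample_snvs: list[AnnotatedVariant],
    eye_ccres: CcreSet,
    non_eye_ccres: CcreSet,
    gene_annot: GeneAnnotation,
    require_rare_high_impact: bool = False,
) -> PrioritizationResult:
    """Assign one category to an outlier by first-match precedence.

    Rules in order: SV/CNV covering the whole gene body; SV/CNV overlapping
    an exon; high-impact SNV in the gene; SV/CNV then rare SNV in an eye
    cCRE within 10 kb; SV/CNV then rare SNV in a non-eye cCRE within 10 kb;
    SV/CNV in an intron; SV/CNV anywhere within 10 kb; common SNV in any
    cCRE (no candidate); otherwise no variant of interest.  All variants
    satisfying the winning rule become candidates.
    """
    gene_id = outlier.gene_id
    if gene_id not in gene_annot.table.index:
        raise ValueError(f"gene {gene_id!r} missing from annotation")
    row = gene_annot.table.loc[gene_id]
    exons = gene_annot.exons.get(gene_id)
    if not exons:
        raise ValueError(f"gene {gene_id!r} has no exon spans in the annotation")
    chrom, body_start, body_end = str(row.chrom), int(row.start), int(row.end)
    window = (chrom, body_start - GENE_PAD_BP, body_end + GENE_PAD_BP)

    svs = [v for v in sample_svs if v.chrom == chrom and _spans_overlap(
        v.start, v.end, *window[1:])]
    snvs = [v for v in sample_snvs if v.chrom == chrom and _spans_overlap(
        v.start, v.end, *window[1:])]

    metrics = {"z": outlier.z, "log2_fold": outlier.log2_fold, "p_adj": outlier.p_adj}
    oid = f"{outlier.sample_id}-{gene_id}-{outlier.tissue}"

    def result(cat: Category, cands: list[AnnotatedVariant]) -> PrioritizationResult:
        cands = sorted(cands, key=lambda v: v.variant_id)
        return PrioritizationResult(oid, cat, cands, metrics)

    hits = [v for v in svs if v.start <= body_start and v.end >= body_end]
    if hits:
        return result(Category.SV_CNV_WHOLE_GENE, hits)

    hits = [v for v in svs if any(_spans_overlap(v.start, v.end, es, ee) for es, ee in exons)]
    if hits:
        return result(Category.SV_CNV_EXON, hits)

    hits = [
        v for v in snvs
        if v.consequence in HIGH_IMPACT_CONSEQUENCES
        and _spans_overlap(v.start, v.end, body_start, body_end)
        and (v.is_rare or not require_rare_high_impact)
    ]
    if hits:
        return result(Category.HIGH_IMPACT_SNV, hits)

    hits = [v for v in svs if _overlaps_ccres(v, eye_ccres, window)]
    if hits:
        return result(Category.SV_CNV_EYE_CCRE, hits)

    hits = [v for v in snvs if v.is_rare and _overlaps_ccres(v, eye_ccres, window)]
    if hits:
        return result(Category.RARE_SNV_EYE_CCRE, hits)

    hits = [v for v in svs if _overlaps_ccres(v, non_eye_ccres, window)]
    if hits:
        return result(Category.SV_CNV_EPIMAP_CCRE, hits)

    hits = [v for v in snvs if v.is_rare and _overlaps_ccres(v, non_eye_ccres, window)]
    if hits:
        return result(Category.RARE_SNV_EPIMAP_CCRE, hits)

    introns = _introns(body_start, body_end, exons)
    hits = [
        v for v in svs
        if any(_spans_overlap(v.start, v.end, s, e) for s, e in introns)
    ]
    if hits:
        return result(Category.SV_CNV_INTRON, hits)

    if svs:
        return result(Category.SV_CNV_NEAR_GENE, svs)

    common_ccre = [
        v for v in snvs
        if not v.is_rare
        and (_overlaps_ccres(v, eye_ccres, window) or _overlaps_ccres(v, non_eye_ccres, window))
    ]
    if common_ccre:
        return result(Category.COMMON_SNV_CCRE, [])

    return result(Category.NO_CANDIDATE, [])


def summarize_prioritization(results: list[PrioritizationResult]) -> pd.DataFrame:
    """Counts and fractions per category and per tier."""
    n = len(results)
    rows = []
    for cat in Category:
        count = sum(1 for r in results if r.category == cat)
        rows.append(
            {
                "category": cat.value,
                "tier": TIER_OF_CATEGORY[cat],
                "count": count,
                "fraction": count / n if n else 0.0,
            }
        )
    return pd.DataFrame(rows)


def results_to_json(results: list[PrioritizationResult]) -> str:
    """Serialize to the JSON object keyed by outlier id."""
    obj = {
        r.outlier_id: {
            "category": r.category.value,
            "tier": r.tier,
            "candidates": [v.to_dict() for v in r.candidate_variants],
            "metrics": r.outlier_metrics,
        }
        for r in results
    }
    return json.dumps(obj, indent=2, sort_keys=True)
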
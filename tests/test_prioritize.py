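import json

import numpy as np
import pandas as pd
import pytest

from retqtl.outliers import OutlierEvent
from retqtl.prioritize import (
    AnnotatedVariant,
    Category,
    PrioritizationResult,
    extract_sample_rare_variants,
    prioritize,
    results_to_json,
    summarize_prioritization,
)
from retqtl.types import CcreSet, GeneAnnotation

# gene model: body 10_000..30_000 with three exons and two introns
GENE = "GENE_T"


@pytest.fixture
def gene_annot():
    table = pd.DataFrame(
        [{"gene_id": GENE, "chrom": "1", "strand": "+", "tss": 10_000,
          "start": 10_000, "end": 30_000}]
    ).set_index("gene_id")
    exons = {GENE: [(10_000, 12_000), (18_000, 20_000), (28_000, 30_000)]}
    return GeneAnnotation(table=table, exons=exons)


@pytest.fixture
def eye_ccres():
    return CcreSet(pd.DataFrame({
        "chrom": ["1"], "start": [6_999], "end": [7_500],  # ~3 kb upstream
        "ccre_class": ["promoter"], "tissue_tag": ["eye"],
    }))


@pytest.fixture
def non_eye_ccres():
    return CcreSet(pd.DataFrame({
        "chrom": ["1"], "start": [33_999], "end": [34_500],
        "ccre_class": ["proximal_enhancer"], "tissue_tag": ["non_eye"],
    }))


def _outlier():
    return OutlierEvent("S1", GENE, "NSR", -6.0, -3.0, 1e-7, 1e-5)


def _sv(start, end, kind="sv"):
    return AnnotatedVariant(f"SV_1_{start}_{end}", kind, "1", start, end,
                            consequence="structural_variant")


def _snv(pos, consequence="intron_variant", af=None):
    return AnnotatedVariant(f"1_{pos}_A_G", "snv_indel", "1", pos, pos,
                            consequence=consequence, population_af=af)


class TestPrecedence:
    def test_whole_gene_sv_wins_over_everything(self, gene_annot, eye_ccres, non_eye_ccres):
        svs = [_sv(9_000, 31_000)]
        snvs = [_snv(7_200, "upstream_gene_variant", af=0.001)]  # eye cCRE hit too
        res = prioritize(_outlier(), svs, snvs, eye_ccres, non_eye_ccres, gene_annot)
        assert res.category == Category.SV_CNV_WHOLE_GENE
        assert len(res.candidate_variants) == 1

    def test_exon_sv(self, gene_annot, eye_ccres, non_eye_ccres):
        res = prioritize(_outlier(), [_sv(17_500, 18_500)], [], eye_ccres,
                         non_eye_ccres, gene_annot)
        assert res.category == Category.SV_CNV_EXON

    def test_high_impact_snv(self, gene_annot, eye_ccres, non_eye_ccres):
        snvs = [_snv(11_000, "stop_gained", af=0.002)]
        res = prioritize(_outlier(), [], snvs, eye_ccres, non_eye_ccres, gene_annot)
        assert res.category == Category.HIGH_IMPACT_SNV
        assert res.tier == "pLoF variant"

    def test_missense_is_not_high_impact(self, gene_annot, eye_ccres, non_eye_ccres):
        snvs = [_snv(11_000, "missense_variant", af=0.002)]
        res = prioritize(_outlier(), [], snvs, eye_ccres, non_eye_ccres, gene_annot)
        assert res.category == Category.NO_CANDIDATE

    def test_sv_in_eye_ccre(self, gene_annot, eye_ccres, non_eye_ccres):
        res = prioritize(_outlier(), [_sv(7_100, 7_300)], [], eye_ccres,
                         non_eye_ccres, gene_annot)
        assert res.category == Category.SV_CNV_EYE_CCRE

    def test_rare_snv_in_eye_promoter_upstream(self, gene_annot, eye_ccres, non_eye_ccres):
        snvs = [_snv(7_200, "upstream_gene_variant", af=0.0005)]
        res = prioritize(_outlier(), [], snvs, eye_ccres, non_eye_ccres, gene_annot)
        assert res.category == Category.RARE_SNV_EYE_CCRE
        assert res.tier == "Regulatory variant"

    def test_rare_snv_in_non_eye_ccre(self, gene_annot, eye_ccres, non_eye_ccres):
        snvs = [_snv(34_200, "regulatory_region_variant", af=None)]  # absent → rare
        res = prioritize(_outlier(), [], snvs, eye_ccres, non_eye_ccres, gene_annot)
        assert res.category == Category.RARE_SNV_EPIMAP_CCRE

    def test_eye_ccre_precedes_non_eye(self, gene_annot, eye_ccres, non_eye_ccres):
        snvs = [_snv(7_200, af=0.001), _snv(34_200, af=0.001)]
        res = prioritize(_outlier(), [], snvs, eye_ccres, non_eye_ccres, gene_annot)
        assert res.category == Category.RARE_SNV_EYE_CCRE

    def test_intronic_sv(self, gene_annot, eye_ccres, non_eye_ccres):
        res = prioritize(_outlier(), [_sv(13_000, 14_000)], [], eye_ccres,
                         non_eye_ccres, gene_annot)
        assert res.category == Category.SV_CNV_INTRON
        assert res.tier == "Non-coding structural variant"

    def test_sv_near_gene_body(self, gene_annot, eye_ccres, non_eye_ccres):
        res = prioritize(_outlier(), [_sv(31_000, 32_000)], [], eye_ccres,
                         non_eye_ccres, gene_annot)
        assert res.category == Category.SV_CNV_NEAR_GENE

    def test_common_snv_in_ccre_no_candidate_listed(self, gene_annot, eye_ccres,
                                                    non_eye_ccres):
        snvs = [_snv(7_200, af=0.25)]
        res = prioritize(_outlier(), [], snvs, eye_ccres, non_eye_ccres, gene_annot)
        assert res.category == Category.COMMON_SNV_CCRE
        assert res.candidate_variants == []
        assert res.tier == "No candidate variant"

    def test_nothing_of_interest(self, gene_annot, eye_ccres, non_eye_ccres):
        snvs = [_snv(25_000, "intron_variant", af=0.001)]  # intronic SNV: no rule
        res = prioritize(_outlier(), [], snvs, eye_ccres, non_eye_ccres, gene_annot)
        assert res.category == Category.NO_CANDIDATE

    def test_variant_order_irrelevant(self, gene_annot, eye_ccres, non_eye_ccres):
        svs = [_sv(31_000, 32_000), _sv(17_500, 18_500)]
        r1 = prioritize(_outlier(), svs, [], eye_ccres, non_eye_ccres, gene_annot)
        r2 = prioritize(_outlier(), svs[::-1], [], eye_ccres, non_eye_ccres, gene_annot)
        assert r1.category == r2.category == Category.SV_CNV_EXON

    def test_variants_beyond_10kb_ignored(self, gene_annot, eye_ccres, non_eye_ccres):
        res = prioritize(_outlier(), [_sv(41_000, 42_000)], [], eye_ccres,
                         non_eye_ccres, gene_annot)
        assert res.category == Category.NO_CANDIDATE

    def test_missing_exons_rejected(self, eye_ccres, non_eye_ccres):
        table = pd.DataFrame(
            [{"gene_id": GENE, "chrom": "1", "strand": "+", "tss": 10_000,
              "start": 10_000, "end": 30_000}]).set_index("gene_id")
        annot = GeneAnnotation(table=table, exons={})
        with pytest.raises(ValueError, match="exon"):
            prioritize(_outlier(), [], [], eye_ccres, non_eye_ccres, annot)


class TestExtractSampleRareVariants:
    def _table(self):
        return pd.DataFrame([
            {"variant_id": "1_5000_A_G", "sample_id": "S1", "chrom": "1",
             "pos": 5_000, "consequence": "intergenic_variant", "population_af": 0.001},
            {"variant_id": "1_20000_C_T", "sample_id": "S1", "chrom": "1",
             "pos": 20_000, "consequence": "missense_variant", "population_af": np.nan},
            {"variant_id": "1_40000_G_A", "sample_id": "S1", "chrom": "1",
             "pos": 40_000, "consequence": "intergenic_variant", "population_af": 0.001},
            {"variant_id": "1_20500_G_C", "sample_id": "S2", "chrom": "1",
             "pos": 20_500, "consequence": "synonymous_variant", "population_af": 0.01},
        ])

    def test_pad_boundary_inclusive(self):
        out = extract_sample_rare_variants(self._table(), "S1", ("1", 10_000, 30_000))
        ids = {v.variant_id for v in out}
        assert "1_40000_G_A" in ids  # body_end + 10 kb exactly
        assert "1_5000_A_G" in ids
        out2 = extract_sample_rare_variants(
            self._table(), "S1", ("1", 10_000, 29_999))
        assert "1_40000_G_A" not in {v.variant_id for v in out2}

    def test_af_exactly_001_not_rare_and_absent_is_rare(self):
        out = extract_sample_rare_variants(self._table(), "S2", ("1", 10_000, 30_000))
        assert not out[0].is_rare  # AF = 0.01 exactly
        out1 = extract_sample_rare_variants(self._table(), "S1", ("1", 10_000, 30_000))
        absent = next(v for v in out1 if v.variant_id == "1_20000_C_T")
        assert absent.is_rare

    def test_unknown_sample_rejected(self):
        with pytest.raises(ValueError):
            extract_sample_rare_variants(self._table(), "SX", ("1", 1, 100))


class TestSummary:
    def test_empty_all_zero(self):
        out = summarize_prioritization([])
        assert (out["count"] == 0).all()

    def test_one_result_per_category_tier_counts(self):
        results = [
            PrioritizationResult(f"o{i}", cat, [], {})
            for i, cat in enumerate(Category)
        ]
        out = summarize_prioritization(results)
        assert out["count"].sum() == len(list(Category))
        tiers = out.groupby("tier")["count"].sum()
        assert tiers["pLoF variant"] == 3
        assert tiers["Regulatory variant"] == 4
        assert tiers["Non-coding structural variant"] == 2
        assert tiers["No candidate variant"] == 2

    def test_json_output_keyed_by_outlier_id(self):
        res = PrioritizationResult(
            "S1-GENE_T-NSR", Category.HIGH_IMPACT_SNV,
            [AnnotatedVariant("1_11000_A_G", "snv_indel", "1", 11_000, 11_000,
                              "stop_gained", 0.001)],
            {"z": -6.0},
        )
        obj = json.loads(results_to_json([res]))
        assert obj["S1-GENE_T-NSR"]["category"] == "High_impact_SNV_disrupt_gene"
        assert obj["S1-GENE_T-NSR"]["tier"] == "pLoF variant"
        assert obj["S1-GENE_T-NSR"]["candidates"][0]["variant_id"] == "1_11000_A_G"
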
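import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from retqtl.expression import tmm_effective_factors
from retqtl.qc import apply_site_filters, hwe_exact_test
from retqtl.sim import (
    SimConfig,
    TruthTable,
    _records_from_matrix,
    plant_outliers,
    read_fixture_bundle,
    simulate_ccres,
    simulate_cohort,
    simulate_expression,
    simulate_gene_annotation,
    simulate_genotypes,
    write_fixture_bundle,
)


class TestSimConfig:
    def test_invalid_chromosome_length_rejected(self):
        with pytest.raises(ValueError, match="length"):
            SimConfig(genome=[("1", 0)])

    def test_effect_range_capped(self):
        with pytest.raises(ValueError):
            SimConfig(afc_effect_range=(0.5, 7.0))

    def test_zero_samples_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(n_samples=0)


class TestSimulateGenotypes:
    def test_fixed_half_maf_mean_dosage_near_one(self):
        cfg = SimConfig(n_samples=10_000, genome=[("1", 500_000)],
                        variant_density=0.1, maf_beta=(1, 1),
                        maf_range=(0.5, 0.5), missing_rate=0.0, seed=0)
        geno = simulate_genotypes(cfg)
        means = np.nanmean(geno.dosages, axis=0)
        assert np.all(np.abs(means - 1.0) <= 0.05)

    def test_deterministic_given_seed(self):
        cfg = SimConfig(seed=11)
        g1 = simulate_genotypes(cfg)
        g2 = simulate_genotypes(cfg)
        assert g1.variant_ids == g2.variant_ids
        assert np.array_equal(g1.dosages, g2.dosages, equal_nan=True)

    def test_sites_consistent_with_hwe_filter(self):
        cfg = SimConfig(n_samples=200, genome=[("1", 10_000_000)],
                        variant_density=0.1, missing_rate=0.0, seed=1)
        geno = simulate_genotypes(cfg)
        n_pass = 0
        for j in range(geno.n_variants):
            d = geno.dosages[:, j]
            counts = (int((d == 0).sum()), int((d == 1).sum()), int((d == 2).sum()))
            if hwe_exact_test(*counts) > 1e-8:
                n_pass += 1
        assert n_pass / geno.n_variants >= 0.99

    def test_variant_id_format(self):
        geno = simulate_genotypes(SimConfig(seed=2))
        chrom, pos, ref, alt = geno.variant_ids[0].split("_")
        assert int(pos) >= 1
        assert ref in "ACGT" and alt in "ACGT" and ref != alt


class TestSimulateExpression:
    def test_null_model_slope_ci_covers_zero(self):
        cfg = SimConfig(n_samples=200, n_genes=50, n_planted_eqtls=0,
                        n_hidden_factors=0, seed=3)
        geno = simulate_genotypes(cfg)
        annot = simulate_gene_annotation(cfg)
        bundle, truth = simulate_expression(geno, annot, cfg)
        rng = np.random.default_rng(0)
        covered = 0
        tested = 0
        for gene in bundle.gene_ids:
            j = int(rng.integers(geno.n_variants))
            d = geno.dosages[:, j]
            ok = ~np.isnan(d)
            y = np.log1p(bundle.counts.loc[gene].to_numpy()[ok])
            x = d[ok]
            if np.std(x) == 0:
                continue
            slope, se = _ols_slope_se(x, y)
            tested += 1
            covered += abs(slope) <= 1.96 * se
        assert covered / tested >= 0.94

    def test_planted_effect_group_mean_ratio(self):
        cfg = SimConfig(n_samples=200, n_genes=30, n_hidden_factors=0,
                        nb_dispersion=0.05, seed=4)
        geno = simulate_genotypes(cfg)
        annot = simulate_gene_annotation(cfg)
        # pick a common variant near gene 0 and plant k = 1 explicitly
        row = annot.table.iloc[0]
        af = geno.allele_frequency()
        maf = np.minimum(af, 1 - af)
        cands = np.flatnonzero(
            (np.array(geno.chrom) == row.chrom)
            & (np.abs(geno.pos - int(row.tss)) <= 1_000_000) & (maf >= 0.4)
        )
        vid = geno.variant_ids[int(cands[0])]
        bundle, truth = simulate_expression(
            geno, annot, cfg, planted_eqtls=[(annot.table.index[0], vid, 1.0)]
        )
        d = geno.dosages[:, geno.variant_index()[vid]]
        counts = bundle.counts.iloc[0].to_numpy()
        m0 = counts[d == 0].mean()
        m2 = counts[d == 2].mean()
        assert 1.7 <= m2 / m0 <= 2.3

    def test_effect_semantics_converge_at_large_n(self):
        # enough genes that the planted gene's library share is negligible:
        # counts are compositional (column sums fixed at the library size),
        # so a dominant gene would attenuate its own group-mean ratio
        cfg = SimConfig(n_samples=2000, n_genes=150, n_hidden_factors=0,
                        nb_dispersion=0.02, genome=[("1", 4_000_000)],
                        variant_density=0.05, seed=5)
        geno = simulate_genotypes(cfg)
        annot = simulate_gene_annotation(cfg)
        row = annot.table.iloc[0]
        maf = np.minimum(geno.allele_frequency(), 1 - geno.allele_frequency())
        cands = np.flatnonzero(maf >= 0.4)
        vid = geno.variant_ids[int(cands[0])]
        bundle, _ = simulate_expression(
            geno, annot, cfg, planted_eqtls=[(annot.table.index[0], vid, 1.0)]
        )
        d = geno.dosages[:, geno.variant_index()[vid]]
        counts = bundle.counts.iloc[0].to_numpy()
        ratio = counts[d == 2].mean() / counts[d == 0].mean()
        assert ratio == pytest.approx(2.0, rel=0.03)

    def test_planted_variant_outside_cis_window_rejected(self):
        cfg = SimConfig(seed=6)
        geno = simulate_genotypes(cfg)
        annot = simulate_gene_annotation(cfg)
        gene0 = annot.table.index[0]
        far = [v for v, c in zip(geno.variant_ids, geno.chrom)
               if c != annot.table.loc[gene0].chrom][0]
        with pytest.raises(ValueError, match="cis"):
            simulate_expression(geno, annot, cfg, planted_eqtls=[(gene0, far, 1.0)])

    def test_doubled_library_sizes_corrected_by_tmm(self):
        cfg = SimConfig(n_samples=100, n_genes=200, n_planted_eqtls=0,
                        n_hidden_factors=0, nb_dispersion=0.02, seed=7)
        geno = simulate_genotypes(cfg)
        annot = simulate_gene_annotation(
            SimConfig(n_genes=200, seed=7, genome=cfg.genome))
        bundle, _ = simulate_expression(geno, annot, cfg)
        counts = bundle.counts.copy()
        half = counts.columns[:50]
        counts[half] = counts[half] * 2  # doubled depth for half the cohort
        eff = tmm_effective_factors(counts)
        cpm = counts / eff * 1e6
        mean_a = cpm[half].mean(axis=1)
        mean_b = cpm[counts.columns[50:]].mean(axis=1)
        ratio = (mean_a / mean_b).median()
        assert ratio == pytest.approx(1.0, abs=0.05)


class TestCcres:
    def test_empty_class_list(self):
        cfg = SimConfig(seed=8)
        annot = simulate_gene_annotation(cfg)
        ccres = simulate_ccres(cfg, annot, classes=())
        assert len(ccres.table) == 0

    def test_non_overlapping_within_class(self):
        cfg = SimConfig(seed=9)
        annot = simulate_gene_annotation(cfg)
        ccres = simulate_ccres(cfg, annot)
        for (cls, chrom), sub in ccres.table.groupby(["ccre_class", "chrom"]):
            s = sub.sort_values("start")
            assert (s["start"].to_numpy()[1:] >= s["end"].to_numpy()[:-1]).all()

    def test_classes_and_tags_controlled(self):
        cfg = SimConfig(seed=10)
        annot = simulate_gene_annotation(cfg)
        ccres = simulate_ccres(cfg, annot)
        assert set(ccres.table.ccre_class) <= set(ccres.CLASSES)
        assert set(ccres.table.tissue_tag) <= {"eye", "non_eye"}


class TestBundleRoundTrip:
    def test_bundle_bytes_deterministic(self, tmp_path):
        for run in ("a", "b"):
            write_fixture_bundle(simulate_cohort(SimConfig(seed=12)), tmp_path / run)
        for p in sorted((tmp_path / "a").iterdir()):
            assert (hashlib.md5(p.read_bytes()).hexdigest()
                    == hashlib.md5((tmp_path / "b" / p.name).read_bytes()).hexdigest())

    def test_round_trip_content(self, tmp_path):
        cohort = simulate_cohort(SimConfig(seed=13))
        write_fixture_bundle(cohort, tmp_path)
        back = read_fixture_bundle(tmp_path)
        pd.testing.assert_frame_equal(
            back["counts.NSR"], cohort.bundles["NSR"].counts, check_dtype=False)
        assert len(back["vcf_records"]) == cohort.geno.n_variants
        rec = back["vcf_records"][0]
        j = cohort.geno.variant_index()[rec.variant_id]
        assert np.array_equal(rec.dosages, cohort.geno.dosages[:, j], equal_nan=True)
        truth = back["truth"]["NSR"]
        assert len(truth["planted_eqtls"]) == len(cohort.truths["NSR"].planted_eqtls)

    def test_generator_survives_qc_with_low_site_loss(self):
        cohort = simulate_cohort(SimConfig(seed=14))
        geno_qc, qc = apply_site_filters(_records_from_matrix(cohort.geno))
        loss = 1 - geno_qc.n_variants / cohort.geno.n_variants
        assert loss < 0.02


class TestPlantOutliers:
    def test_high_impact_snv_inside_exon(self):
        cohort = simulate_cohort(SimConfig(seed=15))
        truth = cohort.truths["NSR"]
        rec = next(o for o in truth.planted_outliers
                   if o["causal_category"] == "High_impact_SNV_disrupt_gene")
        row = cohort.snv_table[cohort.snv_table.variant_id == rec["causal_variant_id"]]
        assert row.iloc[0]["consequence"] == "stop_gained"
        exons = cohort.gene_annot.exons[rec["gene_id"]]
        pos = int(row.iloc[0]["pos"])
        assert any(s <= pos <= e for s, e in exons)
        assert np.isnan(row.iloc[0]["population_af"])  # absent → rare

    def test_rare_eye_ccre_snv_inside_tagged_interval_within_10kb(self):
        cohort = simulate_cohort(SimConfig(seed=16))
        truth = cohort.truths["NSR"]
        rec = next(o for o in truth.planted_outliers
                   if o["causal_category"] == "Rare_SNV_Intersect_Eye_cCRE")
        pos = int(rec["causal_variant_id"].split("_")[1])
        g = cohort.gene_annot.table.loc[rec["gene_id"]]
        eye = cohort.ccres.subset(tissue_tag="eye").table
        hit = eye[(eye.chrom == g.chrom) & (eye.start < pos) & (pos <= eye.end)]
        assert len(hit) == 1
        assert g.start - 10_000 <= pos <= g.end + 10_000

    def test_unsatisfiable_category_rejected(self):
        cfg = SimConfig(seed=17)
        rng = np.random.default_rng(0)
        geno = simulate_genotypes(cfg, rng)
        annot = simulate_gene_annotation(cfg)
        ccres = simulate_ccres(cfg, annot, classes=())  # no cCREs at all
        bundle, truth = simulate_expression(geno, annot, cfg)
        from retqtl.prioritize import Category
        with pytest.raises(ValueError, match="category"):
            plant_outliers(bundle, geno, ccres, cfg, truth,
                           categories=[Category.RARE_SNV_EYE_CCRE])


def _ols_slope_se(x, y):
    x = x - x.mean()
    y = y - y.mean()
    sxx = (x**2).sum()
    slope = (x * y).sum() / sxx
    resid = y - slope * x
    se = np.sqrt((resid**2).sum() / (len(x) - 2) / sxx)
    return slope, se
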
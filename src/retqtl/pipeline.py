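"""End-to-end orchestration of the cohort analysis.

Chains the stages on a synthetic cohort: site QC, expression normalization
and covariates, per-tissue cis-eQTL mapping, cross-tissue comparison, cCRE
enrichment of eVariants, expression-outlier calling and hierarchical
variant prioritization.  Used by the numbered analysis drivers and by the
end-to-end tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import expression as xp
from .compare import intersect_eqtl_sets, iou, make_keys
from .enrichment import bootstrap_enrichment, gene_density_vector
from .eqtl import CisMapResult, map_cis
from .outliers import OutlierEvent, call_expression_outliers, cross_tissue_share
from .prioritize import (
    AnnotatedVariant,
    PrioritizationResult,
    extract_sample_rare_variants,
    prioritize,
)
from .qc import apply_site_filters, eqtl_eligible_variants
from .sim import Cohort, SimConfig, simulate_cohort
from .types import CcreSet, GenotypeMatrix


@dataclass
class TissueAnalysis:
    tissue: str
    normalized: pd.DataFrame
    covariates: pd.DataFrame
    cis: CisMapResult
    outliers: list[OutlierEvent]


@dataclass
class PipelineResult:
    cohort: Cohort
    geno_qc: GenotypeMatrix
    tissues: dict[str, TissueAnalysis]
    enrichment: list
    prioritization: list[PrioritizationResult]
    comparison: dict

    def summary(self) -> dict:
        out: dict = {"n_samples": self.cohort.geno.n_samples,
                     "n_variants_post_qc": self.geno_qc.n_variants}
        for t, ta in self.tissues.items():
            out[f"egenes_{t}"] = len(ta.cis.egenes)
            out[f"eqtls_{t}"] = len(ta.cis.eqtls)
            out[f"outlier_events_{t}"] = len(ta.outliers)
        out.update(self.comparison)
        return out


def prepare_tissue(
    cohort: Cohort, tissue: str, n_hidden: int = 10
) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Filter, normalize and build covariates for one tissue."""
    b = cohort.bundles[tissue]
    genes = xp.filter_expressed_genes(b.counts, b.tpm)
    norm = xp.normalize_expression(b.counts.loc[genes], b.tpm.loc[genes])
    k = min(n_hidden, min(norm.shape) - 1)
    hidden = xp.hidden_factors(norm, k=k)
    gpcs = xp.genotype_pcs(cohort.geno.dosages, cohort.geno.sample_ids, k=5)
    cov = xp.build_covariates(
        cohort.covariates_raw["sex"], cohort.covariates_raw["batch"], gpcs, hidden
    )
    return norm, cov, genes


def sv_variants_for_sample(sv_table: pd.DataFrame, sample_id: str) -> list[AnnotatedVariant]:
    out = []
    for r in sv_table.itertuples():
        if r.sample_id != sample_id:
            continue
        out.append(
            AnnotatedVariant(
                variant_id=f"SV_{r.chrom}_{r.start}_{r.end}_{r.sv_type}",
                kind="cnv" if str(r.sv_type) == "CNV" else "sv",
                chrom=str(r.chrom),
                start=int(r.start),
                end=int(r.end),
                consequence="structural_variant",
                sample_genotype=str(r.genotype),
            )
        )
    return out


def run_pipeline(
    cfg: SimConfig | None = None,
    seed: int = 0,
    n_permutations: int = 500,
    n_enrichment_iter: int = 500,
    fdr: float = 0.05,
) -> PipelineResult:
    """Simulate a cohort and run every analysis stage on it."""
    cfg = cfg or SimConfig(seed=seed)
    cohort = simulate_cohort(cfg)
    rng = np.random.default_rng(seed + 101)

    # --- genotype QC and eligibility
    from .sim import _records_from_matrix

    geno_qc, _ = apply_site_filters(_records_from_matrix(cohort.geno))
    eligible = eqtl_eligible_variants(geno_qc)
    geno_elig = geno_qc.subset_variants(sorted(eligible, key=geno_qc.variant_index().get))

    tissues: dict[str, TissueAnalysis] = {}
    for tissue in cohort.bundles:
        norm, cov, genes = prepare_tissue(cohort, tissue)
        cis = map_cis(
            norm, geno_elig, cov, cohort.bundles[tissue].gene_annot,
            afc_expression=cohort.bundles[tissue].tpm.loc[genes],
            n_permutations=n_permutations, fdr=fdr,
            seed=int(rng.integers(2**31)),
        )
        events = call_expression_outliers(cohort.bundles[tissue].counts, tissue=tissue)
        tissues[tissue] = TissueAnalysis(tissue, norm, cov, cis, events)

    # --- cross-tissue comparison
    comparison: dict = {}
    names = list(tissues)
    if len(names) >= 2:
        a, b = names[0], names[1]
        keys_a = make_keys(tissues[a].cis.eqtl_frame()) if tissues[a].cis.eqtls else set()
        keys_b = make_keys(tissues[b].cis.eqtl_frame()) if tissues[b].cis.eqtls else set()
        if keys_a or keys_b:
            shared, only_a, only_b = intersect_eqtl_sets(keys_a, keys_b)
            comparison["shared_eqtls"] = len(shared)
            comparison["eqtl_iou"] = iou(keys_a, keys_b)
        ev_share = cross_tissue_share(tissues[a].outliers, tissues[b].outliers)
        comparison["outliers_shared"] = ev_share[2]

    # --- enrichment of first-tissue eVariants in cCRE classes
    first = names[0]
    evariant_ids = sorted({r.variant_id for r in tissues[first].cis.eqtls})
    enrichment = []
    if evariant_ids:
        vindex = geno_elig.variant_index()
        af = geno_elig.allele_frequency()
        tss_table = cohort.gene_annot.table.reset_index()[["chrom", "tss"]]

        def _variant_frame(ids: list[str]) -> pd.DataFrame:
            idx = [vindex[v] for v in ids]
            pos = geno_elig.pos[idx]
            chrom = np.array([geno_elig.chrom[i] for i in idx])
            dens = gene_density_vector(pos, chrom, tss_table)
            return pd.DataFrame(
                {"variant_id": ids, "chrom": chrom, "pos": pos,
                 "af": np.minimum(af[idx], 1 - af[idx]), "density": dens}
            )

        ev_frame = _variant_frame(evariant_ids)
        pool_ids = [v for v in geno_elig.variant_ids if v not in set(evariant_ids)]
        pool_frame = _variant_frame(pool_ids)
        ccre_sets = {
            f"{cls}|{tag}": cohort.ccres.subset(ccre_class=cls, tissue_tag=tag)
            for cls in sorted(cohort.ccres.table.ccre_class.unique())
            for tag in sorted(cohort.ccres.table.tissue_tag.unique())
            if len(cohort.ccres.subset(ccre_class=cls, tissue_tag=tag).table)
        }
        if ccre_sets and len(pool_frame):
            enrichment = bootstrap_enrichment(
                ev_frame, pool_frame, ccre_sets,
                n_iter=n_enrichment_iter, seed=int(rng.integers(2**31)),
            )

    # --- prioritization of first-tissue outliers
    eye = cohort.ccres.subset(tissue_tag="eye")
    non_eye = cohort.ccres.subset(tissue_tag="non_eye")
    annot = cohort.bundles[first].gene_annot
    snv_samples = set(cohort.snv_table["sample_id"])
    prioritization: list[PrioritizationResult] = []
    for ev in tissues[first].outliers:
        if ev.gene_id not in annot.table.index:
            continue
        row = annot.table.loc[ev.gene_id]
        svs = sv_variants_for_sample(cohort.sv_table, ev.sample_id)
        snvs = (
            extract_sample_rare_variants(
                cohort.snv_table, ev.sample_id,
                (str(row.chrom), int(row.start), int(row.end)),
            )
            if ev.sample_id in snv_samples else []
        )
        prioritization.append(prioritize(ev, svs, snvs, eye, non_eye, annot))

    return PipelineResult(
        cohort=cohort, geno_qc=geno_qc, tissues=tissues,
        enrichment=enrichment, prioritization=prioritization,
        comparison=comparison,
    )
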
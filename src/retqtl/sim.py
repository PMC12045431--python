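"""Synthetic paired genome-transcriptome cohort generator.

Produces everything the downstream stages consume — HWE-consistent diploid
genotypes with per-sample GQ/AD fields, negative-binomial expression with
planted cis-eQTL effects (true allelic-fold-change semantics), hidden
expression confounders, labeled cCRE intervals, SV/CNV calls, a variant
annotation table, and rare-variant-driven expression outliers spanning
every prioritization category — together with a truth table for recovery
tests.  A fixed seed makes every artifact, including written files,
byte-identical across runs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .prioritize import Category
from .types import CcreSet, ExpressionBundle, GeneAnnotation, GenotypeMatrix

AFC_CAP = 6.64


@dataclass
class SimConfig:
    """Cohort-level simulation parameters.

    Defaults define a desk-scale cohort: two ~8 Mb chromosomes, ~120
    samples, 60 genes, common planted eQTL effects of 0.5–2 log2 units and
    strong (|log2| = 3) planted outlier effects.
    """

    n_samples: int = 120
    n_genes: int = 60
    genome: list[tuple[str, int]] = field(default_factory=lambda: [("1", 8_000_000), ("2", 8_000_000)])
    variant_density: float = 0.06  # variants per kb
    maf_beta: tuple[float, float] = (0.8, 0.8)  # Beta params, truncated to [0.01, 0.5]
    maf_range: tuple[float, float] = (0.01, 0.5)
    n_planted_eqtls: int = 10
    afc_effect_range: tuple[float, float] = (0.5, 2.0)  # |log2 aFC| bounds
    eqtl_min_maf: float = 0.2
    n_hidden_factors: int = 3
    hidden_factor_sd: float = 0.25
    nb_dispersion: float = 0.08
    library_size_range: tuple[int, int] = (800_000, 1_600_000)
    n_planted_outliers: int = 11
    outlier_log2_effect: float = 3.0
    missing_rate: float = 0.01
    low_gq_rate: float = 0.01
    n_background_rare_snvs: int = 60
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_samples", "n_genes", "n_hidden_factors",
                     "n_planted_eqtls", "n_planted_outliers"):
            if getattr(self, name) < 0 or (name in ("n_samples", "n_genes")
                                           and getattr(self, name) == 0):
                raise ValueError(f"{name} must be positive")
        for chrom, length in self.genome:
            if length <= 0:
                raise ValueError(f"chromosome {chrom!r} has non-positive length")
        lo, hi = self.afc_effect_range
        if not (0 <= lo <= hi <= AFC_CAP):
            raise ValueError(f"afc_effect_range must lie within [0, {AFC_CAP}]")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must be in [0, 1)")


@dataclass
class TruthTable:
    """Ground truth of planted structure for recovery tests."""

    planted_eqtls: list[tuple[str, str, float]] = field(default_factory=list)
    planted_outliers: list[dict] = field(default_factory=list)
    hidden_factor_loadings: np.ndarray | None = None

    def to_json_dict(self) -> dict:
        return {
            "planted_eqtls": [list(t) for t in self.planted_eqtls],
            "planted_outliers": self.planted_outliers,
            "hidden_factor_loadings": (
                self.hidden_factor_loadings.tolist()
                if self.hidden_factor_loadings is not None else None
            ),
        }


_BASES = np.array(list("ACGT"))


def simulate_genotypes(cfg: SimConfig, rng: np.random.Generator | None = None) -> GenotypeMatrix:
    """Diploid dosages sampled per variant at its drawn allele frequency.

    Genotypes are Binomial(2, AF) per sample (Hardy-Weinberg proportions);
    sites are redrawn until polymorphic in the cohort, mirroring a
    discovery VCF that only contains observed variants.  A ``missing_rate``
    fraction of genotypes is set missing.  Variant ids are
    CHR_POS_REF_ALT with 1-based positions.
    """
    rng = rng or np.random.default_rng(cfg.seed)
    chroms: list[str] = []
    positions: list[int] = []
    for chrom, length in cfg.genome:
        n_var = max(1, int(round(length / 1000.0 * cfg.variant_density)))
        pos = np.sort(rng.choice(np.arange(1, length + 1), size=n_var, replace=False))
        chroms.extend([chrom] * n_var)
        positions.extend(pos.tolist())
    n_var = len(positions)

    a, b = cfg.maf_beta
    lo, hi = cfg.maf_range
    maf = lo + (hi - lo) * rng.beta(a, b, size=n_var)

    dosages = np.empty((cfg.n_samples, n_var))
    for j in range(n_var):
        d = rng.binomial(2, maf[j], size=cfg.n_samples).astype(float)
        while d.sum() == 0 or d.sum() == 2 * cfg.n_samples:
            d = rng.binomial(2, maf[j], size=cfg.n_samples).astype(float)
        dosages[:, j] = d
    if cfg.missing_rate > 0:
        miss = rng.random(dosages.shape) < cfg.missing_rate
        dosages[miss] = np.nan

    refs = _BASES[rng.integers(0, 4, size=n_var)]
    alts = np.array([_BASES[(list(_BASES).index(r) + rng.integers(1, 4)) % 4] for r in refs])
    variant_ids = [
        f"{c}_{p}_{r}_{al}" for c, p, r, al in zip(chroms, positions, refs, alts)
    ]
    sample_ids = [f"S{i:04d}" for i in range(cfg.n_samples)]
    return GenotypeMatrix(
        dosages=dosages,
        variant_ids=variant_ids,
        sample_ids=sample_ids,
        chrom=chroms,
        pos=np.array(positions),
    )


def simulate_gene_annotation(cfg: SimConfig, rng: np.random.Generator | None = None) -> GeneAnnotation:
    """Gene models spaced along the genome with 3-6 exons each."""
    rng = rng or np.random.default_rng(cfg.seed + 1)
    rows = []
    exons: dict[str, list[tuple[int, int]]] = {}
    genome = cfg.genome
    per_chrom = int(np.ceil(cfg.n_genes / len(genome)))
    gid = 0
    for chrom, length in genome:
        spacing = length // (per_chrom + 1)
        for k in range(per_chrom):
            if gid >= cfg.n_genes:
                break
            start = (k + 1) * spacing
            body_len = int(rng.integers(8_000, 30_000))
            end = min(start + body_len, length - 1)
            strand = "+" if gid % 2 == 0 else "-"
            tss = start if strand == "+" else end
            gene_id = f"GENE{gid:04d}"
            n_ex = int(rng.integers(3, 7))
            cuts = np.sort(rng.choice(np.arange(start + 200, end - 200), size=2 * n_ex, replace=False))
            exons[gene_id] = [(int(cuts[0]), int(cuts[1]))]
            exons[gene_id] = [(int(cuts[2 * i]), int(cuts[2 * i + 1])) for i in range(n_ex)]
            # anchor first/last exon to the body bounds so exon spans tile the gene
            exons[gene_id][0] = (start, exons[gene_id][0][1])
            exons[gene_id][-1] = (exons[gene_id][-1][0], end)
            rows.append(
                {"gene_id": gene_id, "chrom": chrom, "strand": strand,
                 "tss": tss, "start": start, "end": end}
            )
            gid += 1
    table = pd.DataFrame(rows).set_index("gene_id")
    return GeneAnnotation(table=table, exons=exons)


def simulate_ccres(
    cfg: SimConfig,
    gene_annot: GeneAnnotation,
    rng: np.random.Generator | None = None,
    classes: tuple[str, ...] = CcreSet.CLASSES,
) -> CcreSet:
    """Labeled cCRE intervals, non-overlapping within each class.

    Promoters sit just upstream of gene TSSs (alternating eye / non-eye
    tags); enhancers and other classes fill intergenic space.  Gene bodies
    are left free of non-promoter cCREs so intronic structural variants
    stay category-clean.
    """
    rng = rng or np.random.default_rng(cfg.seed + 2)
    rows = []
    if classes:
        for i, (gene_id, row) in enumerate(gene_annot.table.iterrows()):
            if "promoter" not in classes:
                break
            width = int(rng.integers(300, 800))
            if row.strand == "+":
                end0 = int(row.tss) - 200
                start0 = end0 - width
            else:
                start0 = int(row.tss) + 200
                end0 = start0 + width
            if start0 < 0:
                continue
            rows.append(
                {"chrom": row.chrom, "start": start0, "end": end0,
                 "ccre_class": "promoter",
                 "tissue_tag": "eye" if i % 2 == 0 else "non_eye"}
            )
        body_spans: dict[str, list[tuple[int, int]]] = {}
        for _, row in gene_annot.table.iterrows():
            body_spans.setdefault(row.chrom, []).append((int(row.start) - 2000, int(row.end) + 2000))
        for cls in classes:
            if cls == "promoter":
                continue
            for chrom, length in cfg.genome:
                occupied = sorted(body_spans.get(chrom, []))
                n_intervals = max(3, cfg.n_genes // (2 * len(cfg.genome)))
                placed: list[tuple[int, int]] = []
                attempts = 0
                while len(placed) < n_intervals and attempts < 50 * n_intervals:
                    attempts += 1
                    start0 = int(rng.integers(0, length - 2000))
                    end0 = start0 + int(rng.integers(200, 1500))
                    if any(s <= end0 and start0 <= e for s, e in occupied):
                        continue
                    if any(s < end0 and start0 < e for s, e in placed):
                        continue
                    placed.append((start0, end0))
                for start0, end0 in sorted(placed):
                    rows.append(
                        {"chrom": chrom, "start": start0, "end": end0,
                         "ccre_class": cls,
                         "tissue_tag": "eye" if rng.random() < 0.5 else "non_eye"}
                    )
    table = pd.DataFrame(rows, columns=["chrom", "start", "end", "ccre_class", "tissue_tag"])
    table = table.sort_values(["chrom", "start", "end", "ccre_class"]).reset_index(drop=True)
    return CcreSet(table)


def simulate_expression(
    geno: GenotypeMatrix,
    gene_annot: GeneAnnotation,
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
    tissue: str = "NSR",
    planted_eqtls: list[tuple[str, str, float]] | None = None,
) -> tuple[ExpressionBundle, TruthTable]:
    """Negative-binomial counts with planted cis effects and hidden factors.

    The genotype effect follows allelic-fold-change semantics: mean
    expression scales by (2 - g + g * 2^k) / 2 for dosage g, so hom-alt
    means are 2^k times hom-ref means.  Hidden factors act multiplicatively
    (log-normal); column totals follow the drawn library sizes.  If
    ``planted_eqtls`` is given (gene, variant, k triples) those exact
    effects are used; otherwise ``cfg.n_planted_eqtls`` are drawn among
    common variants within 1 Mb of gene TSSs.
    """
    rng = rng or np.random.default_rng(cfg.seed + 3)
    genes = gene_annot.gene_ids[: cfg.n_genes]
    n_g, n_s = len(genes), geno.n_samples
    vindex = geno.variant_index()
    chrom_arr = np.array(geno.chrom)
    af = geno.allele_frequency()
    maf = np.minimum(af, 1 - af)

    if planted_eqtls is None:
        planted_eqtls = []
        candidates = list(range(cfg.n_planted_eqtls))
        eligible_genes = rng.permutation(genes).tolist()
        lo, hi = cfg.afc_effect_range
        for gene_id in eligible_genes:
            if len(planted_eqtls) >= cfg.n_planted_eqtls:
                break
            row = gene_annot.table.loc[gene_id]
            in_cis = (
                (chrom_arr == row.chrom)
                & (np.abs(geno.pos - int(row.tss)) <= 1_000_000)
                & (maf >= cfg.eqtl_min_maf)
            )
            idx = np.flatnonzero(in_cis)
            if idx.size == 0:
                continue
            j = int(rng.choice(idx))
            k = float(rng.uniform(lo, hi) * rng.choice([-1.0, 1.0]))
            planted_eqtls.append((gene_id, geno.variant_ids[j], k))
    else:
        for gene_id, vid, k in planted_eqtls:
            row = gene_annot.table.loc[gene_id]
            j = vindex[vid]
            if geno.chrom[j] != row.chrom or abs(int(geno.pos[j]) - int(row.tss)) > 1_000_000:
                raise ValueError(f"planted variant {vid} outside cis window of {gene_id}")

    base = np.exp(rng.normal(np.log(400.0), 0.9, size=n_g))
    loadings = rng.normal(0.0, cfg.hidden_factor_sd, size=(n_g, cfg.n_hidden_factors))
    factors = rng.normal(0.0, 1.0, size=(cfg.n_hidden_factors, n_s))

    mu = np.tile(base[:, None], (1, n_s)).astype(float)
    gene_pos = {g: i for i, g in enumerate(genes)}
    for gene_id, vid, k in planted_eqtls:
        if gene_id not in gene_pos:
            continue
        d = geno.dosages[:, vindex[vid]].copy()
        d[np.isnan(d)] = np.nanmean(d)
        mu[gene_pos[gene_id]] *= (2.0 - d + d * 2.0**k) / 2.0
    if cfg.n_hidden_factors:
        mu *= np.exp(loadings @ factors)

    lib = rng.integers(cfg.library_size_range[0], cfg.library_size_range[1] + 1, size=n_s)
    mu = mu / mu.sum(axis=0, keepdims=True) * lib

    disp = cfg.nb_dispersion
    if disp > 0:
        lam = rng.gamma(shape=1.0 / disp, scale=mu * disp)
    else:
        lam = mu
    counts = rng.poisson(lam).astype(float)

    counts_df = pd.DataFrame(counts, index=genes, columns=geno.sample_ids)
    tpm_df = counts_df / counts_df.sum(axis=0) * 1e6  # fixed equal gene lengths

    bundle = ExpressionBundle(
        counts=counts_df, tpm=tpm_df,
        gene_annot=GeneAnnotation(
            table=gene_annot.table.loc[genes], exons={g: gene_annot.exons[g] for g in genes}
        ),
        tissue=tissue,
    )
    truth = TruthTable(
        planted_eqtls=list(planted_eqtls),
        hidden_factor_loadings=loadings,
    )
    return bundle, truth


# ---------------------------------------------------------------------------
# outlier planting

_OUTLIER_CATEGORY_CYCLE = [
    Category.SV_CNV_WHOLE_GENE,
    Category.SV_CNV_EXON,
    Category.HIGH_IMPACT_SNV,
    Category.SV_CNV_EYE_CCRE,
    Category.RARE_SNV_EYE_CCRE,
    Category.SV_CNV_EPIMAP_CCRE,
    Category.RARE_SNV_EPIMAP_CCRE,
    Category.SV_CNV_INTRON,
    Category.SV_CNV_NEAR_GENE,
    Category.COMMON_SNV_CCRE,
    Category.NO_CANDIDATE,
]


def plant_outliers(
    bundle: ExpressionBundle,
    geno: GenotypeMatrix,
    ccres: CcreSet,
    cfg: SimConfig,
    truth: TruthTable,
    rng: np.random.Generator | None = None,
    categories: list[Category] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Plant expression outliers with causal variants of every category.

    One sample's counts for one gene are scaled by 2^(±outlier_log2_effect)
    and a causal variant matching the requested category is constructed.
    Returns (sv_table, snv_annotation_table) and updates ``truth`` and the
    bundle's counts in place.  SV table columns: chrom, start (1-based),
    end, sv_type, sample_id, genotype.  SNV table columns: variant_id,
    sample_id, chrom, pos, consequence, population_af (NaN = absent from
    the population reference).
    """
    rng = rng or np.random.default_rng(cfg.seed + 4)
    if categories is None:
        categories = [
            _OUTLIER_CATEGORY_CYCLE[i % len(_OUTLIER_CATEGORY_CYCLE)]
            for i in range(cfg.n_planted_outliers)
        ]
    annot = bundle.gene_annot
    eye = ccres.subset(tissue_tag="eye")
    non_eye = ccres.subset(tissue_tag="non_eye")

    # genes with solid expression make detectable outliers
    mean_counts = bundle.counts.mean(axis=1)
    usable = [g for g in bundle.gene_ids if mean_counts[g] >= 50]
    rng.shuffle(usable)
    samples = list(bundle.counts.columns)

    sv_rows: list[dict] = []
    snv_rows: list[dict] = []
    used_genes: set[str] = set()

    def _eye_ccre_near(gene_row) -> tuple | None:
        lo, hi = int(gene_row.start) - 10_000, int(gene_row.end) + 10_000
        t = eye.table
        sub = t[(t.chrom == gene_row.chrom) & (t.start + 1 <= hi) & (t.end >= lo)]
        return None if sub.empty else sub.iloc[0]

    def _non_eye_ccre_near(gene_row) -> tuple | None:
        lo, hi = int(gene_row.start) - 10_000, int(gene_row.end) + 10_000
        # must not also fall in an eye cCRE: pick a non-eye interval that
        # doesn't intersect any eye interval (they never overlap by class+tag here)
        t = non_eye.table
        sub = t[(t.chrom == gene_row.chrom) & (t.start + 1 <= hi) & (t.end >= lo)]
        for r in sub.itertuples():
            e = eye.table
            clash = e[(e.chrom == r.chrom) & (e.start < r.end) & (r.start < e.end)]
            if clash.empty:
                return r
        return None

    for i, cat in enumerate(categories):
        placed = False
        for gene_id in usable:
            if gene_id in used_genes:
                continue
            row = annot.table.loc[gene_id]
            body_start, body_end = int(row.start), int(row.end)
            chrom = str(row.chrom)
            exons = annot.exons[gene_id]
            sample = samples[int(rng.integers(len(samples)))]
            direction = -1.0 if cat in (
                Category.SV_CNV_WHOLE_GENE, Category.SV_CNV_EXON, Category.HIGH_IMPACT_SNV
            ) else float(rng.choice([-1.0, 1.0]))
            causal_id = None

            if cat == Category.SV_CNV_WHOLE_GENE:
                sv_rows.append({"chrom": chrom, "start": body_start - 1000,
                                "end": body_end + 1000, "sv_type": "DEL",
                                "sample_id": sample, "genotype": "0/1"})
                causal_id = f"SV_{chrom}_{body_start - 1000}_{body_end + 1000}_DEL"
            elif cat == Category.SV_CNV_EXON:
                if len(exons) < 2:
                    continue
                es, ee = exons[1]
                sv_rows.append({"chrom": chrom, "start": max(body_start + 1, es - 50),
                                "end": min(body_end - 1, ee + 50), "sv_type": "DEL",
                                "sample_id": sample, "genotype": "0/1"})
                causal_id = f"SV_{chrom}_{es - 50}_{ee + 50}_DEL"
            elif cat == Category.HIGH_IMPACT_SNV:
                pos = int((exons[0][0] + exons[0][1]) // 2)
                causal_id = f"{chrom}_{pos}_C_T"
                snv_rows.append({"variant_id": causal_id, "sample_id": sample,
                                 "chrom": chrom, "pos": pos,
                                 "consequence": "stop_gained", "population_af": np.nan})
            elif cat in (Category.SV_CNV_EYE_CCRE, Category.RARE_SNV_EYE_CCRE):
                cc = _eye_ccre_near(row)
                if cc is None:
                    continue
                s1, e1 = int(cc.start) + 1, int(cc.end)
                if cat == Category.SV_CNV_EYE_CCRE:
                    sv_span = _clip_outside_body(s1 - 200, e1 + 200, body_start, body_end)
                    if sv_span is None or not _spans(*sv_span, s1, e1):
                        continue  # SV must hit the cCRE without reaching the body
                    sv_rows.append({"chrom": chrom, "start": sv_span[0], "end": sv_span[1],
                                    "sv_type": "DUP", "sample_id": sample,
                                    "genotype": "0/1"})
                    causal_id = f"SV_{chrom}_{sv_span[0]}_{sv_span[1]}_DUP"
                else:
                    pos = (s1 + e1) // 2
                    causal_id = f"{chrom}_{pos}_G_A"
                    snv_rows.append({"variant_id": causal_id, "sample_id": sample,
                                     "chrom": chrom, "pos": pos,
                                     "consequence": "upstream_gene_variant",
                                     "population_af": 0.0005})
            elif cat in (Category.SV_CNV_EPIMAP_CCRE, Category.RARE_SNV_EPIMAP_CCRE):
                cc = _non_eye_ccre_near(row)
                if cc is None:
                    continue
                s1, e1 = int(cc.start) + 1, int(cc.end)
                if cat == Category.SV_CNV_EPIMAP_CCRE:
                    sv_span = _clip_outside_body(s1, e1, body_start, body_end)
                    if sv_span is None:
                        continue
                    sv_rows.append({"chrom": chrom, "start": sv_span[0], "end": sv_span[1],
                                    "sv_type": "DEL", "sample_id": sample,
                                    "genotype": "0/1"})
                    causal_id = f"SV_{chrom}_{sv_span[0]}_{sv_span[1]}_DEL"
                else:
                    pos = (s1 + e1) // 2
                    causal_id = f"{chrom}_{pos}_T_C"
                    snv_rows.append({"variant_id": causal_id, "sample_id": sample,
                                     "chrom": chrom, "pos": pos,
                                     "consequence": "regulatory_region_variant",
                                     "population_af": np.nan})
            elif cat == Category.SV_CNV_INTRON:
                intron = _first_intron(body_start, body_end, exons, min_len=400)
                if intron is None:
                    continue
                s, e = intron
                sv_rows.append({"chrom": chrom, "start": s + 100, "end": min(e - 100, s + 600),
                                "sv_type": "DEL", "sample_id": sample, "genotype": "0/1"})
                causal_id = f"SV_{chrom}_{s + 100}_{min(e - 100, s + 600)}_DEL"
            elif cat == Category.SV_CNV_NEAR_GENE:
                # downstream flank clear of cCREs (cCREs avoid a 2 kb margin
                # around bodies, so a short SV just past the body is safe)
                s = body_end + 500
                e = body_end + 1500
                if _any_ccre_overlap(ccres, chrom, s, e):
                    continue
                sv_rows.append({"chrom": chrom, "start": s, "end": e, "sv_type": "CNV",
                                "sample_id": sample, "genotype": "CN3"})
                causal_id = f"SV_{chrom}_{s}_{e}_CNV"
            elif cat == Category.COMMON_SNV_CCRE:
                cc = _eye_ccre_near(row)
                if cc is None:
                    cc = _non_eye_ccre_near(row)
                if cc is None:
                    continue
                pos = (int(cc.start) + 1 + int(cc.end)) // 2
                causal_id = f"{chrom}_{pos}_A_G"
                snv_rows.append({"variant_id": causal_id, "sample_id": sample,
                                 "chrom": chrom, "pos": pos,
                                 "consequence": "regulatory_region_variant",
                                 "population_af": 0.22})
            elif cat == Category.NO_CANDIDATE:
                causal_id = None  # nothing planted near this gene

            # apply the expression shock
            effect = direction * cfg.outlier_log2_effect
            old = bundle.counts.loc[gene_id, sample]
            bundle.counts.loc[gene_id, sample] = float(np.round(old * 2.0**effect))
            truth.planted_outliers.append(
                {
                    "sample_id": sample,
                    "gene_id": gene_id,
                    "tissue": bundle.tissue,
                    "direction": "up" if effect > 0 else "down",
                    "log2_effect": effect,
                    "causal_variant_id": causal_id,
                    "causal_category": cat.value,
                }
            )
            used_genes.add(gene_id)
            placed = True
            break
        if not placed:
            raise ValueError(f"could not satisfy outlier category {cat.value}")

    # refresh TPM after count edits
    bundle.tpm = bundle.counts / bundle.counts.sum(axis=0) * 1e6

    # background rare SNVs, kept clear of planted-outlier gene windows
    outlier_windows = [
        (annot.table.loc[o["gene_id"]].chrom,
         int(annot.table.loc[o["gene_id"]].start) - 20_000,
         int(annot.table.loc[o["gene_id"]].end) + 20_000)
        for o in truth.planted_outliers
    ]
    genome = dict(cfg.genome)
    for _ in range(cfg.n_background_rare_snvs):
        chrom = str(list(genome)[int(rng.integers(len(genome)))])
        for _attempt in range(20):
            pos = int(rng.integers(1, genome[chrom]))
            if not any(c == chrom and s <= pos <= e for c, s, e in outlier_windows):
                break
        sample = samples[int(rng.integers(len(samples)))]
        snv_rows.append({"variant_id": f"{chrom}_{pos}_C_G", "sample_id": sample,
                         "chrom": chrom, "pos": pos, "consequence": "intergenic_variant",
                         "population_af": float(rng.uniform(0.0001, 0.009))})

    sv_table = pd.DataFrame(
        sv_rows, columns=["chrom", "start", "end", "sv_type", "sample_id", "genotype"]
    )
    snv_table = pd.DataFrame(
        snv_rows,
        columns=["variant_id", "sample_id", "chrom", "pos", "consequence", "population_af"],
    )
    return sv_table, snv_table


def _spans(a_start: int, a_end: int, b_start: int, b_end: int) -> bool:
    return a_start <= b_end and b_start <= a_end


def _clip_outside_body(start: int, end: int, body_start: int, body_end: int):
    """Trim a 1-based span so it does not intersect [body_start, body_end]."""
    if not _spans(start, end, body_start, body_end):
        return (start, end)
    if start < body_start:
        return (start, body_start - 1)
    if end > body_end:
        return (body_end + 1, end)
    return None  # span fully inside the body: cannot be trimmed


def _first_intron(body_start, body_end, exons, min_len=400):
    exons = sorted(exons)
    for (s1, e1), (s2, _) in zip(exons, exons[1:]):
        if s2 - e1 - 1 >= min_len:
            return (e1 + 1, s2 - 1)
    return None


def _any_ccre_overlap(ccres: CcreSet, chrom: str, start1: int, end1: int) -> bool:
    t = ccres.table
    sub = t[(t.chrom.astype(str) == chrom) & (t.start + 1 <= end1) & (t.end >= start1)]
    return not sub.empty


def _records_from_matrix(geno: GenotypeMatrix):
    """View a genotype matrix as QC-ready records (no GQ/AD synthesis)."""
    from .types import VariantRecord

    out = []
    for j, vid in enumerate(geno.variant_ids):
        chrom, pos, ref, alt = vid.split("_")
        out.append(
            VariantRecord(
                chrom=chrom, pos=int(pos), ref=ref, alt=alt,
                sample_ids=geno.sample_ids, dosages=geno.dosages[:, j],
            )
        )
    return out


# ---------------------------------------------------------------------------
# whole-cohort assembly and fixture writing


@dataclass
class Cohort:
    """A fully assembled two-tissue synthetic cohort."""

    cfg: SimConfig
    geno: GenotypeMatrix
    gene_annot: GeneAnnotation
    ccres: CcreSet
    bundles: dict[str, ExpressionBundle]
    truths: dict[str, TruthTable]
    sv_table: pd.DataFrame
    snv_table: pd.DataFrame
    covariates_raw: pd.DataFrame  # sex + batch per sample


def simulate_cohort(
    cfg: SimConfig,
    tissues: tuple[str, ...] = ("NSR", "RPE"),
    shared_eqtl_fraction: float = 0.6,
) -> Cohort:
    """Generate genotypes, annotation, cCREs and per-tissue expression.

    Tissues share genotypes; a ``shared_eqtl_fraction`` of the first
    tissue's planted eQTLs (same variant and effect) is reused in later
    tissues, the rest are drawn independently.  Outliers (with causal
    variants) are planted in the first tissue.
    """
    rng = np.random.default_rng(cfg.seed)
    geno = simulate_genotypes(cfg, np.random.default_rng(int(rng.integers(2**31))))
    gene_annot = simulate_gene_annotation(cfg, np.random.default_rng(int(rng.integers(2**31))))
    ccres = simulate_ccres(cfg, gene_annot, np.random.default_rng(int(rng.integers(2**31))))

    bundles: dict[str, ExpressionBundle] = {}
    truths: dict[str, TruthTable] = {}
    first_eqtls: list[tuple[str, str, float]] | None = None
    for t_i, tissue in enumerate(tissues):
        sub_rng = np.random.default_rng(int(rng.integers(2**31)))
        planted = None
        if t_i > 0 and first_eqtls:
            n_shared = int(round(shared_eqtl_fraction * len(first_eqtls)))
            shared = first_eqtls[:n_shared]
            extra_cfg = cfg
            bundle, truth = simulate_expression(
                geno, gene_annot, extra_cfg, sub_rng, tissue=tissue, planted_eqtls=None
            )
            # overwrite the leading planted effects with the shared ones by
            # re-simulating with an explicit list
            combined = shared + truth.planted_eqtls[n_shared:]
            # drop duplicates on gene
            seen: set[str] = set()
            final = []
            for g, v, k in combined:
                if g not in seen:
                    final.append((g, v, k))
                    seen.add(g)
            sub_rng = np.random.default_rng(int(rng.integers(2**31)))
            bundle, truth = simulate_expression(
                geno, gene_annot, cfg, sub_rng, tissue=tissue, planted_eqtls=final
            )
        else:
            bundle, truth = simulate_expression(geno, gene_annot, cfg, sub_rng, tissue=tissue)
            first_eqtls = truth.planted_eqtls
        bundles[tissue] = bundle
        truths[tissue] = truth

    first = tissues[0]
    sv_table, snv_table = plant_outliers(
        bundles[first], geno, ccres, cfg, truths[first],
        np.random.default_rng(int(rng.integers(2**31))),
    )

    cov_rng = np.random.default_rng(int(rng.integers(2**31)))
    covariates_raw = pd.DataFrame(
        {
            "sex": cov_rng.integers(0, 2, size=cfg.n_samples),
            "batch": [f"B{int(b)}" for b in cov_rng.integers(0, 2, size=cfg.n_samples)],
        },
        index=geno.sample_ids,
    )
    return Cohort(cfg, geno, gene_annot, ccres, bundles, truths, sv_table, snv_table,
                  covariates_raw)


def write_fixture_bundle(cohort: Cohort, out_dir: str | Path) -> dict[str, Path]:
    """Write the cohort to disk: VCF + TSVs + BED + truth JSON.

    Returns a name -> path map.  Outputs are byte-deterministic for a
    fixed config/seed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    from .vcfio import write_vcf

    paths["vcf"] = out / "genotypes.vcf"
    write_vcf(cohort.geno, paths["vcf"], seed=cohort.cfg.seed,
              low_gq_rate=cohort.cfg.low_gq_rate)

    for tissue, bundle in cohort.bundles.items():
        for name, mat in (("counts", bundle.counts), ("tpm", bundle.tpm)):
            p = out / f"{name}.{tissue}.tsv"
            mat.to_csv(p, sep="\t", float_format="%.6g")
            paths[f"{name}_{tissue}"] = p

    p = out / "gene_annotation.tsv"
    tab = cohort.gene_annot.table.copy()
    tab["exons"] = [
        ";".join(f"{s}-{e}" for s, e in cohort.gene_annot.exons[g]) for g in tab.index
    ]
    tab.to_csv(p, sep="\t")
    paths["gene_annotation"] = p

    p = out / "ccres.bed"
    with open(p, "w") as fh:
        for r in cohort.ccres.table.itertuples():
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.ccre_class}|{r.tissue_tag}\n")
    paths["ccres"] = p

    paths["sv"] = out / "sv_calls.tsv"
    sv = cohort.sv_table.copy()
    sv["start0"] = sv["start"] - 1  # BED-like 0-based starts on disk
    sv[["chrom", "start0", "end", "sv_type", "sample_id", "genotype"]].to_csv(
        paths["sv"], sep="\t", index=False
    )
    paths["snv_annotation"] = out / "variant_annotation.tsv"
    cohort.snv_table.to_csv(paths["snv_annotation"], sep="\t", index=False, float_format="%.6g")

    paths["covariates"] = out / "covariates.tsv"
    cohort.covariates_raw.to_csv(paths["covariates"], sep="\t")

    paths["truth"] = out / "truth.json"
    truth_obj = {t: tt.to_json_dict() for t, tt in cohort.truths.items()}
    with open(paths["truth"], "w") as fh:
        json.dump(truth_obj, fh, indent=2, sort_keys=True)

    return paths


def read_fixture_bundle(in_dir: str | Path) -> dict:
    """Re-read a written bundle into plain frames for round-trip checks."""
    d = Path(in_dir)
    out: dict = {}
    from .vcfio import read_vcf_records

    out["vcf_records"] = read_vcf_records(d / "genotypes.vcf")
    for p in sorted(d.glob("counts.*.tsv")):
        out[p.stem] = pd.read_csv(p, sep="\t", index_col=0)
    for p in sorted(d.glob("tpm.*.tsv")):
        out[p.stem] = pd.read_csv(p, sep="\t", index_col=0)
    out["gene_annotation"] = pd.read_csv(d / "gene_annotation.tsv", sep="\t", index_col=0)
    out["ccres"] = pd.read_csv(
        d / "ccres.bed", sep="\t", names=["chrom", "start", "end", "label"]
    )
    out["sv"] = pd.read_csv(d / "sv_calls.tsv", sep="\t")
    out["snv_annotation"] = pd.read_csv(d / "variant_annotation.tsv", sep="\t")
    out["covariates"] = pd.read_csv(d / "covariates.tsv", sep="\t", index_col=0)
    with open(d / "truth.json") as fh:
        out["truth"] = json.load(fh)
    return out
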
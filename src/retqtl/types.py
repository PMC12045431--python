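"""Core in-memory containers shared across the pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class VariantRecord:
    """One biallelic VCF record with the per-sample fields QC needs."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    sample_ids: list[str]
    dosages: np.ndarray  # per-sample alt-allele dosage, NaN = missing
    filter_flag: str | None = "PASS"
    gq: np.ndarray | None = None  # per-sample genotype quality
    allelic_balance: np.ndarray | None = None  # alt reads / total reads, NaN where no reads

    @property
    def variant_id(self) -> str:
        return f"{self.chrom}_{self.pos}_{self.ref}_{self.alt}"


@dataclass
class GenotypeMatrix:
    """Samples × variants dosage matrix with per-variant coordinates.

    Dosage is the alt-allele count (0/1/2), NaN for missing calls.
    """

    dosages: np.ndarray  # (n_samples, n_variants)
    variant_ids: list[str]
    sample_ids: list[str]
    chrom: list[str]
    pos: np.ndarray  # 1-based positions

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.pos = np.asarray(self.pos, dtype=int)
        if self.dosages.shape != (len(self.sample_ids), len(self.variant_ids)):
            raise ValueError("dosage matrix shape inconsistent with id lists")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variant_ids)

    def variant_index(self) -> dict[str, int]:
        return {v: i for i, v in enumerate(self.variant_ids)}

    def allele_frequency(self) -> np.ndarray:
        """Alt-allele frequency per variant over non-missing genotypes."""
        d = self.dosages
        with np.errstate(invalid="ignore"):
            called = ~np.isnan(d)
            af = np.nansum(d, axis=0) / (2.0 * called.sum(axis=0))
        return af

    def subset_variants(self, keep: list[str]) -> "GenotypeMatrix":
        idx = self.variant_index()
        cols = [idx[v] for v in keep]
        return GenotypeMatrix(
            dosages=self.dosages[:, cols],
            variant_ids=list(keep),
            sample_ids=list(self.sample_ids),
            chrom=[self.chrom[c] for c in cols],
            pos=self.pos[cols],
        )


@dataclass
class GeneAnnotation:
    """Gene model table: 1-based inclusive body span, TSS, exon spans."""

    table: pd.DataFrame  # index gene_id; columns chrom, strand, tss, start, end
    exons: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        required = {"chrom", "strand", "tss", "start", "end"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"gene annotation missing columns: {sorted(missing)}")
        bad = self.table[(self.table.tss < self.table.start) | (self.table.tss > self.table.end)]
        if len(bad):
            raise ValueError(f"TSS outside body span for genes: {list(bad.index[:5])}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.table.index)


@dataclass
class ExpressionBundle:
    """Counts, TPM and normalized matrices for one tissue, genes × samples."""

    counts: pd.DataFrame
    tpm: pd.DataFrame
    gene_annot: GeneAnnotation
    tissue: str = "NSR"
    normalized: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if not self.counts.index.equals(self.tpm.index) or not self.counts.columns.equals(
            self.tpm.columns
        ):
            raise ValueError("counts and TPM matrices must share gene and sample indices")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)


@dataclass
class CcreSet:
    """Labeled candidate cis-regulatory element intervals.

    Table columns: chrom, start (0-based), end (exclusive), ccre_class,
    tissue_tag ("eye"-family tissue name or a non-eye source label).
    """

    table: pd.DataFrame

    CLASSES = ("promoter", "proximal_enhancer", "distal_enhancer", "ctcf_only", "dnase_h3k4me3")

    def __post_init__(self) -> None:
        required = {"chrom", "start", "end", "ccre_class", "tissue_tag"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"cCRE table missing columns: {sorted(missing)}")
        if len(self.table) and (self.table.start >= self.table.end).any():
            raise ValueError("cCRE intervals must have start < end")

    def subset(self, ccre_class: str | None = None, tissue_tag: str | None = None) -> "CcreSet":
        t = self.table
        if ccre_class is not None:
            t = t[t.ccre_class == ccre_class]
        if tissue_tag is not None:
            t = t[t.tissue_tag == tissue_tag]
        return CcreSet(t.reset_index(drop=True))
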
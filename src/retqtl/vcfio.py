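"""Reading and writing the cohort VCF (v4.2, biallelic SNVs, GT/GQ/AD)."""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .types import GenotypeMatrix, VariantRecord

_HEADER = """##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">
"""


def write_vcf(
    geno: GenotypeMatrix, path: str | Path, seed: int = 0, low_gq_rate: float = 0.0
) -> Path:
    """Serialize a genotype matrix as an uncompressed VCF.

    Per-sample GQ and AD fields are synthesized deterministically from the
    seed: depth ~ Poisson(30), heterozygous allele balance near 0.5, GQ
    high for called genotypes except a ``low_gq_rate`` fraction drawn
    below 20.  Missing dosages become ./. calls.
    """
    path = Path(path)
    rng = np.random.default_rng(seed + 7)
    n_s, n_v = geno.dosages.shape
    depth = rng.poisson(30, size=(n_s, n_v)).clip(min=8)
    ab = rng.beta(40, 40, size=(n_s, n_v))
    gq = rng.integers(30, 100, size=(n_s, n_v))
    if low_gq_rate > 0:
        low = rng.random((n_s, n_v)) < low_gq_rate
        gq = np.where(low, rng.integers(5, 20, size=(n_s, n_v)), gq)

    contigs = sorted(set(geno.chrom), key=lambda c: (len(c), c))
    with open(path, "w", newline="\n") as fh:
        fh.write(_HEADER)
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(geno.sample_ids) + "\n"
        )
        for j, vid in enumerate(geno.variant_ids):
            chrom, pos, ref, alt = vid.split("_")
            fields = []
            for i in range(n_s):
                d = geno.dosages[i, j]
                dp = int(depth[i, j])
                if np.isnan(d):
                    fields.append("./.:.:.")
                    continue
                d = int(d)
                if d == 0:
                    gt, adr, ada = "0/0", dp, 0
                elif d == 1:
                    gt = "0/1"
                    ada = int(round(dp * ab[i, j]))
                    adr = dp - ada
                else:
                    gt, adr, ada = "1/1", 0, dp
                fields.append(f"{gt}:{int(gq[i, j])}:{adr},{ada}")
            fh.write(
                f"{chrom}\t{pos}\t{vid}\t{ref}\t{alt}\t.\tPASS\t.\tGT:GQ:AD\t"
                + "\t".join(fields) + "\n"
            )
    return path


def read_vcf_records(path: str | Path) -> list[VariantRecord]:
    """Parse a biallelic VCF into QC-ready records using cyvcf2."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    records: list[VariantRecord] = []
    for v in vcf:
        if len(v.ALT) != 1:
            raise ValueError(
                f"multiallelic record at {v.CHROM}:{v.POS}; split to biallelic first"
            )
        gts = np.array(v.genotypes, dtype=object)
        dosages = np.empty(len(samples))
        for i, g in enumerate(v.genotypes):
            alleles = [a for a in g[:-1] if a is not None and a >= 0]
            dosages[i] = sum(1 for a in alleles if a > 0) if alleles else np.nan

        gq = None
        try:
            raw_gq = v.format("GQ")
            if raw_gq is not None:
                gq = raw_gq.astype(float).reshape(-1)
        except KeyError:
            pass

        allelic_balance = None
        try:
            ad = v.format("AD")
            if ad is not None:
                ad = ad.astype(float)
                ad[ad < 0] = np.nan
                total = ad.sum(axis=1)
                with np.errstate(invalid="ignore", divide="ignore"):
                    allelic_balance = np.where(total > 0, ad[:, 1] / total, np.nan)
        except KeyError:
            pass

        records.append(
            VariantRecord(
                chrom=v.CHROM,
                pos=v.POS,
                ref=v.REF,
                alt=v.ALT[0],
                sample_ids=samples,
                dosages=dosages,
                filter_flag=v.FILTER or "PASS",
                gq=gq,
                allelic_balance=allelic_balance,
            )
        )
    return records


def read_genotype_matrix(path: str | Path) -> GenotypeMatrix:
    """Load a VCF straight into a genotype matrix (no QC applied)."""
    records = read_vcf_records(path)
    if not records:
        return GenotypeMatrix(np.zeros((0, 0)), [], [], [], np.array([], dtype=int))
    samples = records[0].sample_ids
    return GenotypeMatrix(
        dosages=np.column_stack([r.dosages for r in records]),
        variant_ids=[r.variant_id for r in records],
        sample_ids=samples,
        chrom=[r.chrom for r in records],
        pos=np.array([r.pos for r in records]),
    )
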
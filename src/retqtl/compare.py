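"""Cross-dataset eQTL comparison.

eQTLs are keyed on (variant id, gene id) with coordinate-allele variant ids
(CHR_POS_REF_ALT) and unversioned gene ids.  Replication of a reference
study's lead variants is classified per gene into: replicated (lead variant
significant here), high LD (a local eQTL with dosage r² > 0.8 to the lead),
not replicated, novel eQTL (we find eQTLs for a gene the reference lacks),
or no eQTL.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd
from scipy import stats

from .types import GenotypeMatrix


@dataclass(frozen=True)
class EqtlKey:
    variant_id: str
    gene_id: str

    def __post_init__(self) -> None:
        if self.gene_id != strip_gene_version(self.gene_id):
            raise ValueError(f"gene id must not carry a version suffix: {self.gene_id}")


def strip_gene_version(gene_id: str) -> str:
    base, _, suffix = gene_id.rpartition(".")
    return base if base and suffix.isdigit() else gene_id


def make_keys(frame: pd.DataFrame) -> set[EqtlKey]:
    """Build normalized eQTL keys from a (gene_id, variant_id) frame."""
    return {
        EqtlKey(variant_id=v, gene_id=strip_gene_version(g))
        for g, v in zip(frame["gene_id"], frame["variant_id"])
    }


def intersect_eqtl_sets(a: set, b: set) -> tuple[set, set, set]:
    """(shared, A-only, B-only) — an exact partition of A ∪ B."""
    return a & b, a - b, b - a


def iou(a: set, b: set) -> float:
    """Intersection over union; undefined (raises) when both sets are empty."""
    union = a | b
    if not union:
        raise ValueError("IoU undefined for two empty sets")
    return len(a & b) / len(union)


def ld_r2(u: np.ndarray, v: np.ndarray, min_pairs: int = 10) -> float:
    """Squared Pearson correlation of dosages over pairwise-complete samples.

    This is the composite-LD surrogate for haplotype r²; it is invariant to
    allele relabeling (dosage flips g -> 2 - g).
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    ok = ~np.isnan(u) & ~np.isnan(v)
    if ok.sum() < min_pairs:
        raise ValueError(f"need at least {min_pairs} pairwise-complete samples")
    uu, vv = u[ok], v[ok]
    if np.std(uu) == 0 or np.std(vv) == 0:
        raise ValueError("LD undefined for a monomorphic vector")
    r = np.corrcoef(uu, vv)[0, 1]
    return float(r * r)


class ReplicationCategory(str, Enum):
    REPLICATED = "replicated"
    HIGH_LD = "high_LD"
    NOVEL_EQTL = "novel_eqtl"
    NOT_REPLICATED = "not_replicated"
    NO_EQTL = "no_eqtl"


@dataclass
class ReplicationCall:
    gene_id: str
    category: ReplicationCategory
    ld_r2: float | None = None
    ld_unavailable: bool = False


def classify_replication(
    reference_leads: dict[str, str],
    candidate_eqtls: pd.DataFrame,
    geno: GenotypeMatrix | None = None,
    r2_threshold: float = 0.8,
) -> list[ReplicationCall]:
    """Classify each gene's replication status against a reference study.

    ``reference_leads`` maps gene id -> lead variant id in the reference
    study; ``candidate_eqtls`` is this study's significant eQTL table with
    gene_id and variant_id columns.  Genes in the candidate set but absent
    from the reference are called novel.  When genotypes are missing for an
    LD lookup the gene is classified without LD and flagged.
    """
    cand_by_gene: dict[str, set[str]] = {}
    for g, v in zip(candidate_eqtls["gene_id"], candidate_eqtls["variant_id"]):
        cand_by_gene.setdefault(strip_gene_version(g), set()).add(v)

    vindex = geno.variant_index() if geno is not None else {}
    calls: list[ReplicationCall] = []

    for gene, lead in sorted(reference_leads.items()):
        gene = strip_gene_version(gene)
        cand = cand_by_gene.get(gene, set())
        if not cand:
            calls.append(ReplicationCall(gene, ReplicationCategory.NO_EQTL))
            continue
        if lead in cand:
            calls.append(ReplicationCall(gene, ReplicationCategory.REPLICATED))
            continue
        best_r2: float | None = None
        unavailable = False
        if geno is None or lead not in vindex:
            unavailable = True
        else:
            lead_dos = geno.dosages[:, vindex[lead]]
            for v in sorted(cand):
                if v not in vindex:
                    unavailable = True
                    continue
                try:
                    r2 = ld_r2(lead_dos, geno.dosages[:, vindex[v]])
                except ValueError:
                    unavailable = True
                    continue
                if best_r2 is None or r2 > best_r2:
                    best_r2 = r2
        if best_r2 is not None and best_r2 > r2_threshold:
            calls.append(ReplicationCall(gene, ReplicationCategory.HIGH_LD, ld_r2=best_r2))
        else:
            calls.append(
                ReplicationCall(
                    gene, ReplicationCategory.NOT_REPLICATED,
                    ld_r2=best_r2, ld_unavailable=unavailable,
                )
            )

    ref_genes = {strip_gene_version(g) for g in reference_leads}
    for gene in sorted(set(cand_by_gene) - ref_genes):
        calls.append(ReplicationCall(gene, ReplicationCategory.NOVEL_EQTL))
    return calls


def egene_property_contrast(
    eqtls: pd.DataFrame,
    evariant_af: pd.Series,
    cv_per_gene: pd.Series,
    disease_genes: set[str],
) -> pd.DataFrame:
    """Contrast eGene/eQTL properties between disease and non-disease genes.

    Reports, per group: median expression CV, median eVariants per gene,
    median |log2 aFC| per eQTL, median eVariant allele frequency, and the
    Spearman correlation of AF with |log2 aFC| within the group; each
    contrast carries a two-sided Mann–Whitney p-value (the correlations a
    Spearman p).  ``eqtls`` needs gene_id, variant_id, afc_log2 columns.
    """
    genes = eqtls["gene_id"].map(strip_gene_version)
    is_disease = genes.isin({strip_gene_version(g) for g in disease_genes})
    for label, mask in (("disease", is_disease), ("non_disease", ~is_disease)):
        if not mask.any():
            raise ValueError(f"group {label!r} is empty")

    rows = []

    def _contrast(name: str, a: np.ndarray, b: np.ndarray) -> None:
        stat_p = stats.mannwhitneyu(a, b, alternative="two-sided").pvalue if (
            len(a) and len(b)
        ) else np.nan
        rows.append(
            {
                "property": name,
                "disease_median": float(np.median(a)) if len(a) else np.nan,
                "non_disease_median": float(np.median(b)) if len(b) else np.nan,
                "p_value": float(stat_p),
            }
        )

    egenes_d = sorted(set(genes[is_disease]))
    egenes_n = sorted(set(genes[~is_disease]))

    cv_d = cv_per_gene.reindex(egenes_d).dropna().to_numpy()
    cv_n = cv_per_gene.reindex(egenes_n).dropna().to_numpy()
    _contrast("cv", cv_d, cv_n)

    per_gene_counts = eqtls.assign(gene=genes).groupby("gene")["variant_id"].nunique()
    _contrast(
        "evariants_per_gene",
        per_gene_counts.reindex(egenes_d).dropna().to_numpy(),
        per_gene_counts.reindex(egenes_n).dropna().to_numpy(),
    )

    abs_afc = eqtls["afc_log2"].abs()
    _contrast("abs_afc", abs_afc[is_disease].dropna().to_numpy(),
              abs_afc[~is_disease].dropna().to_numpy())

    af = eqtls["variant_id"].map(evariant_af)
    _contrast("evariant_af", af[is_disease].dropna().to_numpy(),
              af[~is_disease].dropna().to_numpy())

    for label, mask in (("disease", is_disease), ("non_disease", ~is_disease)):
        sub = pd.DataFrame({"af": af[mask], "abs_afc": abs_afc[mask]}).dropna()
        if len(sub) >= 3:
            rho, p = stats.spearmanr(sub["af"], sub["abs_afc"])
        else:
            rho, p = np.nan, np.nan
        rows.append(
            {
                "property": f"spearman_af_vs_abs_afc_{label}",
                "disease_median": float(rho) if label == "disease" else np.nan,
                "non_disease_median": float(rho) if label == "non_disease" else np.nan,
                "p_value": float(p) if p == p else np.nan,
            }
        )
    return pd.DataFrame(rows)
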
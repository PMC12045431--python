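"""Cross-tissue eQTL comparison: shared keys, IoU, replication classes.

Treats the RPE eQTL set as the "reference study" and classifies each RPE
eGene's lead variant against the NSR candidate set (replicated / high LD /
not replicated / novel / no eQTL), with LD computed as dosage r².  Also
contrasts eGene properties (CV, eVariants per gene, |aFC|, eVariant AF)
between a planted "disease gene" list and the rest.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from retqtl.compare import (
    classify_replication, egene_property_contrast, intersect_eqtl_sets, iou, make_keys,
)
from retqtl.expression import coefficient_of_variation
from retqtl.pipeline import run_pipeline

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    ROOT.mkdir(parents=True, exist_ok=True)
    res = run_pipeline(seed=0)
    nsr, rpe = res.tissues["NSR"], res.tissues["RPE"]
    keys_nsr, keys_rpe = make_keys(nsr.cis.eqtl_frame()), make_keys(rpe.cis.eqtl_frame())
    shared, a_only, b_only = intersect_eqtl_sets(keys_nsr, keys_rpe)
    print(f"eQTL keys: NSR {len(keys_nsr)}, RPE {len(keys_rpe)}, shared {len(shared)}, "
          f"IoU {iou(keys_nsr, keys_rpe):.3f}")

    leads = {
        r.gene_id: r.top_variant_id
        for r in rpe.cis.permutations if not np.isnan(r.p_t)
    }
    calls = classify_replication(leads, nsr.cis.eqtl_frame(), res.geno_qc)
    frame = pd.DataFrame(
        [{"gene_id": c.gene_id, "category": c.category.value, "ld_r2": c.ld_r2}
         for c in calls]
    )
    frame.to_csv(ROOT / "replication_classes.tsv", sep="\t", index=False,
                 float_format="%.4g")
    print("replication classes:", frame["category"].value_counts().to_dict())

    # property contrast: planted eGenes with |k| above the median act as the
    # "disease gene" list so both groups are non-empty at desk scale
    eqtls = nsr.cis.eqtl_frame()
    if len(eqtls):
        truth = res.cohort.truths["NSR"].planted_eqtls
        ks = sorted(abs(k) for _, _, k in truth)
        disease = {g for g, _, k in truth if abs(k) >= ks[len(ks) // 2]}
        af = pd.Series(
            np.minimum(res.geno_qc.allele_frequency(),
                       1 - res.geno_qc.allele_frequency()),
            index=res.geno_qc.variant_ids,
        )
        cv = coefficient_of_variation(res.cohort.bundles["NSR"].tpm)
        if eqtls["gene_id"].isin(disease).any() and (~eqtls["gene_id"].isin(disease)).any():
            contrast = egene_property_contrast(eqtls, af, cv, disease)
            contrast.to_csv(ROOT / "egene_property_contrast.tsv", sep="\t",
                            index=False, float_format="%.4g")
            print(contrast.to_string(index=False))
    print(f"wrote comparison tables under {ROOT}")


if __name__ == "__main__":
    main()
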
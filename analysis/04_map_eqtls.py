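"""Cis-eQTL mapping per tissue with permutation FDR and allelic fold change.

Reconstructs the seed-0 cohort, runs QC + eligibility, maps cis-eQTLs in
each tissue (1 Mb window, 500 permutations, Storey FDR 0.05, per-gene p_t),
and reports recovery of the planted effects.  Writes per-gene permutation
tables and significant eQTL tables (with log2 aFC) under results/.
"""

from pathlib import Path

import numpy as np

from retqtl.pipeline import run_pipeline

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    ROOT.mkdir(parents=True, exist_ok=True)
    res = run_pipeline(seed=0)
    for tissue, ta in res.tissues.items():
        ta.cis.permutation_frame().to_csv(
            ROOT / f"eqtl_permutations.{tissue}.tsv", sep="\t", index=False,
            float_format="%.6g")
        ta.cis.eqtl_frame().to_csv(
            ROOT / f"eqtls.{tissue}.tsv", sep="\t", index=False, float_format="%.6g")

        truth = {(g, v): k for g, v, k in res.cohort.truths[tissue].planted_eqtls}
        truth_genes = {g for g, _ in truth}
        egenes = set(ta.cis.egenes)
        recovered = truth_genes & egenes
        afc_errors = [
            abs(r.afc_log2 - truth[(r.gene_id, r.variant_id)])
            for r in ta.cis.eqtls if (r.gene_id, r.variant_id) in truth
        ]
        print(f"{tissue}: {len(egenes)} eGenes, {len(ta.cis.eqtls)} eQTLs; "
              f"planted-eGene recovery {len(recovered)}/{len(truth_genes)}; "
              f"median |aFC error| at planted pairs: "
              f"{np.median(afc_errors):.3f}" if afc_errors else "no planted pair significant")
    print(f"wrote eQTL tables under {ROOT}")


if __name__ == "__main__":
    main()
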
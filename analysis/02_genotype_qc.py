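"""Site-level QC of the cohort VCF and the eQTL eligibility gate.

Reads results/cohort/genotypes.vcf, applies the filter cascade (hard
filters, inbreeding F < -0.3, GQ/allelic-balance masking, monomorphic,
HWE exact p < 1e-8, missingness > 20%), then gates common variants at
MAF > 2.5% and MAC > 10.  Writes the per-site QC report.
"""

from collections import Counter
from pathlib import Path

import pandas as pd

from retqtl.qc import apply_site_filters, eqtl_eligible_variants
from retqtl.vcfio import read_vcf_records

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    ROOT.mkdir(parents=True, exist_ok=True)
    records = read_vcf_records(ROOT / "cohort" / "genotypes.vcf")
    geno, qc_records = apply_site_filters(records)
    eligible = eqtl_eligible_variants(geno)

    report = pd.DataFrame(
        [
            {"variant_id": r.variant_id, "status": r.filter_status.value,
             "inbreeding_F": r.inbreeding_F, "hwe_p": r.hwe_p,
             "missingness": r.missingness, "maf": r.maf, "mac": r.mac,
             "eqtl_eligible": r.variant_id in eligible}
            for r in qc_records
        ]
    )
    out = ROOT / "qc_report.tsv"
    report.to_csv(out, sep="\t", index=False, float_format="%.6g")

    counts = Counter(report["status"])
    print(f"sites in: {len(qc_records)}  pass: {counts['pass']}  "
          f"drop reasons: {dict((k, v) for k, v in counts.items() if k != 'pass')}")
    print(f"eQTL-eligible (MAF>2.5%, MAC>10): {len(eligible)}")
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
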
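"""Generate the synthetic two-tissue cohort and write the fixture bundle.

Produces genotypes (VCF), counts/TPM matrices for NSR and RPE, the gene
annotation, labeled cCRE intervals, SV/CNV calls, the variant annotation
table, covariates, and the truth JSON under results/cohort/.
"""

import sys
from pathlib import Path

from retqtl.sim import SimConfig, simulate_cohort, write_fixture_bundle

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 0
OUT = Path(__file__).resolve().parents[1] / "results" / "cohort"


def main() -> None:
    cfg = SimConfig(seed=SEED)
    cohort = simulate_cohort(cfg)
    paths = write_fixture_bundle(cohort, OUT)
    truth = cohort.truths["NSR"]
    print(f"cohort: {cohort.geno.n_samples} samples, {cohort.geno.n_variants} variants, "
          f"{cfg.n_genes} genes per tissue")
    print(f"planted: {len(truth.planted_eqtls)} cis-eQTLs, "
          f"{len(truth.planted_outliers)} expression outliers (NSR)")
    print(f"wrote {len(paths)} files under {OUT}")


if __name__ == "__main__":
    main()
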
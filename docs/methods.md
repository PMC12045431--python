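# Methods

`retqtl` implements a paired genome–transcriptome analysis for two ocular
tissues (neurosensory retina, NSR, and retinal pigment epithelium, RPE):
variant-level QC of a cohort VCF, expression normalization, cis-eQTL mapping
with a permutation-calibrated gene-level FDR and allelic-fold-change effect
sizes, cross-dataset eQTL comparison, matched-control bootstrap enrichment of
eVariants in candidate cis-regulatory elements (cCREs), expression-outlier
calling, and a hierarchical prioritization of rare variants driving outliers.
All stages run against a built-in synthetic cohort with planted ground truth.

## Site-level genotype QC

Biallelic records pass a fixed cascade, each site receiving exactly one
terminal verdict: (1) non-PASS filter flag; (2) overlap with a low-complexity
region BED; (3) inbreeding coefficient F = 1 − obs-het/exp-het below −0.3;
(4) genotypes with GQ < 20 masked; (5) heterozygous genotypes with allelic
balance (alt reads / total) > 0.8 or < 0.2 masked; (6) monomorphic after
masking; (7) exact Hardy–Weinberg test p < 1e-8; (8) missingness > 20%.
GQ/AB bounds are strict inequalities. The HWE test is the exact conditional
test: given the allele counts, it sums the probabilities of all heterozygote
counts no more likely than the one observed; the test suite checks it against
an exact-rational enumeration for every configuration with up to 60 genotypes
(agreement < 1e-12). Sites enter eQTL mapping only with MAF > 2.5% and
MAC > 10 (both strict), computed over non-missing calls. Multiallelic input
must be pre-split; a simple per-ALT splitter is provided (calls carrying a
different ALT become missing, which also covers compound-het ALT1/ALT2
removal). Sample matching is supported by singleton concordance: the fraction
of a sample's WGS singletons re-called from RNA-seq, with the denominator
restricted to sites assessable at RNA depth > 15× (the natural denominator
when RNA coverage is sparse; the unrestricted variant is a one-line change).

## Expression normalization

Genes are kept when TPM > 0.1 **and** raw counts ≥ 6 in at least 20% of
samples (the sample count is `ceil(0.2·n)`). Libraries are scaled by trimmed
mean of M-values (TMM) with the originating method's defaults (M-trim 0.30,
A-trim 0.05, reference = library with upper quartile closest to the mean);
the implementation reproduces edgeR's `calcNormFactors` to 1e-8 on random
matrices, and edgeR is kept in the test suite as an independent oracle only.
Two quantities are exposed: the composition factor (the M-value output, 1 for
a pure depth change) and the effective factor (library size × composition),
which is what CPM normalization divides by and which is scale-equivariant.
Each gene is then mapped to normal quantiles across samples with the
rank-based inverse normal transform Φ⁻¹((rank − 0.5)/n), average ranks for
ties. Hidden expression confounders are the top principal components of the
normalized samples × genes matrix (genes centered, sign fixed so the largest
loading is positive). PCA stands in the covariate role that PEER factors fill
in autoencoder-era pipelines; it is deterministic, and k is configurable
(the cohort-scale default of 30 is reduced to 10 on the desk-scale synthetic
cohort, where genes are few). Genotype PCs are computed from centered,
MAF-scaled dosages (top 5). The per-gene coefficient of variation defaults to
SD/mean; a flag exposes the reciprocal, since both conventions circulate.

## Cis-eQTL mapping

For each gene, all QC-passing common variants within 1 Mb of the TSS
(inclusive bounds, strand-agnostic) are tested. Phenotype and mean-imputed
dosages are residualized against the covariates plus intercept; the slope of
residual-on-residual equals the multiple-regression coefficient
(Frisch–Waugh), with t-tests at df = n − rank(covariates + intercept) − 1.

Gene-level calibration permutes the residualized phenotype B times (default
1000; 500 in the desk-scale runs), with genotypes fixed so cis LD is
preserved, and records each permutation's minimum nominal p. A Beta(a, b) is
fitted to the minima by maximum likelihood (method-of-moments start, L-BFGS-B
in log-parameter space, Newton polish; accepted when the likelihood gradient
norm is below 1e-4, typically < 1e-10). The observed minimum p maps to
`adjusted_beta_p = BetaCDF(p_min; a, b)` — the tail-extrapolated empirical p.
The fit is validated against the order-statistic identity that the minimum of
k independent uniforms is Beta(1, k).

Storey q-values over the adjusted p-values define eGenes at FDR 0.05: π₀ is
estimated on the λ grid 0.05…0.95 with a cubic polynomial smoother evaluated
at λ = 0.95, falling back to π₀ = 1 (Benjamini–Hochberg) for small inputs or
estimates outside (0, 1]. The genome-wide boundary p* is the midpoint between
the largest adjusted p with q ≤ FDR and the smallest with q > FDR (1.0 when
every gene passes — an interpolation choice, since none is canonical); each
eGene's nominal threshold is p_t = BetaQuantile(p*; a, b), and its eQTLs are
the cis variants with nominal p ≤ p_t.

Effect sizes are log2 allelic fold change (aFC): under an additive haplotype
model a sample with dosage g has expected expression c·(2 − g + g·2^k)/2, so
hom-alt means are 2^k × hom-ref means. Covariates are removed in log2 space,
genotype-group means are formed on the linear scale, and (c, k) minimize the
group-size-weighted squared log2 residuals; k is clamped to ±6.64 (log2 100).
aFC is computed on TPM, not the rank-normalized phenotype, so it retains
fold-change units. Model-consistent group means are recovered exactly;
negative-binomial noise at n = 500 recovers planted k within ±0.15. Note that
covariate removal can shrink aFC when hidden factors absorb part of a strong
genotype effect — a property shared with any pipeline that adjusts for
expression-derived confounders.

## Cross-dataset comparison

eQTLs are keyed by (CHR_POS_REF_ALT, unversioned gene id); sharing and the
intersection-over-union statistic are exact set operations. Replication of a
reference study's per-gene lead variants is classified as: replicated (lead
is a significant eQTL here), high LD (some local eQTL has dosage r² > 0.8
with the lead — strict; composite LD from unphased dosages, which is
allele-flip invariant), not replicated, novel eQTL (gene absent from the
reference), or no eQTL. Genes with missing genotypes for the LD lookup are
classified without LD and flagged. Property contrasts between a disease-gene
list and other eGenes (CV, eVariants per gene, |aFC|, eVariant AF, Spearman
AF-vs-|aFC|) use two-sided Mann–Whitney tests.

## cCRE enrichment

Each bootstrap iteration draws a subsample of eVariants with replacement and
one matched control per draw — a non-eQTL variant from the same allele-
frequency decile (edges from the pooled AF distribution) and gene-density bin
(0–5, 6–10, 11–20, 21–50, >50 TSSs within 1 Mb); empty bins fall back to the
nearest non-empty bin and are logged. The statistic per cCRE class is the
ratio of eVariant to control overlaps; over iterations the mean ratio, the
2.5–97.5% percentile CI and a two-sided Z-test against a null with mean 1 and
the bootstrap SD are reported. Iterations with zero control overlaps are
excluded and counted rather than smoothed. Overlap follows BED conventions: a
SNV at 1-based position p hits [start, end) iff start < p ≤ end; spanning
variants hit iff ranges intersect. The cohort-scale defaults are 1,000
iterations and a 100,000 subsample; the subsample is capped at 10× the
eVariant count so desk-scale runs keep the same subsample-to-set proportions
(at full scale the subsample is likewise a fraction of the eVariant set, and
the Z-test is calibrated for that regime — a subsample far larger than the
set makes the frozen sampling noise of the labels look significant).

## Expression outliers

The caller is a deliberately transparent stand-in for autoencoder-based
aberrant-expression tools, keeping their event schema and published cutoffs
(expression cutoff 1 on a cohort-mean FPKM-like scale with the fixed 2 kb
gene length; per-sample BH-adjusted p < 0.05): counts are size-factor
normalized (median of ratios), log2(x+1) transformed, the top
`ceil(n_samples/20)` principal components are removed as a confounder proxy,
and per-gene robust z-scores ((value − median)/(1.4826·MAD)) give two-sided
normal p-values. Genes with zero MAD are skipped with a warning. Cross-tissue
accounting counts unique (sample, gene) events per tissue and shared.

## Hierarchical prioritization

Each outlier (sample, gene) is assigned exactly one category by first match
over the sample's variants near the gene, in fixed precedence: SV/CNV
covering the whole gene body; SV/CNV overlapping any exon; high-impact SNV in
the gene (stop_gained, frameshift_variant, start_lost, stop_lost,
splice_donor_variant, splice_acceptor_variant — by default regardless of
rarity, with a flag to require AF < 1%); SV/CNV then rare SNV overlapping an
eye-tagged cCRE within 10 kb of the gene body; SV/CNV then rare SNV in a
non-eye cCRE within 10 kb; SV/CNV in an intron; any SV/CNV within 10 kb;
common SNV in a cCRE (reported with no candidate); otherwise no variant of
interest. "Rare" means population AF < 0.01 (strict) or absent from the
reference table; the 10 kb pad is inclusive. Categories map onto four tiers
(pLoF / regulatory / non-coding structural / no candidate). Output is a JSON
object keyed by `sample-gene-tissue` with category, tier, candidate list and
the outlier's statistics.

## Synthetic cohort

The generator produces what the analyses consume, with planted truth. Its
defaults are the desk-scale study conditions: 120 samples, 60 genes on two
8 Mb chromosomes, 0.06 variants/kb (~960 sites), allele frequencies from a
Beta(0.8, 0.8) rescaled to [0.01, 0.5] (covering common eQTL-eligible and
rarer regimes), genotypes Binomial(2, AF) per sample — Hardy–Weinberg by
construction — with sites redrawn until polymorphic (a discovery VCF contains
only observed variants), 1% missing calls and 1% low-GQ calls. Expression is
negative binomial (gene dispersion 0.08, a typical bulk RNA-seq value) around
lognormal gene baselines, multiplied by planted cis effects with true aFC
semantics, by log-normal hidden-factor effects (3 factors, loading SD 0.25),
and scaled to library sizes of 0.8–1.6 M; TPM uses fixed equal gene lengths,
so counts are compositional. Ten planted eQTLs draw |k| from 0.5–2 log2 units
at MAF ≥ 0.2; eleven planted outliers (one per prioritization category) shock
one (sample, gene) count by 2^±3 and insert a causal variant constructed to
satisfy exactly its category: promoters sit just upstream of TSSs (tags
alternating eye/non-eye), other cCRE classes avoid a 2 kb margin around gene
bodies so intronic and near-gene structural variants stay category-clean, and
background rare SNVs avoid the planted genes' windows so recovery tests
measure the workflow rather than collisions. Two tissues share genotypes and
a configurable fraction (default 0.6) of planted eQTLs. A fixed seed makes
every artifact byte-identical, including written files (VCF v4.2 with
GT/GQ/AD, TSV matrices, BED with `class|tissue` labels, SV/CNV TSV, variant
annotation TSV, truth JSON).

What the generator does **not** emulate: linkage disequilibrium beyond
independent sites, population structure and relatedness, realistic gene
length/GC effects, splicing or allele-specific signals, and annotation noise.
Passing recovery tests therefore demonstrates correctness of the inferential
machinery under its stated model, not performance on real cohorts — in
particular, LD makes top-variant identification harder and enrichment more
correlated than the synthetic results suggest.

## Problem sizes and numerical choices

Default analyses use the desk-scale cohort above with 500 permutations per
gene and 500 bootstrap iterations, chosen so each calibration stage reruns in
seconds on one CPU; cohort-scale flags (B = 1000, 100,000 subsample, k = 30
factors) remain the documented defaults of the respective functions. Beta
fits clamp p-values to [1e-300, 1 − 1e-16] with a warning; degenerate cases
(constant phenotype, monomorphic LD vectors, single genotype group, empty
cCRE class, single bootstrap iteration) raise or report undefined rather than
silently returning 0 or ∞. Type-I calibration (fully null cohorts of 200
samples × 50 genes, 10 seeds) yields ≤ 1 expected eGene at FDR 0.05; power
runs (planted |k| ≥ 1, MAF ≥ 0.2, n = 200) detect ≥ 90% of planted eGenes
with the planted variant (or an r² > 0.8 proxy) as top eVariant.

## Known limitations

Permutation count is fixed rather than adaptive; conditional/independent
signal mapping, trans-eQTLs and interaction QTLs are out of scope, as are
splicing and monoallelic-expression outliers, probabilistic
(posterior-based) outlier–variant integration, colocalization, and
haplotype-EM LD. The outlier caller's PCA confounder removal is a linear
approximation of the autoencoder it replaces.
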
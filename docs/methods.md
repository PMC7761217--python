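# Methods

## Scope and model

`twindiff` compares one affected/healthy monozygotic twin pair across three
molecular layers — small variants, structural/copy-number variants, and
CpG methylation — and integrates the gene-level evidence into a ranked
candidate list. Upstream read processing (alignment, variant calling,
methylation extraction) and annotation computation (VEP consequences,
PolyPhen-2/SIFT/MutationTaster verdicts, CADD scores, population
frequencies) are out of scope: the pipeline consumes caller and annotator
output as VCF INFO fields and tabular inputs. All internal coordinates are
0-based half-open; VCF and bismark-coverage positions are converted at the
format boundary only.

## Variant discordance and the filter cascade

A call is recoded per ALT allele (multiallelic records are split; INDELs are
assumed left-normalized by the caller). Discordance is a total function of
the two genotypes: *unique to a twin* means that twin carries ≥ 1 ALT allele
while the other is homozygous reference or uncalled; *zygosity difference*
means both carry ALT with unequal genotypes. Two deliberate ambiguities are
exposed as modes rather than resolved silently:

- **Absence strictness.** Raw co-twin uniqueness is dominated by coverage
  artifacts, so `strict_absence` additionally requires the healthy twin's
  site to be callable (DP ≥ 10) before a variant counts as unique. Default
  off: an uncalled healthy site counts as absence.
- **Quality target.** The GQ/DP floor applies to the carrier (affected)
  twin; `strict_quality` applies it to both.

The cascade order is discordance → quality (GQ ≥ 20, DP ≥ 10, inclusive) →
rarity (maximum frequency across configured populations < 0.01; an
unobserved frequency counts as rare) → deleteriousness. Consequence classes
use an embedded VEP-style severity table; HIGH passes unconditionally,
MODERATE requires ≥ 1 damaging predictor verdict, LOW is removed, and
MODIFIER classes are routed to the non-coding branch, which requires CADD
strictly above 15. Survivor counts are recorded after every stage
(`FilterTrace`), and the survivor percentage is rounded half-up to two
decimals.

## SV/CNV screen

"Common" is operationalized as ≥ 50 % reciprocal overlap with any same-type
interval of the common-SV reference set; the threshold is configurable
because the matching convention used for the reference set is not uniquely
determined in the literature. SV uniqueness uses exact carrier labels from
the merged input (no breakpoint fuzz window), which is conservative and
testable. CNV gain/loss is called against a fixed diploid baseline, with sex
chromosomes excluded by default since per-sample ploidy is not modeled.
Gene mapping is ≥ 1 bp span overlap under half-open semantics.

## Differential methylation

Methylation level is 100·meth/coverage; the stored percentage column of
coverage files is ignored and recomputed. Only positions present in both
samples with coverage in [10, 500] (inclusive) in *both* are tested; the
difference threshold (≥ 25 points) is inclusive. The criterion is a fixed
difference, not a significance test: with a single individual per group a
group-variance model cannot be estimated honestly (duplicating samples would
fabricate zero within-group variance), so the operative filter is the
difference plus the coverage window. An optional per-site Fisher exact
p-value on the 2×2 count table is attached as labeled extra output and never
filters. CpGs are kept per strand as reported; an optional symmetric-CpG
merge (summing the +/− pair at offset 1) is off by default. Conversion QC
aggregates the unmethylated lambda spike-in and reports 100 − % apparent
mCpG; zero spike-in coverage yields an "unavailable" flag, not an error.

## Feature annotation

Promoter windows are strand-aware around the TSS. Two conventions exist in
the field and both are supported: the default `minus500_plus2k`
(−500 bp/+2 kb) governs the summary tables; `minus2k_plus500` is selectable.
Shores are the union of 2-kb flanks of every CGI minus the union of all CGI
bodies (merged; therefore shores never intersect islands by construction).
Promoter-CGIs are the base-pair intersection of the two tracks. Overlap is
≥ 1 bp under half-open semantics via interval trees; composite labels
(TFBS-in-promoter, cardiac-TFBS-in-promoter) require simultaneous membership
in both parent tracks. Nearest-gene distance is measured to gene spans (not
TSS), matching common annotator defaults; all genes tied at the minimal
distance are returned, signed negative when the gene lies left of the site.
Location classes use fixed precedence exonic > intronic > intergenic; a gene
without exon blocks counts as exonic throughout. Summary rows are
deliberately *not* mutually exclusive — one CpG can increment several rows —
and each site counts once per row even if it lies in two overlapping
features of the same class.

## Prioritization

Genes are nominated by: variant survivors (nearest gene), SV and CNV
survivors (overlapped genes), and DMCs in promoter-CGIs or at TFBS in
promoters (nearest gene). Expression (> 1 RPKM/TPM, strict, in ≥ 1 dataset)
is a hard requirement by default and an annotation in soft mode, because the
source analyses are ambiguous about whether non-expressed genes were
reported or removed. Gene symbols match case-insensitively with no alias
resolution. The ranking key — number of nominating arms, then evidence-list
count, then name — is this package's own convention; the narrative analyses
it reproduces define no total order.

## Synthetic data generator

The generator emulates the *structure* of a discordant-twin WGS + WGBS
study, not its sequence content (no reads, no haplotype structure, no
CpG-dense sequence composition). Defaults: 1 chromosome of 1 Mb, 50
non-nested genes ≥ 3 kb apart (so each promoter belongs unambiguously to its
gene), 30 CGIs (half straddling a TSS), 60 TFBS (a third cardiac, 40 %
inside promoters), 10 intergenic enhancers, 400 shared background variants,
and ~30 planted discordant variants across seven classes, each engineered to
a deterministic funnel fate (damaging missense and high-CADD non-coding
survive; tolerated, low-CADD, common, low-quality and zygosity-difference
variants fall at their designated stage).

Methylomes: 100k CpG positions; the baseline level of each CpG is shared by
both twins (monozygotic germline) and drawn from a bimodal mixture — 87.5 %
Beta(140.5, 9.45) (highly methylated, mean 0.937) and 12.5 % Beta(4, 96)
(island-like, mean 0.04) — giving a genome-wide mean of 82.5 %. The
bimodality mirrors real methylomes, where intermediate levels are rare; it
also keeps the binomial tails at the 25-point cutoff small, which a unimodal
Beta of the same mean would not (a design consideration verified by an
independent Monte-Carlo tail oracle, `expected_null_dmc_rate`). A single
Beta prior is selectable via `meth_alpha`/`meth_beta`. Coverage is
negative-binomial (mean 50, size 25) so both coverage bounds are exercised;
counts are binomial. Planted DMCs start near an extreme baseline
(hyper: ~2–15 %, hypo mirrored) and shift the affected twin by ±delta
(default 40 points), the realistic regime for island/shore methylation
switches. In noiseless mode coverage is fixed at 50 and counts are rounded
expectations, with the planted shift applied in whole read counts
(⌈delta·cov/100⌉) so every planted difference clears the threshold exactly
and non-planted sites have difference exactly 0 — making end-to-end recovery
an equality check against the truth manifest. The lambda spike-in draws
apparent methylation at the conversion-error rate (default 0.003, i.e. a
99.7 % conversion rate).

The manifest records expected funnel counts, survivor positions, SV/CNV
genes, DMC positions with per-feature summary counts, and the expected
candidate list; one SV-nominated decoy gene is deliberately left
non-expressed to exercise the hard expression filter. Everything is
deterministic per seed (byte-identical files).

What passing tests do **not** show about real data: caller/annotator error,
mapping and methylation-extraction bias, within-pair somatic mosaicism
structure, realistic population frequency spectra, or DMC spatial
autocorrelation — none of these are modeled.

## Numerical and testing choices

Problem sizes were chosen to exercise every code path while keeping the full
suite fast: the closure dataset uses the default full-scale configuration
(100k CpGs); stochastic recovery pools five seeds (1,000 planted DMCs);
brute-force oracle comparisons run on ≥ 100 random instances against
quadratic scans and per-base set arithmetic. Property tests (hypothesis,
derandomized) cover swap symmetry of discordance classes, sample-swap
antisymmetry of DMC diffs, the coverage-window invariant and BED round-trips.
Percentages are rounded half-up via decimal arithmetic to avoid binary
floating-point ties. Degenerate inputs have defined behavior throughout:
empty funnels yield zero traces, zero-coverage CpGs are retained by readers
and rejected by the level computation, empty BED files are empty tracks, and
a missing arm input skips that arm with a warning rather than failing the
run.
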
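# Methods

## Data model and conventions

A methylome is a per-cytosine table (`chrom, pos, strand, context, meth,
total`) in the Bismark cytosine-report dialect; positions are 1-based,
annotation intervals BED-style 0-based half-open, with conversions kept in
one place (`intervals`/`io`). CpG records exist per strand and are merged
onto the plus-strand coordinate for all mCG analyses (counts summed;
merging is lossless and idempotent) — merging maximizes per-site coverage
at the simulated depth. CH records are strand-specific and never merged.
Coverage rules: CG sites enter analyses when covered ≥ 1×, CH sites ≥ 10×.
The methylation level of a feature is the **unweighted mean of site levels**
within it, not a pooled-count ratio, so deep sites do not dominate.

## Synthetic cohort

The generator builds a genome scaffold (default: three 10-Mb autosomes plus
a 5-Mb X) carrying CpG sites (mean background spacing 120 bp, densified in
CGIs, promoters, imprinted DMRs and planted DMRs), CH sites with fixed
trinucleotide contexts, CGIs, LADs, gene models with one TSS each, a
50-interval imprinted-DMR catalogue, and planted DMRs with known etiologies.
Per-site truth for a sample is assembled by ordered overrides: baseline mCG
(0.85) → PMD depression over a state-specific LAD subset → planted-DMR
etiology levels → iDMRs at 0.50 (0.90 when hypermethylated in a lineage) →
CGIs 0.05 / promoters 0.08 → state-program promoters 0.75 → RPE-signature
promoters (0.05 in RPE states, 0.75 otherwise) → reprogramming CGI errors
0.88 with optional flanking PMDs → X-inactivation structure. Observed
counts: `total ~ Poisson(mean depth)` per emitted record (default 10×; the
≥ 10× CH filter requires per-record depth near 10 for CH sites to survive,
and strand-merged CpGs then average ~20×), and
`meth ~ Binomial(total, p(1-e) + (1-p)e)` with a symmetric bisulfite
error floor e = 0.005.

Cell states: fibroblasts carry deep PMDs (depth 0.35, all LADs); iPSCs none
but CAG-skewed mCH and reprogramming errors; iRPE/xRPE shallow PMDs (0.18,
70% of LADs) with inherited errors, xRPE regaining CAC-skewed mCH and
demethylating the resolved-fate DMR subset; cRPE shallow PMDs without
errors; nRPE no PMDs and the highest, CAC-skewed mCH. An ESC-like state
(iPSC parameters without lineage errors) serves as the properly-reprogrammed
reference for origin tracing.

Lineage memory: each reprogrammed patient draws one error set shared by its
iPSC/iRPE/xRPE samples — CGI errors mostly (70%) from a common error-prone
pool of neutral promoter CGIs (never state-program or signature promoters,
so planted identity and planted error stay separable) plus patient-specific
extras; 6 iDMRs hypermethylated in every lineage with 13 extras in the
second patient (12% and 38% of the catalogue); and, in female lineages, 10%
of XCI-subject genes escape (TSS regions at 0.02). The female X is modeled
as the aggregate of two alleles: XCI-subject promoters sit at a per-gene
level in 0.25–0.42, males at 0.04. Expression is log-normal per gene with
additive log2 effects: −2 for a methylated/errored promoter, +1 for escaped
genes in reprogrammed female samples, and an inverse mCH coupling scaled by
the state's global mCH level; FPKM = 2^log2, hence non-negative.

What the generator does **not** emulate: read-level artifacts (mapping
bias, M-bias, SNPs), fragment-level autocorrelation of coverage, partial
(continuous-gradient) PMD boundaries, allele-resolved data, and realistic
inter-individual variability beyond the planted error sets. Passing tests
therefore demonstrate correctness of the pipeline's logic under the stated
statistical model, not robustness to every artifact of real libraries.

## Segmentation

Change-point detection is least-squares binary segmentation with bottom-up
pruning: segments are recursively split at the SSE-optimal point until no
split helps, then adjacent segments are greedily re-merged while the
cheapest merge raises total SSE by at most the penalty. The pruning phase is
what lets a short deviating interval (a CGI dip, a small PMD) be found
inside a long flat segment — a penalty-gated greedy descent provably misses
those, because the best *single* split of flat+spike explains almost
nothing. Defaults: penalty 3.0 (detects a 10-kb, 30-point step at 10×,
ignores depth noise, whose per-site variance is ≈ p(1−p)/10), minimum 20
sites per segment, blocks broken at inter-site gaps > 100 kb so assembly
gaps are not bridged. Domain boundaries fall midway between flanking CpGs;
the nCpG-weighted mean of domain levels equals the chromosome mean by
construction. PMD thresholds are strict (> 10 kb, < 70%). Whether
segmentation runs on site levels or binned means is exposed via the input
(pre-binned tables pass through the same API).

## DMR calling

Candidates come from segmenting the per-CpG group-mean difference signal
(penalty 1.5, ≥ 10 sites); each candidate gets a two-sided Mann-Whitney U
comparing all per-CpG, per-sample levels of the two groups, BH adjustment is
genome-wide over all candidate segments, and the reported set satisfies
nCpG ≥ 20, q < 0.01, |Δ| > 0.30 (Δ = difference of group means; the group
mean, not median, is used). Chromosomes X and Y are excluded by default.
metilene's exact 2-D KS machinery is deliberately not re-implemented: the
package's contribution is the filtering/classification logic downstream, the
caller is validated by planted-truth recovery (power 1.0 at Δ = 0.4 with 2v4
samples at 10×; zero false calls over 20 null cohorts), and a
metilene-format reader accepts external output.

Origin/fate rules quantify the qualitative tracing logic: iPSC and ESC are
"similarly methylated" when |Δ| ≤ 0.15; an iPSC state is "transmitted" when
iPSC and iRPE sit on the same side of 0.5; fate is resolved-in-xRPE when
|xRPE − nRPE| < |iRPE − nRPE| − 0.10. All three constants are arguments.
K-means (k-means++, fixed seed, n_init 10) renumbers clusters by descending
mean iPSC level so reporting is reproducible without subjective ordering.

## Clustering

The decomposition orientation is X (features × samples) ≈ S·A. Sources are
rescaled to unit variance so loadings are in SD units (making the
"|loading| ≥ 5" contributor threshold portable) with the scale absorbed into
the mixing matrix; component sign is fixed so the largest-magnitude mixing
weight is positive. The "common component" is the mixing row with the lowest
coefficient of variation, but it is removed **only when** that CV is ≤ 0.5:
in feature spaces where no shared baseline survives centering (promoters,
where almost all features sit near 0.08 in every sample), the lowest-CV row
is an ordinary contrast and removing it distorts distances — keeping the
full component space makes component-space Ward clustering agree with
raw-feature Ward up to rotation. Missing features are dropped listwise (and
logged), never imputed. ICA convergence failures are reported with the seed
and iteration count. Default component count: samples − 1. Component
identities (IC numbering) are run-specific; components are matched to
biology by their discrimination pattern (exact rank-sum p on mixing
weights), not by index.

## Imprinting, XCI, mCH, enrichment

iDMR status bands default to intermediate = [0.25, 0.75], symmetric around
the expected 50% allelic imprint; hyper/hypo outside. XCI candidacy uses
group means over non-reprogrammed samples (male ≤ 0.10, female in
[0.20, 0.45], inclusive); callability requires ≥ 5 covered CpGs in
TSS ± 500 bp; escape requires ≤ 0.05 in **all** reprogrammed samples of the
lineage (an any-sample mode exists but is off). Calls are monotone in the
thresholds. CH contexts are classified by literal trinucleotide with the
CG-at-second-position exception: CCG is displayed as its own axis but
excluded from aggregate CHG means by default (`ccg_in_chg` restores literal
classification). Context ranking breaks ties lexicographically. Gene-set
enrichment is classic per-term Fisher with term-size (10–500) and reporting
(p < 0.01, overlap ≥ 3) filters; topGO's elim decorrelation is out of scope,
and BH-adjusted values are exported alongside without gating the report.
The default enrichment universe is the feature-covered gene set. Odds
ratios are conditional-MLE, with the sample odds ratio also exported.

## Problem sizes and numerics

The bundled test suite and acceptance script run the cohort analyses on a
reduced scaffold (two 3-Mb autosomes + 1.5-Mb X, 16 samples, ~71k CpGs) and
the segmentation benchmark on the full default scaffold (three 10-Mb
autosomes, ~324k CpGs), sizes chosen so the whole analysis is a
minute-scale, single-CPU computation; all statistical structure is scale-
free except gene-count-limited correlations, which are noted where they
appear. Every random draw flows from a single integer seed through
`numpy.random.default_rng`; re-running any stage with the same seed is
bit-reproducible. Degenerate inputs are defined away rather than special-
cased: empty domain sets refuse MDL plotting, constant series report NaN
correlations, chromosomes with fewer sites than one segment are skipped
with a warning.

## Known limitations

- The DMR caller's boundary precision is one inter-CpG spacing; it is not a
  smoothing caller and will fragment very long gradual differences.
- Greedy agglomerative pruning is not exactly optimal partitioning (PELT
  would be); on planted steps the difference is confined to ±few sites.
- The common-component heuristic assumes the baseline is near-constant in
  mixing weights; decompositions of already-standardized matrices may have
  no removable component (by design, nothing is then removed).
- Real iDMRs and XCI bands show inter-individual drift that the planted
  bands do not; classifier accuracy on real data is bounded by band choice.
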
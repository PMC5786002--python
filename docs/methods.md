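# Methods

## Segmentation model

A WGBS methylome is modeled as an ordered sequence of CpG dyads, each
carrying methylated/total read counts (strand-merged; 0-based half-open
coordinates, a CpG occupying `[pos, pos+2)`). Segmentation proceeds in
two stages.

**PMR detection.** Polarized chromatin shows methylation levels near the
two modes of the genome-wide mixture (close to 0 at regulatory regions,
close to 1 elsewhere); partially methylated regions (PMRs) show
disordered, intermediate levels. The *disorder score* of CpG *i* is the
fraction of CpGs in the centered `window_cpgs = 101` window whose
observed level lies strictly inside `disorder_bounds = (0.3, 0.7)`.
CpGs whose centered window would be truncated carry the nearest
full-window score; chromosomes with fewer CpGs than one window are
skipped. The band is a tunable: it must exclude both class modes at the
working coverage. At 30× the binomial sampling noise of a
fully-methylated CpG (latent level ≈ 0.85) spills far below 0.9, so the
band cannot extend near the modes; (0.3, 0.7) separates fully methylated
windows (score ≈ 0.08) from disordered windows (score ≈ 0.45) by
several window standard deviations, while wider bands such as (0.1, 0.9)
make the two states statistically indistinguishable at realistic
coverage.

A two-state Gaussian HMM on the score is fit by EM (means initialized at
the 25th/75th score percentiles, shared initial variance, sticky
transitions 0.99/0.01; convergence when the log-likelihood improves by
less than 1e-4, at most 100 iterations; backed by
`hmmlearn.GaussianHMM`). Decoding is posterior by default (Viterbi by
flag): a CpG is disordered when P(high state) > 0.5. Degenerate fits and
state collapses (mean separation < `min_state_separation = 0.1`,
e.g. on effectively one-state data) fall back to a fixed 0.5 score
threshold. High-state runs separated by fewer than one window of CpGs
are fused, and fused runs spanning fewer CpGs than one window are
discarded: one window is the resolution limit of the score, and
sub-window calls are indistinguishable from score bumps that
intermediate-methylation features (LMRs) produce. PMR coordinates span
the first to last member CpG dyad.

**Hypomethylated-region detection.** PMR CpGs are masked, extended by
`mask_margin_cpgs` (default half a window) on each side to absorb the
one-window boundary uncertainty. The retained methylome is smoothed with
a running window of `smooth_cpgs = 3` (coverage-weighted mean by
default; plain mean by flag), truncated at chromosome ends and at masked
gaps — windows and runs never reach across a PMR. Candidate regions are
maximal runs of CpGs with smoothed level ≤ `max_meth = 0.50`; a
candidate is kept when it has at least `min_cpgs = 3` member CpGs, at
least `min_cpgs` of them with *raw* level ≤ `max_meth`, and a
coverage-weighted mean ≤ `max_meth`. The support conditions are part of
the detection rule by design: under 3-CpG smoothing a single
unmethylated CpG smears into a 3-long run of smoothed-low values, so a
rule counting only smoothed CpGs degenerates to "one low CpG" and its
shuffle FDR (below) cannot reach useful levels on any methylome with a
realistic scattered-low CpG fraction. Regions with ≥ `lmr_umr_cutoff =
30` CpGs are classified UMR, smaller ones LMR.

**FDR calibration.** Suitable detection parameters are identified by
comparing region counts between the original methylome and a randomized
one: the PMR-masked methylome with its (meth, total) pairs permuted
across the fixed CpG positions, per chromosome, both smoothed
identically. FDR = randomized count / original count (defined as 1 when
the original count is zero); the permuted count may be averaged over
`n_randomizations` independent permutations (the acceptance path uses
10) to reduce the Monte-Carlo error of the estimate. The chosen grid
point is the standard (3, 0.50) when its FDR clears `fdr_threshold =
0.05`, otherwise the least stringent passing point; no point passing is
an error. Masking precedes permutation deliberately: permuting first
would scatter PMR-origin intermediate levels into the null and the
estimate would no longer describe the hypomethylated-region detector.

**Stage merging.** Segmentations of several stages are merged per class
family (hypomethylated vs PMR): overlapping or book-ended intervals are
unioned, and merged hypomethylated intervals are re-classified LMR/UMR
by their CpG count in the pooled (count-summed) union methylome.

## Annotation

A gene is eligible for a genic UMR when its genic extent
`[min(TSS,TES), max(TSS,TES))` minus CpG-island coverage is ≥ 1.5 kb.
Its gUMR is the union of UMRs whose interval contains the TSS coordinate
(single-base test, the strictest reading of "overlaps the TSS";
config-widenable), intersected with the genic extent, minus CpG islands,
kept when ≥ 10 CpGs remain. Fragments of one gene are one logical unit —
lengths summed, CpGs counted jointly — because all downstream criteria
are per-gene. Extended genic demethylation is flagged when the gUMR
totals ≥ 5 kb and/or ≥ 25% of the gene. FMRs are the per-chromosome
complement of CGIs ∪ LMRs ∪ UMRs ∪ PMRs. Gene proximity maps a region to
the gene minimizing boundary-to-extent distance within 10 kb (ties:
smaller TSS distance, then lexicographic id).

## Differential methylation

Regions are predefined (FMRs, CGIs, LMRs, gUMRs, PMRs). Replicates with
median CpG coverage ≤ 4 are excluded; fewer than two survivors per group
is an error. PMRs overlapping a single gene by ≥ 75% are removed before
testing, since genic regions downstream of gUMRs are frequently
partially methylated. Per region, only CpGs covered (≥ 1 read) in every
retained sample of both groups are used; group means pool counts
(coverage-weighted). The p-value is a two-sided Mann–Whitney rank-sum
test on the pooled per-(CpG, sample) levels — a distribution-free region
test; Welch's t on per-sample region means is available by flag. A
region is significant when |Δ| > 0.10 and p ≤ 0.001 (raw p by design;
Benjamini–Hochberg q-values are reported but do not gate). Regions with
fewer than 3 common CpGs are reported untestable (p = 1) rather than
tested — the rank test is degenerate there, mirroring the 3-CpG
detection floor. The pooled per-CpG observations within a region share
group labels exchangeably under the null, so the two-sided test is valid
though conservative in combination with the 10% effect gate (the joint
false-positive rate is held to ≤ 2× the nominal α in the acceptance
suite).

## Chromatin marks

Each coverage track is scaled by G / total, where G is the geometric
mean of the genome-wide coverage integrals of the tracks being compared;
log-scaled totals are thereby equalized. Signal per target is the
integral of scaled coverage over the target: promoters (TSS ± 1 kb) for
H3K27ac, H3K9ac and H3K4me3; genic regions (TSS–TES) for H3K36me3,
H3K9me3, H3K27me3 and H3K4me1; explicit regions otherwise (LMR windows,
5hmC — treated as generic coverage). Condition ratios are log2 of scaled
signals with a pseudocount of 1% of the mean per-kb scaled signal
(averaged over the two tracks, scaled by target length) to bound ratios
at empty regions; ratios of several marks are combined as the arithmetic
mean of the log2 ratios.

For the expression-rank analysis, differential genes (q < 0.05) are
ranked by log2 fold-change. Per mark, a cubic polynomial of rank is fit
to the mark's log2 ratio (R² = 1 − SSres/SStot on the ratio): cubic is
the simplest closed-form family capturing the monotone-with-saturation
trend; LOESS would serve equally and the choice is declared, not
derived. The combined model regresses the rank on two marks' ratios with
quadratic and interaction terms and reports R² on the rank — the
fraction of the expression ranking the marks explain. For two marks with
coupling ρ to the standardized expression change and independent unit
noise, the best linear predictor attains R² = 2ρ²/(1 + ρ²) on the
underlying change; the rank transform costs a few percent of that, which
the acceptance band (±0.1) absorbs.

## SNP enrichment

SNP sets are leads plus precomputed LD proxies (R² > 0.8 retrieval is
upstream provenance; duplicates removed on union). Null sets are drawn
with the identical length multiset as the LMRs: chromosome with
probability proportional to length among chromosomes long enough, start
uniform, optional exclusion mask with bounded rejection retries;
`n_iter = 100` by default. A SNP at position p is inside `[start, end)`
iff start ≤ p < end. Fold = observed in-LMR SNPs / mean over null sets.
Significance is a 1-df Pearson chi-squared (no continuity correction) on
the 2×2 table of observed (in, out) versus pooled-null counts scaled to
the observed total; an empirical permutation p,
(1 + #{null ≥ observed}) / (1 + n_iter), is always reported as a
cross-check and is the only p when no null draw captures a SNP.

## Synthetic data: what it emulates, and what it does not

The generator plants a fixed composition per 5 Mb — 17 PMRs (50–200 kb),
4 UMRs (3.5–6 kb, half with a CpG-island core of ~30% of their span),
36 LMRs (0.8–2.2 kb) — separated by fully methylated spacers, PMRs
covering ≈ 43% of the genome. Inter-CpG gaps are 2 + geometric with mean
≈ 100 bp, five-fold densified inside islands (~50k CpGs per 5 Mb).
Latent per-CpG methylation is Beta per class — FMR Beta(17,3), UMR
Beta(2,38), LMR Beta(6,14), PMR Uniform(0,1), CGI Beta(1,49) — with
binomial read counts at zero-truncated Poisson coverage (default 30×,
the depth of a replicate-pooled stage). Replicate groups add
beta-binomial overdispersion (per-replicate Beta re-draw around the
latent mean, concentration 50) so the differential test faces realistic
between-replicate noise. Planted hypomethylated truth is labeled by its
*realized* CpG count against the 30-CpG cutoff, and truth intervals span
the planted CpG support — the extent a CpG-level caller can recover.

Two deliberate departures from naive downscaling: special-segment counts
are fixed rather than redrawn per seed, so the study conditions are
stable across seeds; and UMR/LMR counts per Mb are set to reproduce the
CpG-weighted scattered-low fraction of real non-PMD methylomes (≈ 3% of
retained CpGs) rather than to scale genome-wide region counts linearly
into 5 Mb. The shuffle-FDR procedure responds (roughly cubically) to
that fraction, so matching it is what makes the toy informative about
the real calibration; matching region counts instead would create a
low-CpG mixture no real methylome has. Consequences for interpretation:
passing tests demonstrate correct behavior under clustered Beta-mixture
methylation with independent CpGs within class, not under real-genome
features the generator omits — CpG-density autocorrelation beyond
islands, sequence-driven coverage bias, bisulfite conversion failure,
copy-number variation, or chromosome-scale heterogeneity. Mark tracks
are flat within targets (ratios exactly encoded, plus a uniform
background), so quantification is tested for its arithmetic, not for
peak-shape robustness. SNP placement is uniform within/outside LMRs with
no LD clustering.

Every generator draws from a domain-separated RNG stream
(`default_rng([domain, seed])`), so the same seed can safely feed
several generators without their streams colliding.

## Numerical and degenerate-input choices

* Region ends are last-CpG + 2 (covering the dyad), half-open.
* Zero-coverage CpGs are dropped at ingestion; every downstream
  statistic is coverage-weighted over observed reads.
* Rank-sum with all values tied returns p = 1 (no evidence either way).
* FDR with zero original regions is defined as 1.
* `chi2_2x2` uses the closed form N(ad−bc)²/(r₁r₂c₁c₂); degenerate
  margins return (0, 1).
* Calibration permutation seeds derive from the user seed by fixed
  offsets; no hidden global RNG anywhere.
* lstsq (rcond default) fits the polynomial regressions; constant
  predictors return R² = 0 with a warning rather than raising.

## Known limitations

* The disorder-score HMM treats heavily overlapping windows as
  conditionally independent emissions; transition probabilities are
  therefore not interpretable as per-CpG switch rates, and PMR
  boundaries carry one-window (~±50 CpG) uncertainty — hence the
  half-window mask margin and the sub-window call filter.
* The randomization preserves each chromosome's marginal (level,
  coverage) multiset but not local autocorrelation; the FDR it estimates
  concerns scattered-low false positives only.
* Per-(CpG, sample) pooling in the rank-sum test treats CpGs within a
  region as independent observations; with strong within-region latent
  correlation the nominal p is optimistic, which the |Δ| > 10% gate and
  the acceptance bound on the joint rate mitigate but do not remove.
* De-novo DMR discovery (binary-segmentation style), LD computation,
  peak calling and chromatin-state learning are out of scope; predefined
  regions, precomputed proxy tables and coverage tracks are the inputs.
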
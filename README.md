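# segmeth

Whole-genome bisulfite sequencing (WGBS) methylomes of differentiated
cells partition into a small set of recurring region classes: large
**partially methylated regions** (PMRs) with highly disordered,
intermediate CpG methylation; CpG-rich, essentially unmethylated
regions (**UMRs**, typically promoters and demethylated gene bodies);
small CpG-poor **low-methylated regions** (**LMRs**, 10–50% methylation,
the signature of distal *cis*-regulatory elements); and the fully
methylated remainder (**FMRs**). `segmeth` implements this segmentation
and the region-level analyses built on it, for researchers studying
methylome dynamics in development and disease (the motivating system is
the cardiomyocyte methylome across fetal, infantile, adult non-failing
and failing stages):

* **Segmentation.** A per-CpG disorder score (fraction of a centered
  101-CpG window with intermediate observed methylation) is decoded by a
  two-state Gaussian HMM into PMRs; after PMR masking and 3-CpG
  smoothing, maximal runs of ≥ 3 CpGs with smoothed mCpG ≤ 50% become
  hypomethylated regions, split at 30 CpGs into LMRs (< 30) and UMRs
  (≥ 30). Detection parameters are calibrated so that the false
  discovery rate — the region count on a randomized (per-chromosome
  permuted) methylome divided by the count on the original — stays
  below 5%.
* **Annotation.** Genic UMRs (gUMRs: the island-free genic portion of a
  TSS-overlapping UMR), flags for genes with extended demethylation
  (gUMR ≥ 5 kb and/or ≥ 25% of the gene), FMRs as the genomic
  complement, and ≤ 10 kb gene-proximity assignment.
* **Differential methylation.** Replicate-aware region tests (coverage
  ≥ 1 in all samples per CpG; replicates with median coverage ≤ 4
  excluded; PMRs ≥ 75% inside a single gene removed); significant when
  |Δ mCpG| > 10% and rank-sum p ≤ 0.001.
* **Chromatin marks.** Geometric-mean normalization of coverage tracks,
  promoter (TSS ± 1 kb) or genic (TSS–TES) quantification by mark,
  log-scale averaging of mark ratios, and polynomial regression of mark
  ratios against the expression-change rank of differential genes.
* **SNP enrichment.** Fold enrichment of trait-associated SNP sets
  (leads plus precomputed LD proxies) in LMRs versus length-matched
  random region sets, with chi-squared and empirical significance.
* **Synthetic data.** Seeded generators with planted ground truth for
  every input — methylomes, replicate groups, mark tracks, DE tables,
  SNP sets — so every stage is testable offline.

## Worked example

```python
import warnings; warnings.filterwarnings("ignore")
from segmeth.synthetic import build_layout, simulate_methylome, simulate_snp_sets
from segmeth.segmentation import SegmentationParams, segment_methylome
from segmeth.enrichment import sample_matched_regions, snp_region_enrichment

layout = build_layout(seed=1)                       # 5-Mb planted genome
methylome, truth = simulate_methylome(layout, mean_coverage=30, seed=1)

pmrs, hypo, cal = segment_methylome(
    methylome, SegmentationParams(), seed=1,
    calibration_grid=[(3, 0.5), (4, 0.5), (5, 0.5)], n_randomizations=10,
)
lmrs = [r for r in hypo if r.region_class == "LMR"]

snps, _ = simulate_snp_sets(lmrs, layout.chrom_sizes, fold=3.0, n_snps=500, seed=1)
nulls = sample_matched_regions(lmrs, layout.chrom_sizes, n_iter=100, seed=1)
res = snp_region_enrichment(snps, lmrs, nulls)
```

Output of the session above:

```
simulated 49987 CpGs on a 5-Mb chromosome (115 planted segments)
called 17 PMRs, 37 LMRs, 5 UMRs
calibration chose (min_cpgs, max_meth) = (3, 0.5) at shuffle FDR = 1.4%
SNP enrichment in LMRs: fold = 3.24, -log10 p = 1.6 (14 of 500 SNPs in LMRs, 4.3 expected)
```

Reading the numbers: the 17 called PMRs match the 17 planted disordered
domains; the 42 hypomethylated regions recover the planted LMRs/UMRs.
The calibration confirms that at the standard detection parameters
(≥ 3 CpGs, mean mCpG ≤ 50%) a permuted methylome yields only 1.4% as
many regions as the real one — the detections are not an artifact of the
marginal methylation distribution. The SNP set was planted at 3-fold
enrichment inside LMRs and the estimator returns 3.24 (14 SNPs observed
in LMRs against 4.3 expected from 100 length-matched random region
sets).

The same stages are available from the shell — `segmeth simulate`,
`segmeth segment`, `segmeth annotate`, `segmeth dmr`, `segmeth marks`,
`segmeth enrich` — and `segmeth pipeline run config.yaml` orchestrates
them end to end with a checksummed output manifest (see
`segmeth pipeline validate --help`).

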
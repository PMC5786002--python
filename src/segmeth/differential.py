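"""Replicate-aware differential methylation over predefined regions.

The test compares two replicate groups region by region (FMRs, CpG
islands, LMRs, gUMRs, PMRs). For each region, only CpGs covered by at
least one read in *every* retained sample of both groups enter the
statistic. Group means are coverage-weighted; the p-value comes from a
two-sided Mann-Whitney rank-sum test on the pooled per-(CpG, sample)
methylation levels. A region is significant when |mean difference| > 10%
and p <= 0.001 — the raw-p rule used for region-level DMR calls;
Benjamini-Hochberg q-values are reported for transparency but do not gate
significance.

Replicates with median CpG coverage <= 4 are excluded beforehand, and
PMRs lying at least 75% within a single gene are removed, since genic
regions downstream of gUMRs are frequently partially methylated.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import reduce

import numpy as np
from scipy import stats

from . import intervals as iv
from .io import GeneModel, GenomicRegion, Methylome


@dataclass
class DmrTestParams:
    min_diff: float = 0.10
    alpha: float = 0.001
    min_cov_per_cpg: int = 1
    max_median_cov_exclude: int = 4
    pmr_gene_overlap_exclude: float = 0.75
    min_testable_cpgs: int = 3
    statistic: str = "ranksum"  # or 'welch' on per-sample region means


@dataclass
class DmrResult:
    region: GenomicRegion
    mean_a: float
    mean_b: float
    diff: float  # mean_b - mean_a
    p_value: float
    q_value: float | None
    n_cpg_tested: int
    significant: bool
    untestable: bool = False


@dataclass(frozen=True)
class ReplicateExclusion:
    sample_id: str
    reason: str
    median_coverage: float | None


def filter_replicates(
    methylomes: list[Methylome], params: DmrTestParams | None = None
) -> tuple[list[Methylome], list[ReplicateExclusion]]:
    """Drop replicates with median CpG coverage <= 4 (or no CpGs)."""
    params = params or DmrTestParams()
    kept, excluded = [], []
    for m in methylomes:
        totals = [c.total for c in m.data.values() if len(c)]
        if not totals:
            excluded.append(ReplicateExclusion(m.sample_id, "no CpGs", None))
            continue
        med = float(np.median(np.concatenate(totals)))
        if med <= params.max_median_cov_exclude:
            excluded.append(
                ReplicateExclusion(m.sample_id, f"median coverage {med:g} <= 4", med)
            )
        else:
            kept.append(m)
    return kept, excluded


def exclude_gene_spanning_pmrs(
    pmrs: list[GenomicRegion],
    genes: list[GeneModel],
    min_overlap: float = 0.75,
) -> tuple[list[GenomicRegion], list[GenomicRegion]]:
    """Remove PMRs overlapping a single gene by at least ``min_overlap``.

    Returns (kept, removed). The overlap fraction is |PMR ∩ genic extent|
    / |PMR|, evaluated per gene — two genes covering 40% each do not
    trigger removal.
    """
    genes_by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        genes_by_chrom.setdefault(g.chrom, []).append(g)
    kept, removed = [], []
    for p in pmrs:
        frac = 0.0
        for g in genes_by_chrom.get(p.chrom, []):
            ov = iv.overlap_length(p.interval, g.extent)
            frac = max(frac, ov / p.length)
        (removed if frac >= min_overlap else kept).append(p)
    return kept, removed


def _region_levels(
    region: GenomicRegion,
    samples: list[Methylome],
    other: list[Methylome],
    min_cov: int,
):
    """Positions covered (>= min_cov) in every sample of both groups, and
    per-sample (meth, total) arrays at those positions for ``samples``."""
    pos_sets = []
    for m in samples + other:
        calls = m.data.get(region.chrom)
        if calls is None:
            return None, []
        i0 = int(np.searchsorted(calls.pos, region.start, side="left"))
        i1 = int(np.searchsorted(calls.pos, region.end, side="left"))
        p = calls.pos[i0:i1][calls.total[i0:i1] >= min_cov]
        pos_sets.append(p)
    common = reduce(np.intersect1d, pos_sets)
    per_sample = []
    for m in samples:
        calls = m.data[region.chrom]
        idx = np.searchsorted(calls.pos, common)
        per_sample.append((calls.meth[idx], calls.total[idx]))
    return common, per_sample


def region_dmr_test(
    regions: list[GenomicRegion],
    group_a: list[Methylome],
    group_b: list[Methylome],
    params: DmrTestParams | None = None,
) -> list[DmrResult]:
    """Test each region for differential methylation between two groups.

    Groups are first passed through the median-coverage replicate filter;
    fewer than two surviving replicates in either group is an error.
    Regions with fewer than ``params.min_testable_cpgs`` commonly covered
    CpGs are reported untestable (p = 1, not significant) rather than
    tested, mirroring the 3-CpG detection floor.
    """
    params = params or DmrTestParams()
    ga, _ = filter_replicates(group_a, params)
    gb, _ = filter_replicates(group_b, params)
    if len(ga) < 2 or len(gb) < 2:
        raise ValueError(
            f"need >= 2 replicates per group after coverage filtering "
            f"(got {len(ga)} vs {len(gb)})"
        )

    raw: list[DmrResult] = []
    for region in regions:
        common, per_a = _region_levels(region, ga, gb, params.min_cov_per_cpg)
        if common is None or len(common) == 0:
            raw.append(
                DmrResult(region, np.nan, np.nan, 0.0, 1.0, None, 0, False, True)
            )
            continue
        _, per_b = _region_levels(region, gb, ga, params.min_cov_per_cpg)
        mean_a = _pooled_mean(per_a)
        mean_b = _pooled_mean(per_b)
        diff = mean_b - mean_a
        n = len(common)
        if n < params.min_testable_cpgs:
            raw.append(
                DmrResult(region, mean_a, mean_b, diff, 1.0, None, n, False, True)
            )
            continue
        p = _group_pvalue(per_a, per_b, params.statistic)
        sig = abs(diff) > params.min_diff and p <= params.alpha
        raw.append(DmrResult(region, mean_a, mean_b, diff, p, None, n, sig))

    _attach_qvalues(raw)
    return raw


def _pooled_mean(per_sample) -> float:
    meth = sum(int(m.sum()) for m, _ in per_sample)
    total = sum(int(t.sum()) for _, t in per_sample)
    return meth / total if total else np.nan


def _group_pvalue(per_a, per_b, statistic: str) -> float:
    if statistic == "welch":
        ma = [float(m.sum() / t.sum()) for m, t in per_a]
        mb = [float(m.sum() / t.sum()) for m, t in per_b]
        if np.ptp(ma + mb) == 0:
            return 1.0
        return float(stats.ttest_ind(ma, mb, equal_var=False).pvalue)
    xa = np.concatenate([m / t for m, t in per_a])
    xb = np.concatenate([m / t for m, t in per_b])
    if np.ptp(np.concatenate([xa, xb])) == 0:
        return 1.0  # all values tied: no evidence either way
    return float(stats.mannwhitneyu(xa, xb, alternative="two-sided").pvalue)


def _attach_qvalues(results: list[DmrResult]) -> None:
    from statsmodels.stats.multitest import multipletests

    idx = [i for i, r in enumerate(results) if not r.untestable]
    if not idx:
        return
    pvals = [results[i].p_value for i in idx]
    q = multipletests(pvals, method="fdr_bh")[1]
    for i, qi in zip(idx, q):
        results[i].q_value = float(qi)
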
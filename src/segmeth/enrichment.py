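"""Enrichment of trait-associated SNPs in low-methylated regions.

Disease-associated SNP sets (GWAS lead SNPs expanded with precomputed
linkage-disequilibrium proxies) are intersected with LMRs and compared to
length-matched region sets sampled uniformly from the genome. Fold
enrichment is observed / expected (mean over null draws); significance
comes from a 1-df chi-squared test on the 2x2 in/out table of observed
versus pooled-null counts scaled to the observed total, with an empirical
permutation p-value always reported alongside as a cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import stats

from .io import GenomicRegion


@dataclass
class SnpSet:
    """Positions (0-based) of trait-associated SNPs, duplicates removed."""

    trait: str
    positions: list[tuple[str, int]]
    provenance: list[str] = field(default_factory=list)  # 'lead' or 'proxy'

    def __post_init__(self):
        if not self.provenance:
            self.provenance = ["lead"] * len(self.positions)
        if len(self.provenance) != len(self.positions):
            raise ValueError("provenance length mismatch")
        if len(set(self.positions)) != len(self.positions):
            raise ValueError("duplicate SNP positions within a trait")

    def __len__(self) -> int:
        return len(self.positions)


@dataclass
class EnrichmentResult:
    trait: str
    observed_in: int
    expected_in: float
    fold: float | None
    chi2: float | None
    p_value: float
    p_empirical: float
    neg_log10_p: float
    n_snps: int
    n_iter: int


def expand_with_proxies(
    leads: SnpSet, proxy_table: dict[tuple[str, int], list[tuple[str, int]]]
) -> SnpSet:
    """Union of lead SNPs and their LD proxies, duplicates removed.

    ``proxy_table`` maps a lead position to its proxy positions (an
    externally precomputed R^2 > 0.8 table; LD retrieval itself is out of
    scope). A proxy listed for several leads, or coinciding with a lead,
    appears once.
    """
    positions = list(leads.positions)
    provenance = list(leads.provenance)
    seen = set(positions)
    for lead in leads.positions:
        for proxy in proxy_table.get(lead, []):
            if proxy not in seen:
                seen.add(proxy)
                positions.append(proxy)
                provenance.append("proxy")
    return SnpSet(trait=leads.trait, positions=positions, provenance=provenance)


class _RegionIndex:
    """Sorted per-chromosome boundaries for O(log n) point-in-region tests."""

    def __init__(self, regions: list[GenomicRegion]):
        from . import intervals as iv

        self.bounds: dict[str, np.ndarray] = {}
        per_chrom: dict[str, list[tuple[int, int]]] = {}
        for r in regions:
            per_chrom.setdefault(r.chrom, []).append(r.interval)
        for chrom, ivs in per_chrom.items():
            merged = iv.merge(ivs, book_ended=False)
            self.bounds[chrom] = np.array(
                [x for s_e in merged for x in s_e], dtype=np.int64
            )

    def contains(self, chrom: str, pos: np.ndarray) -> np.ndarray:
        b = self.bounds.get(chrom)
        if b is None:
            return np.zeros(len(pos), dtype=bool)
        # odd insertion index => start <= pos < end for some region
        return (np.searchsorted(b, pos, side="right") % 2).astype(bool)


def count_snps_in_regions(snps: SnpSet, regions: list[GenomicRegion]) -> int:
    idx = _RegionIndex(regions)
    per_chrom: dict[str, list[int]] = {}
    for chrom, pos in snps.positions:
        per_chrom.setdefault(chrom, []).append(pos)
    n = 0
    for chrom, pos in per_chrom.items():
        n += int(idx.contains(chrom, np.asarray(pos, dtype=np.int64)).sum())
    return n


def sample_matched_regions(
    lmrs: list[GenomicRegion],
    chrom_sizes: dict[str, int],
    n_iter: int = 100,
    seed: int = 0,
    mask: list[GenomicRegion] | None = None,
    max_retries: int = 1000,
) -> list[list[GenomicRegion]]:
    """Draw ``n_iter`` null region sets length-matched to the LMR set.

    Every null set has the same number of regions and the identical
    length multiset as the LMRs. For each region a chromosome is chosen
    with probability proportional to its length (among chromosomes long
    enough), then a start uniform over the valid range; placements
    overlapping the optional exclusion mask are rejected and redrawn, up
    to ``max_retries`` times.
    """
    rng = np.random.default_rng(seed)
    lengths = np.array([r.length for r in lmrs], dtype=np.int64)
    chroms = sorted(chrom_sizes)
    sizes = np.array([chrom_sizes[c] for c in chroms], dtype=np.int64)
    mask_idx = _RegionIndex(mask) if mask else None
    if len(sizes) == 0 or (len(lengths) and lengths.max() > sizes.max()):
        bad = int(lengths.max()) if len(lengths) else 0
        raise ValueError(f"region length {bad} exceeds every chromosome")

    out: list[list[GenomicRegion]] = []
    n = len(lengths)
    for _ in range(n_iter):
        # draw every placement of the set at once; redraw mask offenders
        ci = np.empty(n, dtype=np.int64)
        start = np.empty(n, dtype=np.int64)
        todo = np.arange(n)
        for _round in range(max_retries):
            lns = lengths[todo]
            ok = sizes[None, :] >= lns[:, None]
            w = np.where(ok, sizes[None, :], 0).astype(np.float64)
            w /= w.sum(axis=1, keepdims=True)
            u = rng.random(len(todo))
            ci[todo] = (w.cumsum(axis=1) < u[:, None]).sum(axis=1)
            room = sizes[ci[todo]] - lns + 1
            start[todo] = (rng.random(len(todo)) * room).astype(np.int64)
            if mask_idx is None:
                todo = todo[:0]
                break
            bad = []
            for j in todo:
                probe = np.array([start[j], start[j] + lengths[j] - 1], dtype=np.int64)
                if mask_idx.contains(chroms[ci[j]], probe).any():
                    bad.append(j)
            todo = np.array(bad, dtype=np.int64)
            if len(todo) == 0:
                break
        if len(todo):
            raise RuntimeError(
                f"failed to place {len(todo)} regions after {max_retries} retries "
                "(mask too restrictive)"
            )
        out.append(
            [
                GenomicRegion(chroms[c], int(s), int(s + ln), "raw")
                for c, s, ln in zip(ci, start, lengths)
            ]
        )
    return out


def snp_region_enrichment(
    snps: SnpSet,
    lmrs: list[GenomicRegion],
    null_sets: list[list[GenomicRegion]],
) -> EnrichmentResult:
    """Fold enrichment of a SNP set in LMRs over length-matched nulls.

    observed_in is the number of SNPs falling in any LMR; expected_in the
    mean over null sets. The chi-squared statistic (1 df, no continuity
    correction) is computed on the 2x2 table of observed (in, out) versus
    pooled-null (in, out) scaled to the observed total. When no null draw
    captures any SNP the fold is undefined and only the empirical p
    (1 + #null >= observed) / (1 + n_iter) is meaningful.
    """
    n = len(snps)
    observed = count_snps_in_regions(snps, lmrs)
    null_counts = np.array(
        [count_snps_in_regions(snps, ns) for ns in null_sets], dtype=np.float64
    )
    expected = float(null_counts.mean())
    n_iter = len(null_sets)
    p_emp = float((1 + (null_counts >= observed).sum()) / (1 + n_iter))

    if expected > 0:
        fold = observed / expected
        table = np.array(
            [[observed, n - observed], [expected, n - expected]], dtype=np.float64
        )
        chi2, p = chi2_2x2(table)
    else:
        fold, chi2, p = None, None, p_emp
    return EnrichmentResult(
        trait=snps.trait,
        observed_in=observed,
        expected_in=expected,
        fold=fold,
        chi2=chi2,
        p_value=p,
        p_empirical=p_emp,
        neg_log10_p=float(-np.log10(p)) if p > 0 else np.inf,
        n_snps=n,
        n_iter=n_iter,
    )


def chi2_2x2(table: np.ndarray) -> tuple[float, float]:
    """Pearson chi-squared (1 df, no continuity correction) of a 2x2 table.

    chi2 = N (ad - bc)^2 / (r1 r2 c1 c2), closed form for the 2x2 case.
    """
    (a, b), (c, d) = table
    n = a + b + c + d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        return 0.0, 1.0
    chi2 = float(n * (a * d - b * c) ** 2 / denom)
    return chi2, float(stats.chi2.sf(chi2, df=1))


def snp_lmr_overlap_sets(
    snp_sets: list[SnpSet], lmrs: list[GenomicRegion]
) -> tuple[dict[str, set], dict[tuple[str, ...], int]]:
    """Per-trait sets of SNP-bearing LMRs and their intersection counts.

    LMRs are keyed by (chrom, start, end). Intersection counts are
    reported for every pair of traits and, with three or more traits,
    every triple.
    """
    per_chrom: dict[str, list[GenomicRegion]] = {}
    for r in lmrs:
        per_chrom.setdefault(r.chrom, []).append(r)
    index: dict[str, tuple[np.ndarray, np.ndarray, list]] = {}
    for chrom, regs in per_chrom.items():
        regs.sort(key=lambda r: r.start)
        index[chrom] = (
            np.array([r.start for r in regs], dtype=np.int64),
            np.array([r.end for r in regs], dtype=np.int64),
            [r.key for r in regs],
        )
    per_trait: dict[str, set] = {}
    for snp_set in snp_sets:
        hit: set = set()
        for chrom, pos in snp_set.positions:
            if chrom not in index:
                continue
            starts, ends, keys = index[chrom]
            i = int(np.searchsorted(starts, pos, side="right")) - 1
            if i >= 0 and pos < ends[i]:
                hit.add(keys[i])
        per_trait[snp_set.trait] = hit
    counts: dict[tuple[str, ...], int] = {}
    traits = [s.trait for s in snp_sets]
    for k in (2, 3):
        for combo in combinations(traits, k):
            inter = set.intersection(*(per_trait[t] for t in combo))
            counts[combo] = len(inter)
    return per_trait, counts
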
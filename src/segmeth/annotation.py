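"""Gene-level annotation of the consensus segment set.

Derives genic UMRs (gUMRs), flags genes with extended genic
demethylation, computes fully methylated regions (FMRs) as the genomic
complement of all other classes, and maps regions to nearby genes.

A gUMR is the portion of a TSS-overlapping UMR that lies inside the genic
extent and outside annotated CpG islands. Genes must span at least 1.5 kb
outside CpG islands to be eligible, and the surviving fragments must
retain at least 10 CpGs. Genic demethylation tracks the progressive loss
of gene-body methylation that starts at the TSS.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import intervals as iv
from .io import GeneModel, GenomicRegion, Methylome


@dataclass
class GUmr:
    """The genic UMR of one gene: island-free fragments treated jointly."""

    gene_id: str
    fragments: list[GenomicRegion]
    total_length: int
    n_cpg: int
    mean_meth: float | None
    gene_fraction: float


@dataclass(frozen=True)
class ExtendedDemethylationFlag:
    gene_id: str
    flagged: bool
    reason: str | None  # 'length', 'fraction', 'both', or None


def assign_gumrs(
    umrs: list[GenomicRegion],
    genes: list[GeneModel],
    cgis: list[GenomicRegion],
    methylome: Methylome,
    min_outside_cgi: int = 1500,
    min_cpgs: int = 10,
) -> list[GUmr]:
    """Assign one gUMR per eligible gene.

    For each gene whose genic extent minus CpG-island coverage is at least
    ``min_outside_cgi`` bp: take the UMRs whose interval contains the TSS
    coordinate, intersect their union with the genic extent, subtract CpG
    islands, and keep the result when at least ``min_cpgs`` CpGs remain.
    CpG counts and mean methylation come from ``methylome`` (island CpGs
    are excluded by construction, as the fragments avoid islands).
    """
    cgi_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for c in cgis:
        cgi_by_chrom.setdefault(c.chrom, []).append(c.interval)
    umr_by_chrom: dict[str, list[GenomicRegion]] = {}
    for u in umrs:
        umr_by_chrom.setdefault(u.chrom, []).append(u)

    out: list[GUmr] = []
    for gene in genes:
        lo, hi = gene.extent
        chrom_cgis = cgi_by_chrom.get(gene.chrom, [])
        outside = iv.total_length(iv.subtract([(lo, hi)], chrom_cgis))
        if outside < min_outside_cgi:
            continue
        hits = [
            u
            for u in umr_by_chrom.get(gene.chrom, [])
            if u.start <= gene.tss < u.end
        ]
        if not hits:
            continue
        if len(hits) > 1:
            warnings.warn(
                f"{gene.gene_id}: {len(hits)} UMRs overlap the TSS; union taken",
                stacklevel=2,
            )
        union = iv.merge([u.interval for u in hits])
        frags = iv.subtract(iv.intersect(union, [(lo, hi)]), chrom_cgis)
        if not frags:
            continue
        n_cpg, meth, total = _count_cpgs(methylome, gene.chrom, frags)
        if n_cpg < min_cpgs:
            continue
        frag_regions = [
            GenomicRegion(gene.chrom, s, e, "gUMR") for s, e in frags
        ]
        total_len = sum(e - s for s, e in frags)
        out.append(
            GUmr(
                gene_id=gene.gene_id,
                fragments=frag_regions,
                total_length=total_len,
                n_cpg=n_cpg,
                mean_meth=meth / total if total else None,
                gene_fraction=total_len / (hi - lo),
            )
        )
    return out


def _count_cpgs(
    methylome: Methylome, chrom: str, frags: list[tuple[int, int]]
) -> tuple[int, int, int]:
    calls = methylome.data.get(chrom)
    if calls is None:
        return 0, 0, 0
    n = meth = total = 0
    for s, e in frags:
        i0 = int(np.searchsorted(calls.pos, s, side="left"))
        i1 = int(np.searchsorted(calls.pos, e, side="left"))
        n += i1 - i0
        meth += int(calls.meth[i0:i1].sum())
        total += int(calls.total[i0:i1].sum())
    return n, meth, total


def flag_extended_demethylation(
    gumr: GUmr,
    gene: GeneModel,
    min_length: int = 5000,
    min_fraction: float = 0.25,
) -> ExtendedDemethylationFlag:
    """Flag genes with pronounced genic demethylation.

    A gene is flagged when its gUMR spans at least 5 kb and/or covers at
    least 25% of the gene (the >= 10 CpG floor is already guaranteed by
    gUMR assignment).
    """
    if gumr.gene_id != gene.gene_id:
        raise ValueError("gUMR and gene id mismatch")
    by_len = gumr.total_length >= min_length
    by_frac = gumr.gene_fraction >= min_fraction
    if by_len and by_frac:
        reason = "both"
    elif by_len:
        reason = "length"
    elif by_frac:
        reason = "fraction"
    else:
        reason = None
    return ExtendedDemethylationFlag(gumr.gene_id, by_len or by_frac, reason)


def compute_fmrs(
    chrom_sizes: dict[str, int],
    cgis: list[GenomicRegion],
    lmrs: list[GenomicRegion],
    umrs: list[GenomicRegion],
    pmrs: list[GenomicRegion],
) -> list[GenomicRegion]:
    """Fully methylated regions: the per-chromosome complement of the
    union of CpG islands, LMRs, UMRs, and PMRs."""
    by_chrom: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_sizes}
    for group in (cgis, lmrs, umrs, pmrs):
        for r in group:
            if r.chrom in by_chrom:
                by_chrom[r.chrom].append(r.interval)
    out: list[GenomicRegion] = []
    for chrom in sorted(chrom_sizes):
        size = chrom_sizes[chrom]
        clipped = [
            (max(0, s), min(size, e))
            for s, e in by_chrom[chrom]
            if s < size and e > 0
        ]
        for s, e in iv.complement(clipped, (0, size)):
            out.append(GenomicRegion(chrom, s, e, "FMR"))
    return out


def nearest_gene_within(
    regions: list[GenomicRegion],
    genes: list[GeneModel],
    max_dist: int = 10000,
) -> dict[tuple[str, int, int], str | None]:
    """Map each region to the closest gene within ``max_dist`` bp.

    Distance is measured from the region boundary to the genic extent (0
    when overlapping). Ties are broken by the smaller distance from the
    region to the TSS, then by lexicographic gene id. Regions farther than
    ``max_dist`` from every gene map to None.
    """
    genes_by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        genes_by_chrom.setdefault(g.chrom, []).append(g)

    out: dict[tuple[str, int, int], str | None] = {}
    for r in regions:
        best: tuple[int, int, str] | None = None
        for g in genes_by_chrom.get(r.chrom, []):
            d = iv.gap_distance(r.interval, g.extent)
            if d > max_dist:
                continue
            tss_d = iv.gap_distance(r.interval, (g.tss, g.tss + 1))
            cand = (d, tss_d, g.gene_id)
            if best is None or cand < best:
                best = cand
        out[r.key] = best[2] if best is not None else None
    return out
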
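"""Seeded generators for every input the pipeline consumes.

The generators produce methylomes, replicate groups, mark tracks, DE
tables and SNP sets with known ground truth, so segmentation recovery,
DMR power and type-I error, mark-rank regression and enrichment
calibration are all testable offline.

The default genome layout is a 5-Mb toy chromosome tiled by alternating
fully methylated spacers and planted special segments (PMR, UMR or LMR),
with CpG islands inside half of the UMRs. Proportions are chosen to match
the CpG-weighted class composition of somatic methylomes — roughly 45%
of the genome in large disordered PMRs, ~1% in CpG-rich UMRs, ~2% in
small CpG-poor LMRs, the rest fully methylated — because the class
mixture *per CpG* is what segmentation statistics respond to. Inter-CpG
gaps are geometric with mean ~100 bp, densified five-fold inside CpG
islands. Per-CpG methylation is Beta-distributed per class; read counts
are binomial at truncated-Poisson coverage. Replicate noise is
beta-binomial (a per-replicate Beta re-draw around the latent mean) so
the differential test faces realistic overdispersion.

All generators are bit-reproducible given (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import intervals as iv
from .io import ChromCalls, GeneModel, GenomicRegion, Methylome


@dataclass
class ClassMethylationModel:
    """Beta parameters of the latent per-CpG methylation level per class.

    Defaults: FMR Beta(17, 3) (mean 0.85), UMR Beta(2, 38) (mean 0.05),
    LMR Beta(6, 14) (mean 0.30), PMR Beta(1, 1) = Uniform(0, 1),
    CGI Beta(1, 49) (mean 0.02).
    """

    params: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "FMR": (17.0, 3.0),
            "UMR": (2.0, 38.0),
            "LMR": (6.0, 14.0),
            "PMR": (1.0, 1.0),
            "CGI": (1.0, 49.0),
        }
    )

    def __post_init__(self):
        mean = {k: a / (a + b) for k, (a, b) in self.params.items()}
        if not 0.1 < mean["LMR"] < 0.5:
            raise ValueError("LMR latent mean must lie in (0.1, 0.5)")
        if not mean["UMR"] < mean["LMR"] < mean["FMR"]:
            raise ValueError("class means must be ordered UMR < LMR < FMR")

    def mean(self, cls: str) -> float:
        a, b = self.params[cls]
        return a / (a + b)


@dataclass
class LayoutConfig:
    """Geometry of the planted genome layout."""

    total_bp: int = 5_000_000
    chrom: str = "chr1"
    spacer_bp: tuple[int, int] = (25_000, 66_000)
    pmr_bp: tuple[int, int] = (50_000, 200_000)
    umr_bp: tuple[int, int] = (3_500, 6_000)
    lmr_bp: tuple[int, int] = (800, 2_200)
    # planted special-segment counts per 5 Mb (scaled by total_bp);
    # fixed composition keeps the study conditions stable across seeds
    class_counts: dict[str, float] = field(
        default_factory=lambda: {"PMR": 17.0, "UMR": 4.0, "LMR": 36.0}
    )
    cgi_probability: float = 0.5  # fraction of UMRs carrying a CpG island
    cgi_core_fraction: float = 0.3  # CGI spans the central core of its UMR
    mean_gap_bp: float = 100.0
    cgi_densification: float = 5.0
    lmr_umr_cutoff: int = 30


@dataclass
class GenomeLayout:
    """A planted genome: CpG positions, per-CpG classes, truth segments.

    Truth segments for hypomethylated classes are labeled by their
    *realized* CpG count against the 30-CpG LMR/UMR cutoff, and all truth
    intervals span first to last planted CpG dyad (the extent a CpG-level
    caller can recover).
    """

    chrom_sizes: dict[str, int]
    cpg_pos: dict[str, np.ndarray]
    cpg_class: dict[str, np.ndarray]
    segments: list[GenomicRegion]
    cgis: list[GenomicRegion]

    @property
    def n_cpgs(self) -> int:
        return sum(len(p) for p in self.cpg_pos.values())

    def truth_of_class(self, *classes: str) -> list[GenomicRegion]:
        return [s for s in self.segments if s.region_class in classes]


def _geometric_positions(start: int, end: int, mean_gap: float, rng) -> list[int]:
    """CpG positions in [start, end) with gaps 2 + Geometric (mean ~mean_gap)."""
    p = 1.0 / max(mean_gap - 2.0, 1.0)
    out = []
    pos = start + int(rng.geometric(p))
    while pos < end - 1:
        out.append(pos)
        pos += 2 + int(rng.geometric(p))
    return out


def build_layout(config: LayoutConfig | None = None, seed: int = 0) -> GenomeLayout:
    """Draw a planted genome layout (deterministic given config and seed)."""
    cfg = config or LayoutConfig()
    rng = np.random.default_rng([11, seed])
    length_range = {"PMR": cfg.pmr_bp, "UMR": cfg.umr_bp, "LMR": cfg.lmr_bp}
    scale = cfg.total_bp / 5_000_000

    specials: list[str] = []
    for cls in sorted(cfg.class_counts):
        specials.extend([cls] * max(0, round(cfg.class_counts[cls] * scale)))
    specials = [specials[i] for i in rng.permutation(len(specials))]
    lengths = [
        int(rng.integers(length_range[c][0], length_range[c][1] + 1)) for c in specials
    ]
    special_bp = sum(lengths)
    if special_bp >= 0.9 * cfg.total_bp:
        raise ValueError("planted segments exceed 90% of the genome; enlarge total_bp")
    spacer_draws = rng.integers(
        cfg.spacer_bp[0], cfg.spacer_bp[1] + 1, size=len(specials) + 1
    ).astype(np.float64)
    spacer_lens = spacer_draws * (cfg.total_bp - special_bp) / spacer_draws.sum()
    spacer_lens = np.maximum(spacer_lens.round().astype(np.int64), 1)

    zones: list[tuple[str, int, int, tuple[int, int] | None]] = []
    pos = 0
    for i, (cls, ln) in enumerate(zip(specials, lengths)):
        sp = int(spacer_lens[i])
        zones.append(("FMR", pos, pos + sp, None))
        pos += sp
        end = pos + ln
        cgi = None
        if cls == "UMR" and rng.random() < cfg.cgi_probability:
            core = int(ln * cfg.cgi_core_fraction)
            mid = (pos + end) // 2
            cgi = (mid - core // 2, mid + core // 2)
        zones.append((cls, pos, end, cgi))
        pos = end
    zones.append(("FMR", pos, cfg.total_bp, None))
    zones = [(c, s, min(e, cfg.total_bp), g) for c, s, e, g in zones if s < cfg.total_bp and s < e]

    pos_list: list[int] = []
    cls_list: list[str] = []
    segments: list[GenomicRegion] = []
    cgis: list[GenomicRegion] = []
    for cls, zs, ze, cgi in zones:
        if cgi is None:
            pieces = [(zs, ze, cls, cfg.mean_gap_bp)]
        else:
            dense_gap = cfg.mean_gap_bp / cfg.cgi_densification
            pieces = [
                (zs, cgi[0], cls, cfg.mean_gap_bp),
                (cgi[0], cgi[1], "CGI", dense_gap),
                (cgi[1], ze, cls, cfg.mean_gap_bp),
            ]
        zone_positions: list[int] = []
        for ps, pe, pcls, gap in pieces:
            pp = _geometric_positions(ps, pe, gap, rng)
            zone_positions.extend(pp)
            pos_list.extend(pp)
            cls_list.extend([pcls] * len(pp))
        if not zone_positions:
            continue
        n = len(zone_positions)
        lo_pos, hi_pos = zone_positions[0], zone_positions[-1] + 2
        if cls in ("UMR", "LMR"):
            if n < 3:
                continue  # too sparse to ever be a planted hypomethylated region
            true_cls = "UMR" if n >= cfg.lmr_umr_cutoff else "LMR"
        else:
            true_cls = cls
        segments.append(GenomicRegion(cfg.chrom, lo_pos, hi_pos, true_cls, n_cpg=n))
        if cgi is not None:
            cgis.append(GenomicRegion(cfg.chrom, cgi[0], cgi[1], "CGI"))

    return GenomeLayout(
        chrom_sizes={cfg.chrom: cfg.total_bp},
        cpg_pos={cfg.chrom: np.array(pos_list, dtype=np.int64)},
        cpg_class={cfg.chrom: np.array(cls_list)},
        segments=segments,
        cgis=cgis,
    )


def _truncated_poisson(rng, mean: float, n: int) -> np.ndarray:
    cov = rng.poisson(mean, size=n)
    while True:
        zero = cov == 0
        if not zero.any():
            return cov
        cov[zero] = rng.poisson(mean, size=int(zero.sum()))


def _latent_levels(layout: GenomeLayout, model: ClassMethylationModel, rng) -> dict:
    latent = {}
    for chrom, classes in layout.cpg_class.items():
        m = np.empty(len(classes), dtype=np.float64)
        for cls, (a, b) in model.params.items():
            mask = classes == cls
            if mask.any():
                m[mask] = rng.beta(a, b, size=int(mask.sum()))
        latent[chrom] = m
    return latent


def simulate_methylome(
    layout: GenomeLayout,
    model: ClassMethylationModel | None = None,
    mean_coverage: float = 30.0,
    seed: int = 0,
    sample_id: str = "sim",
) -> tuple[Methylome, list[GenomicRegion]]:
    """Binomial bisulfite counts at truncated-Poisson coverage.

    Per CpG: latent level from the class Beta, coverage ~ Poisson
    truncated to >= 1, methylated reads ~ Binomial(coverage, latent).
    Returns the methylome and the layout's truth segments.
    """
    model = model or ClassMethylationModel()
    rng = np.random.default_rng([12, seed])
    latent = _latent_levels(layout, model, rng)
    data = {}
    for chrom, pos in layout.cpg_pos.items():
        cov = _truncated_poisson(rng, mean_coverage, len(pos))
        meth = rng.binomial(cov, latent[chrom])
        data[chrom] = ChromCalls(pos=pos.copy(), meth=meth, total=cov)
    return (
        Methylome(sample_id=sample_id, chrom_sizes=dict(layout.chrom_sizes), data=data),
        list(layout.segments),
    )


def simulate_replicate_groups(
    layout: GenomeLayout,
    model: ClassMethylationModel | None = None,
    dmr_spec: list[tuple[GenomicRegion, float]] | None = None,
    n_per_group: int = 3,
    mean_coverage: float = 20.0,
    seed: int = 0,
    concentration: float = 50.0,
) -> tuple[list[Methylome], list[Methylome], list[tuple[GenomicRegion, float]]]:
    """Two replicate groups with planted methylation differences.

    Group B's latent methylation is shifted by delta (clipped to [0, 1])
    inside the regions of ``dmr_spec``. Each replicate re-draws its
    per-CpG level from a Beta centered on the group latent with the given
    concentration (beta-binomial overdispersion), then binomial counts at
    truncated-Poisson coverage.
    """
    model = model or ClassMethylationModel()
    dmr_spec = dmr_spec or []
    rng = np.random.default_rng([13, seed])
    base = _latent_levels(layout, model, rng)
    shifted = {c: m.copy() for c, m in base.items()}
    for region, delta in dmr_spec:
        pos = layout.cpg_pos.get(region.chrom)
        if pos is None:
            continue
        i0 = int(np.searchsorted(pos, region.start, side="left"))
        i1 = int(np.searchsorted(pos, region.end, side="left"))
        shifted[region.chrom][i0:i1] = np.clip(
            shifted[region.chrom][i0:i1] + delta, 0.0, 1.0
        )

    def _replicate(latent: dict, sid: str) -> Methylome:
        data = {}
        for chrom, pos in layout.cpg_pos.items():
            lat = latent[chrom]
            eps = 1e-4
            m_rep = np.where(
                (lat < eps) | (lat > 1 - eps),
                np.clip(lat, 0.0, 1.0),
                rng.beta(
                    np.clip(lat, eps, 1 - eps) * concentration,
                    (1 - np.clip(lat, eps, 1 - eps)) * concentration,
                ),
            )
            cov = _truncated_poisson(rng, mean_coverage, len(pos))
            meth = rng.binomial(cov, m_rep)
            data[chrom] = ChromCalls(pos=pos.copy(), meth=meth, total=cov)
        return Methylome(sample_id=sid, chrom_sizes=dict(layout.chrom_sizes), data=data)

    group_a = [_replicate(base, f"a{i + 1}") for i in range(n_per_group)]
    group_b = [_replicate(shifted, f"b{i + 1}") for i in range(n_per_group)]
    truth = [(r, d) for r, d in dmr_spec if d != 0.0]
    return group_a, group_b, truth


def tile_regions(
    layout: GenomeLayout,
    cpgs_per_region: int = 10,
    within_class: str | None = "FMR",
    max_regions: int | None = None,
) -> list[GenomicRegion]:
    """Chop planted segments into consecutive tiles of k CpGs each.

    Serves the DMR null and power suites: tiles are non-overlapping
    regions of exactly ``cpgs_per_region`` CpGs lying inside truth
    segments of ``within_class`` (or all segments when None).
    """
    out: list[GenomicRegion] = []
    for seg in layout.segments:
        if within_class is not None and seg.region_class != within_class:
            continue
        pos = layout.cpg_pos[seg.chrom]
        i0 = int(np.searchsorted(pos, seg.start, side="left"))
        i1 = int(np.searchsorted(pos, seg.end, side="left"))
        for j in range(i0, i1 - cpgs_per_region + 1, cpgs_per_region):
            out.append(
                GenomicRegion(
                    seg.chrom,
                    int(pos[j]),
                    int(pos[j + cpgs_per_region - 1]) + 2,
                    "raw",
                    n_cpg=cpgs_per_region,
                )
            )
            if max_regions is not None and len(out) >= max_regions:
                return out
    return out


# ---------------------------------------------------------------------------
# genes, expression, mark tracks
# ---------------------------------------------------------------------------


def simulate_genes(
    chrom_sizes: dict[str, int],
    n_genes: int = 100,
    seed: int = 0,
    gene_bp: tuple[int, int] = (5_000, 40_000),
    min_gap: int = 5_000,
) -> list[GeneModel]:
    """Non-overlapping gene models with alternating strands."""
    rng = np.random.default_rng([14, seed])
    genes: list[GeneModel] = []
    chroms = sorted(chrom_sizes)
    per_chrom = int(np.ceil(n_genes / len(chroms)))
    k = 0
    for chrom in chroms:
        cursor = min_gap
        for _ in range(per_chrom):
            if k >= n_genes:
                break
            ln = int(rng.integers(gene_bp[0], gene_bp[1] + 1))
            if cursor + ln + min_gap > chrom_sizes[chrom]:
                break
            strand = "+" if k % 2 == 0 else "-"
            lo, hi = cursor, cursor + ln
            tss, tes = (lo, hi) if strand == "+" else (hi, lo)
            genes.append(GeneModel(f"gene{k:04d}", chrom, strand, tss, tes))
            cursor = hi + min_gap + int(rng.integers(0, min_gap))
            k += 1
    return genes


def simulate_de_table(
    genes: list[GeneModel] | list[str],
    seed: int = 0,
    sig_fraction: float = 0.8,
    log2fc_scale: float = 1.5,
) -> pd.DataFrame:
    """Differential-expression table: gene, log2fc, q_value, FPKMs.

    log2 fold-changes are Gaussian; a ``sig_fraction`` of genes gets
    q < 0.05. FPKM columns are generated >= 3 so no gene would fall under
    the expression floor applied upstream of a real DE table.
    """
    rng = np.random.default_rng([15, seed])
    ids = [g.gene_id if isinstance(g, GeneModel) else g for g in genes]
    n = len(ids)
    log2fc = rng.normal(0.0, log2fc_scale, size=n)
    sig = rng.random(n) < sig_fraction
    q = np.where(sig, rng.uniform(1e-6, 0.049, size=n), rng.uniform(0.05, 1.0, size=n))
    fpkm_a = 3.0 + rng.gamma(2.0, 10.0, size=n)
    fpkm_b = np.maximum(fpkm_a * 2.0**log2fc, 3.0)
    return pd.DataFrame(
        {
            "gene": ids,
            "log2fc": log2fc,
            "q_value": q,
            "fpkm_a": fpkm_a,
            "fpkm_b": fpkm_b,
        }
    )


def simulate_mark_ratios(
    de: pd.DataFrame,
    coupling: float,
    seed: int = 0,
    marks: tuple[str, ...] = ("H3K27ac", "H3K36me3"),
) -> pd.DataFrame:
    """Per-gene per-mark log2 condition ratios coupled to expression change.

    ratio = coupling * standardized(log2fc) + sqrt(1 - coupling^2) * noise,
    with independent unit-Gaussian noise per mark.
    """
    if not 0.0 <= coupling <= 1.0:
        raise ValueError("coupling must lie in [0, 1]")
    rng = np.random.default_rng([16, seed])
    z = (de["log2fc"] - de["log2fc"].mean()) / de["log2fc"].std(ddof=0)
    out = {}
    for mark in marks:
        noise = rng.normal(0.0, 1.0, size=len(de))
        out[mark] = coupling * z.to_numpy() + np.sqrt(1.0 - coupling**2) * noise
    return pd.DataFrame(out, index=pd.Index(de["gene"], name="gene"))


def simulate_mark_tracks(
    genes: list[GeneModel],
    de: pd.DataFrame,
    coupling: float,
    chrom_sizes: dict[str, int],
    seed: int = 0,
    marks: tuple[str, ...] = ("H3K27ac", "H3K36me3"),
    base_coverage: float = 10.0,
    background: float = 0.5,
    promoter_flank: int = 1000,
):
    """Render condition-pair bedGraph tracks whose target signal encodes
    the planted mark ratios.

    For every mark, the non-failing (denominator) track carries flat
    ``base_coverage`` over each gene's target (promoter or genic region
    by mark) and ``background`` elsewhere; the failing track multiplies
    the target coverage by 2**ratio. Returns ({mark: (track_f, track_nf)},
    de, ratios).
    """
    from .marks import PROMOTER_MARKS, MarkTrack

    ratios = simulate_mark_ratios(de, coupling, seed, marks)
    gene_map = {g.gene_id: g for g in genes}
    tracks = {}
    for mark in marks:
        per_chrom_f: dict[str, list[tuple[int, int, float]]] = {}
        per_chrom_nf: dict[str, list[tuple[int, int, float]]] = {}
        for gid in ratios.index:
            g = gene_map.get(gid)
            if g is None:
                continue
            if mark in PROMOTER_MARKS:
                lo, hi = g.tss - promoter_flank, g.tss + promoter_flank
            else:
                lo, hi = g.extent
            lo = max(lo, 0)
            hi = min(hi, chrom_sizes[g.chrom])
            val_f = base_coverage * 2.0 ** float(ratios.loc[gid, mark])
            per_chrom_f.setdefault(g.chrom, []).append((lo, hi, val_f))
            per_chrom_nf.setdefault(g.chrom, []).append((lo, hi, base_coverage))
        data_f = {c: _fill_background(rows, chrom_sizes[c], background) for c, rows in per_chrom_f.items()}
        data_nf = {c: _fill_background(rows, chrom_sizes[c], background) for c, rows in per_chrom_nf.items()}
        tracks[mark] = (
            MarkTrack(sample_id=f"F:{mark}", mark=mark, data=data_f),
            MarkTrack(sample_id=f"NF:{mark}", mark=mark, data=data_nf),
        )
    return tracks, de, ratios


def _fill_background(rows: list[tuple[int, int, float]], size: int, background: float):
    rows = sorted(rows)
    starts, ends, vals = [], [], []
    cursor = 0
    for s, e, v in rows:
        s = max(s, cursor)
        if s >= e:
            continue
        if s > cursor:
            starts.append(cursor)
            ends.append(s)
            vals.append(background)
        starts.append(s)
        ends.append(e)
        vals.append(v)
        cursor = e
    if cursor < size:
        starts.append(cursor)
        ends.append(size)
        vals.append(background)
    return (
        np.array(starts, dtype=np.int64),
        np.array(ends, dtype=np.int64),
        np.array(vals, dtype=np.float64),
    )


# ---------------------------------------------------------------------------
# SNP sets
# ---------------------------------------------------------------------------


def simulate_snp_sets(
    lmrs: list[GenomicRegion],
    chrom_sizes: dict[str, int],
    fold: float = 1.0,
    n_snps: int = 500,
    seed: int = 0,
    trait: str = "trait",
):
    """SNP positions with a planted in-LMR fold enrichment.

    Each SNP lands inside an LMR with probability p_in = fold * (LMR
    genome fraction), uniform over LMR bases; otherwise uniform over the
    non-LMR genome. The expected enrichment over uniform placement then
    equals the requested fold exactly. Requesting a fold above
    1 / LMR-fraction is an error.
    """
    from .enrichment import SnpSet, _RegionIndex

    rng = np.random.default_rng([17, seed])
    genome_bp = sum(chrom_sizes.values())
    per_chrom: dict[str, list[tuple[int, int]]] = {}
    for r in lmrs:
        per_chrom.setdefault(r.chrom, []).append(r.interval)
    merged = {c: iv.merge(v) for c, v in per_chrom.items()}
    lmr_bp = sum(iv.total_length(v) for v in merged.values())
    fraction = lmr_bp / genome_bp
    p_in = fold * fraction
    if p_in > 1.0:
        raise ValueError(
            f"fold {fold} exceeds 1/LMR-fraction = {1.0 / fraction:.1f}"
        )
    flat = [
        (c, s, e) for c, ivs in sorted(merged.items()) for s, e in ivs
    ]
    lengths = np.array([e - s for _, s, e in flat], dtype=np.float64)
    lmr_w = lengths / lengths.sum() if len(lengths) else None
    idx = _RegionIndex([GenomicRegion(c, s, e, "LMR") for c, s, e in flat])
    chroms = sorted(chrom_sizes)
    chrom_w = np.array([chrom_sizes[c] for c in chroms], dtype=np.float64)
    chrom_w = chrom_w / chrom_w.sum()

    positions: set[tuple[str, int]] = set()
    while len(positions) < n_snps:
        if rng.random() < p_in and lmr_w is not None:
            j = int(rng.choice(len(flat), p=lmr_w))
            c, s, e = flat[j]
            positions.add((c, int(rng.integers(s, e))))
        else:
            while True:
                c = chroms[int(rng.choice(len(chroms), p=chrom_w))]
                pos = int(rng.integers(0, chrom_sizes[c]))
                if not idx.contains(c, np.array([pos]))[0]:
                    positions.add((c, pos))
                    break
    snps = SnpSet(trait=trait, positions=sorted(positions))
    return snps, p_in


# ---------------------------------------------------------------------------
# evaluation helpers
# ---------------------------------------------------------------------------


def segmentation_scores(
    called: list[GenomicRegion],
    truth: list[GenomicRegion],
    classes: tuple[str, ...] = ("LMR", "UMR"),
    min_jaccard: float = 0.5,
) -> dict:
    """Per-class precision/recall/F1 and mean best Jaccard of recovery.

    A truth region is recovered when some called region of the same class
    overlaps it with Jaccard >= ``min_jaccard``; precision is the mirror
    statistic on called regions. ``mean_jaccard`` averages, over all
    truth regions of the listed classes, the best Jaccard against any
    called region of any listed class.
    """
    out: dict = {}
    jaccs: list[float] = []
    called_all = [c for c in called if c.region_class in classes]
    for t in [t for t in truth if t.region_class in classes]:
        best = max(
            (iv.jaccard(t.interval, c.interval) for c in called_all if c.chrom == t.chrom),
            default=0.0,
        )
        jaccs.append(best)
    out["mean_jaccard"] = float(np.mean(jaccs)) if jaccs else 0.0
    for cls in classes:
        t_cls = [t for t in truth if t.region_class == cls]
        c_cls = [c for c in called if c.region_class == cls]
        tp_r = sum(
            1
            for t in t_cls
            if any(
                c.chrom == t.chrom and iv.jaccard(t.interval, c.interval) >= min_jaccard
                for c in c_cls
            )
        )
        tp_p = sum(
            1
            for c in c_cls
            if any(
                c.chrom == t.chrom and iv.jaccard(t.interval, c.interval) >= min_jaccard
                for t in t_cls
            )
        )
        recall = tp_r / len(t_cls) if t_cls else float("nan")
        precision = tp_p / len(c_cls) if c_cls else float("nan")
        f1 = (
            2 * precision * recall / (precision + recall)
            if precision + recall > 0
            else 0.0
        )
        out[cls] = {"precision": precision, "recall": recall, "f1": f1}
    return out
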
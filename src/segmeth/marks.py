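"""Chromatin-mark coverage: normalization, quantification, rank regression.

Coverage tracks (bedGraph) from different samples are made comparable by
scaling each track to the geometric mean of the genome-wide read counts.
Mark signal is then quantified over promoters (TSS +/- 1 kb; H3K27ac,
H3K9ac, H3K4me3), genic regions (TSS to TES; H3K36me3, H3K9me3, H3K27me3,
H3K4me1) or explicit regions (LMR windows, 5hmC). Condition ratios
(failing / non-failing) of the individual marks are averaged on the log2
scale, and differentially expressed genes, ranked by expression change
(log2 fold-change), are regressed against the mark ratios to ask how much
of the expression rank the marks explain.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import GeneModel, GenomicRegion, ParseError, _open_text

PROMOTER_MARKS = {"H3K27ac", "H3K9ac", "H3K4me3"}
GENIC_MARKS = {"H3K36me3", "H3K9me3", "H3K27me3", "H3K4me1"}
KNOWN_MARKS = PROMOTER_MARKS | GENIC_MARKS | {"5hmC", "input"}


@dataclass
class MarkTrack:
    """Step-wise coverage over the genome for one sample and one mark.

    ``data`` maps chromosome -> (starts, ends, values) arrays of
    non-overlapping sorted intervals. ``scale_factor`` is 1.0 until
    normalization sets it.
    """

    sample_id: str
    mark: str
    data: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = field(
        default_factory=dict
    )
    scale_factor: float = 1.0

    def __post_init__(self):
        for chrom, (s, e, v) in self.data.items():
            s = np.asarray(s, dtype=np.int64)
            e = np.asarray(e, dtype=np.int64)
            v = np.asarray(v, dtype=np.float64)
            if np.any(e <= s):
                raise ValueError(f"{chrom}: empty or inverted bedGraph interval")
            if len(s) > 1 and np.any(s[1:] < e[:-1]):
                raise ValueError(f"{chrom}: overlapping bedGraph intervals")
            if np.any(v < 0):
                raise ValueError(f"{chrom}: negative coverage")
            self.data[chrom] = (s, e, v)

    @property
    def genome_total(self) -> float:
        """Sum of coverage x span over the whole track (unscaled)."""
        return float(
            sum(((e - s) * v).sum() for s, e, v in self.data.values())
        )

    @property
    def span_bp(self) -> int:
        return int(sum((e - s).sum() for s, e, _ in self.data.values()))


def read_bedgraph(path, sample_id: str, mark: str) -> MarkTrack:
    """Read a 4-column bedGraph into a MarkTrack (gzip-transparent)."""
    per_chrom: dict[str, list[tuple[int, int, float]]] = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ParseError(f"{path}:{lineno}: expected 4 bedGraph columns")
            try:
                s, e, v = int(parts[1]), int(parts[2]), float(parts[3])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
            per_chrom.setdefault(parts[0], []).append((s, e, v))
    data = {}
    for chrom, rows in per_chrom.items():
        rows.sort()
        data[chrom] = (
            np.array([r[0] for r in rows], dtype=np.int64),
            np.array([r[1] for r in rows], dtype=np.int64),
            np.array([r[2] for r in rows], dtype=np.float64),
        )
    return MarkTrack(sample_id=sample_id, mark=mark, data=data)


def write_bedgraph(track: MarkTrack, path) -> None:
    with open(path, "wt") as fh:
        for chrom in sorted(track.data):
            s, e, v = track.data[chrom]
            for si, ei, vi in zip(s, e, v):
                fh.write(f"{chrom}\t{si}\t{ei}\t{vi:g}\n")


def normalize_to_geometric_mean(tracks: list[MarkTrack]) -> list[MarkTrack]:
    """Set each track's scale factor to G / genome_total, with G the
    geometric mean of the genome-wide totals.

    Scaled quantities are coverage x scale_factor; the product of scale
    factors times totals is G for every track, so the log-scaled totals
    are conserved.
    """
    if len(tracks) < 2:
        raise ValueError("need at least two tracks to normalize")
    totals = np.array([t.genome_total for t in tracks], dtype=np.float64)
    if np.any(totals <= 0):
        bad = tracks[int(np.argmin(totals))].sample_id
        raise ValueError(f"track {bad!r} has zero genome-wide signal")
    g = float(np.exp(np.mean(np.log(totals))))
    for t, tot in zip(tracks, totals):
        t.scale_factor = g / float(tot)
    return tracks


def _targets_for(
    track: MarkTrack,
    gene_set: list[GeneModel] | None,
    mode: str,
    regions: list[GenomicRegion] | None,
    promoter_flank: int,
) -> list[tuple[str, str, int, int]]:
    if mode == "regions" or regions is not None:
        if regions is None:
            raise ValueError("regions mode requires explicit regions")
        return [(f"{r.chrom}:{r.start}-{r.end}", r.chrom, r.start, r.end) for r in regions]
    if mode == "auto":
        if track.mark in PROMOTER_MARKS:
            mode = "promoter"
        elif track.mark in GENIC_MARKS:
            mode = "genic"
        else:
            raise ValueError(
                f"no automatic target mode for mark {track.mark!r}; "
                "pass mode='promoter'/'genic' or explicit regions"
            )
    if gene_set is None:
        raise ValueError(f"{mode} mode requires gene models")
    out = []
    for g in gene_set:
        if mode == "promoter":
            lo, hi = g.tss - promoter_flank, g.tss + promoter_flank
        elif mode == "genic":
            lo, hi = g.extent
        else:
            raise ValueError(f"unknown mode {mode!r}")
        out.append((g.gene_id, g.chrom, lo, hi))
    return out


def quantify_region_signal(
    track: MarkTrack,
    gene_set: list[GeneModel] | None = None,
    mode: str = "auto",
    regions: list[GenomicRegion] | None = None,
    promoter_flank: int = 1000,
    chrom_sizes: dict[str, int] | None = None,
) -> pd.Series:
    """Scaled mark signal per target (gene promoter, genic region, or
    explicit region).

    Signal is the integral of coverage over the target times the track's
    scale factor. Targets extending past chromosome bounds are clipped
    with a warning when ``chrom_sizes`` is given; negative starts are
    always clipped.
    """
    targets = _targets_for(track, gene_set, mode, regions, promoter_flank)
    out = {}
    n_clipped = 0
    for name, chrom, lo, hi in targets:
        if lo < 0 or (chrom_sizes and hi > chrom_sizes.get(chrom, hi)):
            n_clipped += 1
            lo = max(lo, 0)
            if chrom_sizes and chrom in chrom_sizes:
                hi = min(hi, chrom_sizes[chrom])
        out[name] = _interval_signal(track, chrom, lo, hi)
    if n_clipped:
        warnings.warn(f"{n_clipped} targets clipped to chromosome bounds", stacklevel=2)
    return pd.Series(out, name=f"{track.sample_id}:{track.mark}")


def _interval_signal(track: MarkTrack, chrom: str, lo: int, hi: int) -> float:
    if chrom not in track.data or hi <= lo:
        return 0.0
    s, e, v = track.data[chrom]
    i0 = int(np.searchsorted(e, lo, side="right"))
    i1 = int(np.searchsorted(s, hi, side="left"))
    if i0 >= i1:
        return 0.0
    ov = np.minimum(e[i0:i1], hi) - np.maximum(s[i0:i1], lo)
    return float((ov * v[i0:i1]).sum() * track.scale_factor)


def mark_log2_ratio(
    track_num: MarkTrack,
    track_den: MarkTrack,
    gene_set: list[GeneModel] | None = None,
    mode: str = "auto",
    regions: list[GenomicRegion] | None = None,
    pseudocount_fraction: float = 0.01,
) -> pd.Series:
    """Per-target log2 condition ratio of two normalized tracks.

    A pseudocount equal to ``pseudocount_fraction`` of the mean scaled
    per-kb signal (averaged over the two tracks), scaled by target length,
    bounds ratios at empty regions.
    """
    sig_n = quantify_region_signal(track_num, gene_set, mode, regions)
    sig_d = quantify_region_signal(track_den, gene_set, mode, regions)
    per_kb = np.mean(
        [
            t.genome_total * t.scale_factor / max(t.span_bp, 1) * 1000.0
            for t in (track_num, track_den)
        ]
    )
    lengths = _target_lengths(track_num, gene_set, mode, regions)
    pc = pseudocount_fraction * per_kb * lengths / 1000.0
    return np.log2((sig_n + pc) / (sig_d + pc))


def _target_lengths(track, gene_set, mode, regions) -> pd.Series:
    targets = _targets_for(track, gene_set, mode, regions, 1000)
    return pd.Series({name: hi - lo for name, _, lo, hi in targets}, dtype=float)


def combine_mark_ratios(ratios: pd.DataFrame) -> pd.Series:
    """Average per-gene log2 ratios of several marks on the log scale
    (arithmetic mean of the log2 ratios)."""
    return ratios.mean(axis=1)


@dataclass
class RankRegressionResult:
    per_mark_r2: dict[str, float]
    combined_r2: float
    combined_marks: tuple[str, ...]
    ranked_genes: list[str]


def _poly_r2(y: np.ndarray, X: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    sstot = float(((y - y.mean()) ** 2).sum())
    if sstot == 0:
        return 0.0
    return 1.0 - float((resid**2).sum()) / sstot


def expression_rank_regression(
    de: pd.DataFrame,
    mark_ratios: pd.DataFrame,
    combine: tuple[str, str] = ("H3K27ac", "H3K36me3"),
    q_threshold: float = 0.05,
) -> RankRegressionResult:
    """Regress mark ratios against the expression-change rank.

    ``de`` needs columns ``gene``/index, ``log2fc`` and ``q_value``;
    genes with q < ``q_threshold`` are ranked by log2 fold-change
    (rank 1..N). Per mark, a cubic polynomial of the rank is fit to the
    mark's log2 ratio and R^2 = 1 - SSres/SStot reported (the fraction of
    the mark's variation the rank trend captures). The combined model
    fits the rank on the two named marks' ratios with quadratic and
    interaction terms, reporting R^2 on the rank itself — the fraction of
    the expression rank the marks explain.
    """
    de = de.set_index("gene") if "gene" in de.columns else de
    diff = de[de["q_value"] < q_threshold]
    genes = diff.index.intersection(mark_ratios.index)
    if len(genes) < 10:
        raise ValueError(f"need >= 10 differential genes, got {len(genes)}")
    diff = diff.loc[genes].sort_values("log2fc")
    rank = np.arange(1, len(diff) + 1, dtype=np.float64)
    ratios = mark_ratios.loc[diff.index]

    per_mark: dict[str, float] = {}
    Xr = np.column_stack([np.ones_like(rank), rank, rank**2, rank**3])
    for mark in ratios.columns:
        y = ratios[mark].to_numpy(dtype=np.float64)
        if np.ptp(y) == 0:
            warnings.warn(f"{mark}: constant ratio, r2 set to 0", stacklevel=2)
            per_mark[mark] = 0.0
        else:
            per_mark[mark] = _poly_r2(y, Xr)

    m1, m2 = combine
    missing = [m for m in combine if m not in ratios.columns]
    if missing:
        raise ValueError(f"combined model marks absent from ratios: {missing}")
    a = ratios[m1].to_numpy(dtype=np.float64)
    b = ratios[m2].to_numpy(dtype=np.float64)
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        warnings.warn("constant predictor in combined model, r2 set to 0", stacklevel=2)
        combined = 0.0
    else:
        Xc = np.column_stack([np.ones_like(a), a, b, a**2, b**2, a * b])
        combined = _poly_r2(rank, Xc)
    return RankRegressionResult(
        per_mark_r2=per_mark,
        combined_r2=combined,
        combined_marks=combine,
        ranked_genes=list(diff.index),
    )
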
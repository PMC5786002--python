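"""Methylome segmentation into PMRs and hypomethylated (LMR/UMR) regions.

The segmentation follows the classic two-stage scheme for WGBS methylomes:

1. **PMR detection.** A per-CpG *disorder score* measures how strongly the
   local methylation distribution deviates from the polarized (near-0 /
   near-1) pattern of ordered chromatin: the score of a CpG is the fraction
   of CpGs in a centered 101-CpG window whose observed level falls strictly
   inside an intermediate band. A two-state Gaussian HMM fit by EM on that
   score, decoded by posterior probability, yields partially methylated
   regions (PMRs); neighboring PMR runs closer than one window are fused.

2. **Hypomethylated-region detection.** After masking PMRs (with a
   half-window safety margin, since one window is the resolution limit of
   the score) the remaining methylome is smoothed with a 3-CpG running
   window, and maximal runs of >= 3 CpGs with smoothed level <= 50% are
   reported. Regions with >= 30 CpGs are UMRs (CpG-rich unmethylated
   promoters/gene bodies), smaller ones are LMRs (CpG-poor distal
   regulatory elements).

Detection parameters are calibrated by comparing region counts between the
original methylome and one whose (level, counts) pairs were permuted across
CpG positions: the count ratio estimates the false discovery rate, which
must stay below 5%.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .io import ChromCalls, GenomicRegion, Methylome


@dataclass
class SegmentationParams:
    """Tunable knobs of the segmentation, with the standard defaults.

    window_cpgs
        Sliding-window width (in CpGs) of the disorder score; odd.
    window_step
        Step of the sliding window in CpGs (1 = every CpG scored).
    smooth_cpgs
        Running-window width for methylation smoothing after PMR masking.
    min_cpgs / max_meth
        Hypomethylated-region detection floor: at least ``min_cpgs``
        consecutive CpGs with smoothed level <= ``max_meth``.
    lmr_umr_cutoff
        CpG-count cutoff separating LMR (< cutoff) from UMR (>= cutoff).
    fdr_threshold
        Maximum tolerated shuffle-estimated FDR for parameter calibration.
    disorder_bounds
        Open interval of observed levels counted as "disordered" by the
        disorder score.
    mask_margin_cpgs
        Extra CpGs masked on each side of a decoded PMR before smoothing;
        defaults to half a window, the resolution limit of the score.
    """

    window_cpgs: int = 101
    window_step: int = 1
    smooth_cpgs: int = 3
    min_cpgs: int = 3
    max_meth: float = 0.50
    lmr_umr_cutoff: int = 30
    fdr_threshold: float = 0.05
    disorder_bounds: tuple[float, float] = (0.3, 0.7)
    mask_margin_cpgs: int | None = None
    min_state_separation: float = 0.1
    min_pmr_cpgs: int | None = None  # None = one full window (resolution limit)

    def __post_init__(self):
        if self.window_cpgs % 2 != 1:
            raise ValueError("window_cpgs must be odd")
        if self.min_cpgs < 1:
            raise ValueError("min_cpgs must be >= 1")
        if not 0.0 < self.max_meth < 1.0:
            raise ValueError("max_meth must lie in (0, 1)")
        if self.lmr_umr_cutoff <= self.min_cpgs:
            raise ValueError("lmr_umr_cutoff must exceed min_cpgs")
        lo, hi = self.disorder_bounds
        if not 0.0 <= lo < hi <= 1.0:
            raise ValueError("disorder_bounds must satisfy 0 <= lo < hi <= 1")

    @property
    def margin(self) -> int:
        if self.mask_margin_cpgs is None:
            return self.window_cpgs // 2
        return self.mask_margin_cpgs


@dataclass
class DisorderTrack:
    """Per-CpG disorder scores, one array per scored chromosome.

    Chromosomes with fewer CpGs than the window are absent (skipped with a
    warning at construction time). Edge CpGs, whose centered window would
    be truncated, carry the nearest full-window score.
    """

    scores: dict[str, np.ndarray] = field(default_factory=dict)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.scores

    def __getitem__(self, chrom: str) -> np.ndarray:
        return self.scores[chrom]


@dataclass
class SmoothedChrom:
    """PMR-masked, smoothed CpG calls on one chromosome.

    ``gap_before[i]`` is True when one or more masked CpGs (a PMR) sit
    between retained CpG i-1 and i; smoothing windows and hypomethylated
    runs never cross such a gap.
    """

    pos: np.ndarray
    smoothed: np.ndarray
    meth: np.ndarray
    total: np.ndarray
    gap_before: np.ndarray

    def __len__(self) -> int:
        return len(self.pos)


@dataclass
class SmoothedMethylome:
    sample_id: str
    chrom_sizes: dict[str, int]
    data: dict[str, SmoothedChrom] = field(default_factory=dict)

    @property
    def chroms(self) -> list[str]:
        return sorted(self.data)


@dataclass
class FdrCalibration:
    """Grid search of detection parameters against a randomized methylome.

    ``fdr[i] = counts_randomized[i] / counts_original[i]`` (1.0 when the
    original count is zero). ``chosen`` is the selected (min_cpgs,
    max_meth) pair.
    """

    grid: list[tuple[int, float]]
    counts_original: list[int]
    counts_randomized: list[float]
    fdr: list[float]
    chosen: tuple[int, float]
    fdr_threshold: float

    def as_rows(self) -> list[dict]:
        return [
            {
                "min_cpgs": mc,
                "max_meth": mm,
                "n_original": no,
                "n_randomized": nr,
                "fdr": f,
                "chosen": (mc, mm) == self.chosen,
            }
            for (mc, mm), no, nr, f in zip(
                self.grid, self.counts_original, self.counts_randomized, self.fdr
            )
        ]


class CalibrationError(RuntimeError):
    """No grid point achieved the requested FDR."""


# ---------------------------------------------------------------------------
# replicate pooling
# ---------------------------------------------------------------------------


def pool_replicates(methylomes: list[Methylome], sample_id: str = "pooled") -> Methylome:
    """Sum read counts per CpG across replicates to raise coverage."""
    if not methylomes:
        raise ValueError("no methylomes to pool")
    chrom_sizes: dict[str, int] = {}
    for m in methylomes:
        chrom_sizes.update(m.chrom_sizes)
    data: dict[str, ChromCalls] = {}
    chroms = sorted({c for m in methylomes for c in m.data})
    for chrom in chroms:
        acc: dict[int, tuple[int, int]] = {}
        for m in methylomes:
            if chrom not in m.data:
                continue
            c = m.data[chrom]
            for p, me, t in zip(c.pos, c.meth, c.total):
                old = acc.get(int(p), (0, 0))
                acc[int(p)] = (old[0] + int(me), old[1] + int(t))
        pos = np.array(sorted(acc), dtype=np.int64)
        data[chrom] = ChromCalls(
            pos=pos,
            meth=np.array([acc[p][0] for p in pos], dtype=np.int64),
            total=np.array([acc[p][1] for p in pos], dtype=np.int64),
        )
    return Methylome(sample_id=sample_id, chrom_sizes=chrom_sizes, data=data)


# ---------------------------------------------------------------------------
# disorder score
# ---------------------------------------------------------------------------


def disorder_score_track(
    methylome: Methylome, params: SegmentationParams | None = None
) -> DisorderTrack:
    """Score every CpG by the local fraction of intermediate-level CpGs.

    The score of CpG i is the fraction of CpGs in the centered
    ``window_cpgs`` window whose observed level lies strictly inside
    ``params.disorder_bounds``. Fully polarized windows (all levels at 0
    or 1) score 0; fully intermediate windows score 1.
    """
    params = params or SegmentationParams()
    w = params.window_cpgs
    half = w // 2
    lo, hi = params.disorder_bounds
    track = DisorderTrack()
    for chrom in methylome.chroms:
        calls = methylome.data[chrom]
        n = len(calls)
        if n < w:
            warnings.warn(
                f"{chrom}: {n} CpGs < window of {w}, skipped from PMR scoring",
                stacklevel=2,
            )
            continue
        level = calls.level
        inside = ((level > lo) & (level < hi)).astype(np.float64)
        csum = np.concatenate([[0.0], np.cumsum(inside)])
        full = (csum[w:] - csum[:-w]) / w  # score at CpGs half .. n-half-1
        scores = np.empty(n, dtype=np.float64)
        scores[half : n - half] = full
        scores[:half] = full[0]
        scores[n - half :] = full[-1]
        track.scores[chrom] = scores
    return track


# ---------------------------------------------------------------------------
# PMR detection (two-state HMM on the disorder score)
# ---------------------------------------------------------------------------


def _fit_two_state_hmm(obs_per_chrom: list[np.ndarray], params: SegmentationParams):
    """EM fit of a 2-state Gaussian HMM; returns per-chrom P(high state).

    Initialization: state means at the 25th/75th score percentiles, shared
    variance, sticky transitions. Convergence at log-likelihood change
    < 1e-4 or 100 iterations. Falls back to a fixed 0.5 score threshold
    when the states collapse (mean separation below
    ``params.min_state_separation``) or the EM degenerates.
    """
    from hmmlearn.hmm import GaussianHMM

    allobs = np.concatenate(obs_per_chrom)
    q25, q75 = np.percentile(allobs, [25, 75])
    var = max(float(np.var(allobs)), 1e-4)

    model = GaussianHMM(
        n_components=2,
        covariance_type="diag",
        init_params="",
        params="stmc",
        tol=1e-4,
        n_iter=100,
    )
    model.startprob_ = np.array([0.5, 0.5])
    model.transmat_ = np.array([[0.99, 0.01], [0.01, 0.99]])
    model.means_ = np.array([[q25], [q75]])
    model.covars_ = np.array([[var], [var]])

    X = allobs.reshape(-1, 1)
    lengths = [len(o) for o in obs_per_chrom]
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit(X, lengths)
        means = model.means_.ravel()
        if not np.all(np.isfinite(means)) or np.any(model.covars_.ravel() <= 0):
            raise ValueError("degenerate emission parameters")
    except (ValueError, np.linalg.LinAlgError) as exc:
        warnings.warn(f"HMM EM failed ({exc}); falling back to 0.5 threshold", stacklevel=3)
        return [(o > 0.5).astype(float) for o in obs_per_chrom], None

    if abs(means[1] - means[0]) < params.min_state_separation:
        # effectively one-state data: call a CpG disordered only if its
        # score clears the fixed midpoint
        return [(o > 0.5).astype(float) for o in obs_per_chrom], None

    hi = int(np.argmax(means))
    post = model.predict_proba(X)[:, hi]
    out, off = [], 0
    for ln in lengths:
        out.append(post[off : off + ln])
        off += ln
    return out, model


def detect_pmrs(
    track: DisorderTrack,
    methylome: Methylome,
    params: SegmentationParams | None = None,
    decoding: str = "posterior",
) -> list[GenomicRegion]:
    """Call PMRs as maximal runs of the HMM high-disorder state.

    Runs on the same chromosome separated by fewer than ``window_cpgs``
    intervening CpGs are fused, and fused runs spanning fewer than one
    window of CpGs are discarded — one window is the resolution limit of
    the windowed score, so smaller calls cannot be distinguished from
    score bumps over intermediate-methylation features such as LMRs.
    Region coordinates span the first to last member CpG dyad,
    end-exclusive.
    """
    params = params or SegmentationParams()
    chroms = [c for c in methylome.chroms if c in track]
    if not chroms:
        return []
    obs = [track[c] for c in chroms]
    post_per_chrom, model = _fit_two_state_hmm(obs, params)

    if decoding == "viterbi" and model is not None:
        hi = int(np.argmax(model.means_.ravel()))
        states = model.predict(np.concatenate(obs).reshape(-1, 1), [len(o) for o in obs])
        flags, off = [], 0
        for o in obs:
            flags.append(states[off : off + len(o)] == hi)
            off += len(o)
    else:
        flags = [p > 0.5 for p in post_per_chrom]

    regions: list[GenomicRegion] = []
    for chrom, flag in zip(chroms, flags):
        calls = methylome.data[chrom]
        runs = _bool_runs(flag)
        # fuse runs separated by < window_cpgs intervening CpGs
        fused: list[list[int]] = []
        for s, e in runs:
            if fused and s - fused[-1][1] < params.window_cpgs:
                fused[-1][1] = e
            else:
                fused.append([s, e])
        min_run = params.min_pmr_cpgs if params.min_pmr_cpgs is not None else params.window_cpgs
        fused = [(s, e) for s, e in fused if e - s >= min_run]
        for s, e in fused:
            meth = calls.meth[s:e].sum()
            total = calls.total[s:e].sum()
            regions.append(
                GenomicRegion(
                    chrom,
                    int(calls.pos[s]),
                    int(calls.pos[e - 1]) + 2,
                    "PMR",
                    n_cpg=e - s,
                    mean_meth=float(meth / total) if total else None,
                )
            )
    return regions


def _bool_runs(flag: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as half-open index intervals."""
    if not flag.any():
        return []
    padded = np.concatenate([[False], flag, [False]])
    d = np.diff(padded.astype(np.int8))
    starts = np.where(d == 1)[0]
    ends = np.where(d == -1)[0]
    return list(zip(starts.tolist(), ends.tolist()))


# ---------------------------------------------------------------------------
# masking, smoothing, randomization
# ---------------------------------------------------------------------------


def mask_methylome(
    methylome: Methylome,
    pmrs: list[GenomicRegion],
    params: SegmentationParams | None = None,
) -> Methylome:
    """Drop CpGs inside PMRs, extended by the half-window safety margin.

    The margin (``params.mask_margin_cpgs``, default window // 2) guards
    against the one-window boundary uncertainty of the disorder score
    leaking intermediate-methylation CpGs into hypomethylated-region
    detection.
    """
    params = params or SegmentationParams()
    margin = params.margin
    data: dict[str, ChromCalls] = {}
    by_chrom: dict[str, list[GenomicRegion]] = {}
    for r in pmrs:
        by_chrom.setdefault(r.chrom, []).append(r)
    for chrom in methylome.chroms:
        calls = methylome.data[chrom]
        keep = np.ones(len(calls), dtype=bool)
        for r in by_chrom.get(chrom, []):
            i0 = int(np.searchsorted(calls.pos, r.start, side="left"))
            i1 = int(np.searchsorted(calls.pos, r.end, side="left"))
            keep[max(0, i0 - margin) : i1 + margin] = False
        if keep.any():
            data[chrom] = ChromCalls(
                pos=calls.pos[keep], meth=calls.meth[keep], total=calls.total[keep]
            )
    return Methylome(
        sample_id=methylome.sample_id, chrom_sizes=dict(methylome.chrom_sizes), data=data
    )


def smooth_methylome(
    methylome: Methylome,
    pmrs: list[GenomicRegion] | None = None,
    params: SegmentationParams | None = None,
    weighted: bool = True,
) -> SmoothedMethylome:
    """Running-window smoothing of a (masked) methylome.

    The smoothed level of a CpG is the coverage-weighted mean over the CpG
    and its immediate retained neighbors (window ``smooth_cpgs``,
    truncated at chromosome boundaries and at masked gaps). With
    ``weighted=False`` the plain arithmetic mean of levels is used.
    """
    params = params or SegmentationParams()
    half = params.smooth_cpgs // 2
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for r in pmrs or []:
        by_chrom.setdefault(r.chrom, []).append(r.interval)
    out = SmoothedMethylome(
        sample_id=methylome.sample_id, chrom_sizes=dict(methylome.chrom_sizes)
    )
    for chrom in methylome.chroms:
        calls = methylome.data[chrom]
        n = len(calls)
        if n == 0:
            continue
        gap_before = np.zeros(n, dtype=bool)
        ivs = sorted(by_chrom.get(chrom, []))
        if ivs and n > 1:
            # a masked interval between consecutive retained CpGs breaks
            # the smoothing window
            starts = np.array([s for s, _ in ivs])
            ends = np.array([e for _, e in ivs])
            prev = calls.pos[:-1]
            nxt = calls.pos[1:]
            j = np.searchsorted(ends, prev, side="right")
            valid = j < len(starts)
            hit = np.zeros(n - 1, dtype=bool)
            hit[valid] = starts[j[valid]] < nxt[valid]
            gap_before[1:] = hit
        level = calls.level
        w = calls.total.astype(np.float64) if weighted else np.ones(n)
        smoothed = np.empty(n, dtype=np.float64)
        # segment bounds: [seg_start, seg_end) runs without masked gaps
        seg_starts = np.where(gap_before)[0].tolist()
        bounds = [0] + seg_starts + [n]
        for b0, b1 in zip(bounds[:-1], bounds[1:]):
            if b0 >= b1:
                continue
            lw = level[b0:b1] * w[b0:b1]
            cw = np.concatenate([[0.0], np.cumsum(w[b0:b1])])
            clw = np.concatenate([[0.0], np.cumsum(lw)])
            m = b1 - b0
            idx = np.arange(m)
            lo = np.maximum(idx - half, 0)
            hi = np.minimum(idx + half + 1, m)
            smoothed[b0:b1] = (clw[hi] - clw[lo]) / (cw[hi] - cw[lo])
        out.data[chrom] = SmoothedChrom(
            pos=calls.pos.copy(),
            smoothed=smoothed,
            meth=calls.meth.copy(),
            total=calls.total.copy(),
            gap_before=gap_before,
        )
    return out


def mask_and_smooth(
    methylome: Methylome,
    pmrs: list[GenomicRegion],
    params: SegmentationParams | None = None,
    weighted: bool = True,
) -> SmoothedMethylome:
    """Mask PMR CpGs, then smooth the retained methylome."""
    params = params or SegmentationParams()
    return smooth_methylome(mask_methylome(methylome, pmrs, params), pmrs, params, weighted)


def randomize_methylome(methylome: Methylome, seed: int) -> Methylome:
    """Permute (meth, total) pairs across the fixed CpG positions.

    The permutation is per chromosome, preserving each chromosome's level
    and coverage multiset; deterministic given the seed.
    """
    rng = np.random.default_rng(seed)
    data: dict[str, ChromCalls] = {}
    for chrom in methylome.chroms:
        calls = methylome.data[chrom]
        perm = rng.permutation(len(calls))
        data[chrom] = ChromCalls(
            pos=calls.pos.copy(), meth=calls.meth[perm], total=calls.total[perm]
        )
    return Methylome(
        sample_id=f"{methylome.sample_id}:randomized",
        chrom_sizes=dict(methylome.chrom_sizes),
        data=data,
    )


# ---------------------------------------------------------------------------
# hypomethylated-region detection and classification
# ---------------------------------------------------------------------------


def detect_hypomethylated_regions(
    smoothed: SmoothedMethylome,
    min_cpgs: int = 3,
    max_meth: float = 0.50,
) -> list[GenomicRegion]:
    """Detect hypomethylated regions on the masked, smoothed methylome.

    Candidate regions are maximal runs of consecutive CpGs with smoothed
    level <= ``max_meth`` (runs never extend across a masked PMR gap). A
    candidate is kept when it has genuine hypomethylated support: at
    least ``min_cpgs`` member CpGs, of which at least ``min_cpgs`` carry a
    *raw* level <= ``max_meth``, and a coverage-weighted region mean
    <= ``max_meth``. Without the support conditions a single unmethylated
    CpG smeared over the smoothing window would satisfy the nominal
    CpG-count rule, which would make it meaningless.

    Region ``mean_meth`` is the coverage-weighted mean of the raw levels
    in the run; coordinates span first to last member CpG dyad,
    end-exclusive.
    """
    regions: list[GenomicRegion] = []
    for chrom in smoothed.chroms:
        c = smoothed.data[chrom]
        low = c.smoothed <= max_meth
        raw_low = (c.meth / c.total) <= max_meth
        run_start = None
        for i in range(len(c) + 1):
            boundary = i == len(c) or not low[i] or (i > 0 and c.gap_before[i])
            if run_start is not None and boundary:
                end = i
                meth = int(c.meth[run_start:end].sum())
                total = int(c.total[run_start:end].sum())
                mean = meth / total
                if (
                    end - run_start >= min_cpgs
                    and int(raw_low[run_start:end].sum()) >= min_cpgs
                    and mean <= max_meth
                ):
                    regions.append(
                        GenomicRegion(
                            chrom,
                            int(c.pos[run_start]),
                            int(c.pos[end - 1]) + 2,
                            "raw",
                            n_cpg=end - run_start,
                            mean_meth=mean,
                        )
                    )
                run_start = None
            if i < len(c) and low[i] and (run_start is None or (i > 0 and c.gap_before[i])):
                run_start = i
    return regions


def classify_segments(
    regions: list[GenomicRegion], lmr_umr_cutoff: int = 30
) -> list[GenomicRegion]:
    """Split hypomethylated regions into UMR (n_cpg >= cutoff) and LMR."""
    out = []
    for r in regions:
        cls = "UMR" if r.n_cpg >= lmr_umr_cutoff else "LMR"
        out.append(
            GenomicRegion(r.chrom, r.start, r.end, cls, r.n_cpg, r.mean_meth)
        )
    return out


def calibrate_detection_params(
    methylome: Methylome,
    grid: list[tuple[int, float]],
    seed: int,
    params: SegmentationParams | None = None,
    pmrs: list[GenomicRegion] | None = None,
    n_randomizations: int = 1,
) -> FdrCalibration:
    """Estimate the FDR of hypomethylated-region detection per grid point.

    The methylome is PMR-masked and smoothed; a randomized copy (same
    masked positions, permuted (level, counts) pairs per chromosome) is
    smoothed identically. FDR at a grid point = regions detected on the
    randomized methylome / regions detected on the original (1.0 when the
    original count is zero). With ``n_randomizations > 1`` the randomized
    count is averaged over independent permutations to reduce Monte-Carlo
    error.

    The chosen point is the standard (3, 0.50) if its FDR clears
    ``params.fdr_threshold``, otherwise the least stringent passing point
    (smallest min_cpgs, then largest max_meth). Raises CalibrationError
    when no point passes.
    """
    if not grid:
        raise ValueError("empty calibration grid")
    params = params or SegmentationParams()
    if pmrs is None:
        track = disorder_score_track(methylome, params)
        pmrs = detect_pmrs(track, methylome, params)
    masked = mask_methylome(methylome, pmrs, params)
    sm_orig = smooth_methylome(masked, pmrs, params)
    seeds = [seed + 9973 * k for k in range(n_randomizations)]
    sm_rands = [
        smooth_methylome(randomize_methylome(masked, s), pmrs, params) for s in seeds
    ]

    counts_o, counts_r, fdrs = [], [], []
    for mc, mm in grid:
        n_o = len(detect_hypomethylated_regions(sm_orig, mc, mm))
        n_r = float(
            np.mean([len(detect_hypomethylated_regions(sm, mc, mm)) for sm in sm_rands])
        )
        counts_o.append(n_o)
        counts_r.append(n_r)
        fdrs.append(n_r / n_o if n_o > 0 else 1.0)

    passing = [
        (mc, mm)
        for (mc, mm), f in zip(grid, fdrs)
        if f < params.fdr_threshold
    ]
    default = (params.min_cpgs, params.max_meth)
    if default in passing:
        chosen = default
    elif passing:
        chosen = sorted(passing, key=lambda p: (p[0], -p[1]))[0]
    else:
        best = min(fdrs)
        raise CalibrationError(
            f"no grid point reached FDR < {params.fdr_threshold}; best achieved {best:.3f}"
        )
    return FdrCalibration(
        grid=list(grid),
        counts_original=counts_o,
        counts_randomized=counts_r,
        fdr=fdrs,
        chosen=chosen,
        fdr_threshold=params.fdr_threshold,
    )


# ---------------------------------------------------------------------------
# stage merging
# ---------------------------------------------------------------------------


def merge_stage_segmentations(
    stage_sets: list[list[GenomicRegion]],
    union_methylome: Methylome,
    lmr_umr_cutoff: int = 30,
) -> list[GenomicRegion]:
    """Merge per-stage segmentations into one consensus segment set.

    Within each class family ({LMR, UMR, raw} and {PMR}) overlapping or
    book-ended intervals are merged; merged hypomethylated intervals are
    re-classified LMR/UMR by their CpG count in the union methylome, and
    region statistics are recomputed from it.
    """
    from . import intervals as iv

    if not stage_sets:
        raise ValueError("need at least one stage segmentation")
    fam_hypo: dict[str, list[tuple[int, int]]] = {}
    fam_pmr: dict[str, list[tuple[int, int]]] = {}
    for regions in stage_sets:
        for r in regions:
            fam = fam_pmr if r.region_class == "PMR" else fam_hypo
            fam.setdefault(r.chrom, []).append(r.interval)

    out: list[GenomicRegion] = []
    for fam, is_pmr in ((fam_hypo, False), (fam_pmr, True)):
        for chrom, ivs in fam.items():
            calls = union_methylome.data.get(chrom)
            for s, e in iv.merge(ivs):
                if calls is not None:
                    i0 = int(np.searchsorted(calls.pos, s, side="left"))
                    i1 = int(np.searchsorted(calls.pos, e, side="left"))
                    n_cpg = i1 - i0
                    total = int(calls.total[i0:i1].sum())
                    mean = (
                        float(calls.meth[i0:i1].sum() / total) if total else None
                    )
                else:
                    n_cpg, mean = 0, None
                if is_pmr:
                    cls = "PMR"
                else:
                    cls = "UMR" if n_cpg >= lmr_umr_cutoff else "LMR"
                out.append(GenomicRegion(chrom, s, e, cls, n_cpg, mean))
    out.sort(key=lambda r: (r.chrom, r.start, r.end))
    return out


def segment_methylome(
    methylome: Methylome,
    params: SegmentationParams | None = None,
    seed: int = 0,
    calibration_grid: list[tuple[int, float]] | None = None,
    n_randomizations: int = 1,
) -> tuple[list[GenomicRegion], list[GenomicRegion], FdrCalibration | None]:
    """One-call segmentation: PMRs, classified LMR/UMR set, calibration.

    Runs disorder scoring, PMR detection, masking + smoothing,
    (optionally) FDR calibration over ``calibration_grid``, and
    hypomethylated-region detection at the chosen parameters.
    """
    params = params or SegmentationParams()
    track = disorder_score_track(methylome, params)
    pmrs = detect_pmrs(track, methylome, params)
    calibration = None
    mc, mm = params.min_cpgs, params.max_meth
    if calibration_grid:
        calibration = calibrate_detection_params(
            methylome, calibration_grid, seed, params, pmrs, n_randomizations
        )
        mc, mm = calibration.chosen
    smoothed = mask_and_smooth(methylome, pmrs, params)
    hypo = detect_hypomethylated_regions(smoothed, mc, mm)
    return pmrs, classify_segments(hypo, params.lmr_umr_cutoff), calibration
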
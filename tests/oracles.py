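"""Independent brute-force oracles used by unit and acceptance tests."""

from __future__ import annotations

import numpy as np


def brute_force_hypo_regions(sm, min_cpgs: int, max_meth: float):
    """Enumerate hypomethylated regions by direct definition.

    For every chromosome, every maximal contiguous index stretch with all
    smoothed levels <= max_meth and no masked gap inside is found by
    explicit scanning of all start positions; a stretch is kept when it
    has >= min_cpgs CpGs, >= min_cpgs raw levels <= max_meth, and a
    coverage-weighted mean <= max_meth. Returns (chrom, start, end,
    n_cpg) tuples.
    """
    out = []
    for chrom in sm.chroms:
        c = sm.data[chrom]
        n = len(c)
        low = c.smoothed <= max_meth
        raw = c.meth / c.total
        i = 0
        while i < n:
            if not low[i]:
                i += 1
                continue
            # extend j as far as the run definition allows
            j = i + 1
            while j < n and low[j] and not c.gap_before[j]:
                j += 1
            # check maximality on the left (start of run must not extend)
            left_blocked = i == 0 or not low[i - 1] or c.gap_before[i]
            assert left_blocked, "scan invariant"
            seg_meth = int(c.meth[i:j].sum())
            seg_total = int(c.total[i:j].sum())
            if (
                j - i >= min_cpgs
                and int((raw[i:j] <= max_meth).sum()) >= min_cpgs
                and seg_meth / seg_total <= max_meth
            ):
                out.append((chrom, int(c.pos[i]), int(c.pos[j - 1]) + 2, j - i))
            i = j
    return out


def random_smoothed_chrom(rng, n: int, gap_prob: float = 0.03):
    """A random SmoothedChrom-like object mixing low and high levels."""
    from segmeth.segmentation import SmoothedChrom

    pos = np.cumsum(rng.integers(2, 200, size=n)).astype(np.int64)
    total = rng.integers(1, 40, size=n).astype(np.int64)
    # mixture: polarized highs, lows, and mid-range values
    kind = rng.random(n)
    level = np.where(
        kind < 0.35, rng.uniform(0.0, 0.45, n),
        np.where(kind < 0.55, rng.uniform(0.45, 0.55, n), rng.uniform(0.55, 1.0, n)),
    )
    meth = np.rint(level * total).astype(np.int64)
    smoothed = np.clip(level + rng.normal(0, 0.05, n), 0, 1)
    gap_before = rng.random(n) < gap_prob
    gap_before[0] = False
    return SmoothedChrom(
        pos=pos, smoothed=smoothed, meth=meth, total=total, gap_before=gap_before
    )
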
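"""Shared fixtures: small planted genomes and their segmentation products."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from segmeth.io import ChromCalls, Methylome
from segmeth.segmentation import (
    SegmentationParams,
    detect_pmrs,
    disorder_score_track,
    mask_and_smooth,
)
from segmeth.synthetic import build_layout, simulate_methylome


def make_methylome(
    levels, coverages=None, start=1000, gap=100, chrom="chr1", sample_id="m"
) -> Methylome:
    """Methylome on one chromosome from explicit levels (and coverages)."""
    levels = np.asarray(levels, dtype=float)
    if coverages is None:
        coverages = np.full(len(levels), 20, dtype=np.int64)
    coverages = np.asarray(coverages, dtype=np.int64)
    pos = start + gap * np.arange(len(levels), dtype=np.int64)
    meth = np.rint(levels * coverages).astype(np.int64)
    size = int(pos[-1]) + gap if len(pos) else 10_000
    return Methylome(
        sample_id=sample_id,
        chrom_sizes={chrom: size},
        data={chrom: ChromCalls(pos=pos, meth=meth, total=coverages)},
    )


@pytest.fixture(scope="session")
def default_layout():
    return build_layout(seed=7)


@pytest.fixture(scope="session")
def default_methylome(default_layout):
    methylome, truth = simulate_methylome(default_layout, seed=7)
    return methylome, truth


@pytest.fixture(scope="session")
def segmented(default_layout, default_methylome):
    """PMRs and the masked+smoothed methylome for the default layout."""
    methylome, _ = default_methylome
    params = SegmentationParams()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        track = disorder_score_track(methylome, params)
        pmrs = detect_pmrs(track, methylome, params)
        smoothed = mask_and_smooth(methylome, pmrs, params)
    return params, pmrs, smoothed
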
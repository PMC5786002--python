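"""PMR and hypomethylated-region segmentation."""

import warnings

import numpy as np
import pytest

from segmeth import intervals as iv
from segmeth.io import GenomicRegion
from segmeth.segmentation import (
    CalibrationError,
    SegmentationParams,
    SmoothedChrom,
    SmoothedMethylome,
    calibrate_detection_params,
    classify_segments,
    detect_hypomethylated_regions,
    detect_pmrs,
    disorder_score_track,
    mask_and_smooth,
    mask_methylome,
    merge_stage_segmentations,
    pool_replicates,
    randomize_methylome,
    segment_methylome,
    smooth_methylome,
)
from .conftest import make_methylome
from .oracles import brute_force_hypo_regions, random_smoothed_chrom


def smoothed_from_values(values, coverages=None, gaps=None, gap=100):
    """SmoothedMethylome where smoothed == raw == given values."""
    values = np.asarray(values, dtype=float)
    n = len(values)
    cov = np.asarray(
        coverages if coverages is not None else np.full(n, 10), dtype=np.int64
    )
    pos = 1000 + gap * np.arange(n, dtype=np.int64)
    gb = np.zeros(n, dtype=bool)
    if gaps:
        gb[list(gaps)] = True
    chrom = SmoothedChrom(
        pos=pos,
        smoothed=values,
        meth=np.rint(values * cov).astype(np.int64),
        total=cov,
        gap_before=gb,
    )
    return SmoothedMethylome("s", {"chr1": int(pos[-1]) + gap}, {"chr1": chrom})


class TestDisorderScore:
    def test_fully_polarized_window_scores_zero(self):
        m = make_methylome([0.0, 1.0] * 60, coverages=np.full(120, 30))
        track = disorder_score_track(m, SegmentationParams(window_cpgs=101))
        assert np.all(track["chr1"] == 0.0)

    def test_fully_intermediate_window_scores_one(self):
        m = make_methylome([0.5] * 120, coverages=np.full(120, 30))
        track = disorder_score_track(m, SegmentationParams(window_cpgs=101))
        assert np.all(track["chr1"] == 1.0)

    def test_mixed_window_counts_exactly(self):
        # 50 of 101 CpGs intermediate (0.5), the rest polarized at 0.95
        levels = np.array([0.5] * 50 + [0.95] * 51)
        m = make_methylome(levels, coverages=np.full(101, 100))
        track = disorder_score_track(m, SegmentationParams(window_cpgs=101))
        assert np.allclose(track["chr1"], 50 / 101)

    def test_edges_carry_nearest_full_window_score(self):
        levels = np.concatenate([np.full(101, 0.5), np.full(101, 0.95)])
        m = make_methylome(levels, coverages=np.full(202, 100))
        track = disorder_score_track(m, SegmentationParams(window_cpgs=101))
        s = track["chr1"]
        assert np.all(s[:50] == s[50])
        assert np.all(s[-50:] == s[-51])

    def test_short_chromosome_skipped_with_warning(self):
        m = make_methylome([0.5] * 50)
        with pytest.warns(UserWarning, match="skipped"):
            track = disorder_score_track(m, SegmentationParams())
        assert "chr1" not in track


class TestDetectPmrs:
    def test_one_state_polarized_data_yields_no_pmrs(self):
        rng = np.random.default_rng(0)
        levels = rng.choice([0.05, 0.95], size=800)
        m = make_methylome(levels, coverages=np.full(800, 30))
        params = SegmentationParams()
        track = disorder_score_track(m, params)
        assert detect_pmrs(track, m, params) == []

    def test_planted_disordered_block_recovered(self):
        # a 2000-CpG (~200 kb) block of Uniform(0,1) latent levels inside a
        # polarized background, observed at 30x binomial coverage
        rng = np.random.default_rng(1)
        lat = np.concatenate(
            [
                rng.choice([0.03, 0.97], size=1500),
                rng.uniform(0, 1, size=2000),
                rng.choice([0.03, 0.97], size=1500),
            ]
        )
        cov = np.full(len(lat), 30)
        levels = rng.binomial(30, lat) / 30
        m = make_methylome(levels, coverages=cov)
        params = SegmentationParams()
        pmrs = detect_pmrs(disorder_score_track(m, params), m, params)
        pos = m.data["chr1"].pos
        planted = (int(pos[1500]), int(pos[3499]) + 2)
        assert len(pmrs) == 1
        called = pmrs[0]
        overlap = iv.overlap_length(called.interval, planted)
        assert overlap / (planted[1] - planted[0]) >= 0.90
        assert iv.jaccard(called.interval, planted) >= 0.8

    def test_blocks_separated_by_under_one_window_are_fused(self):
        rng = np.random.default_rng(3)
        polarized = lambda n: rng.choice([0.03, 0.97], size=n)  # noqa: E731
        disordered = lambda n: rng.uniform(0.3, 0.7, size=n)  # noqa: E731
        levels = np.concatenate(
            [polarized(400), disordered(200), polarized(50), disordered(200), polarized(400)]
        )
        m = make_methylome(levels, coverages=np.full(len(levels), 30))
        params = SegmentationParams()
        pmrs = detect_pmrs(disorder_score_track(m, params), m, params)
        assert len(pmrs) == 1
        # the fused region spans both planted blocks
        pos = m.data["chr1"].pos
        assert pmrs[0].start <= pos[420]
        assert pmrs[0].end > pos[830]


class TestMaskAndSmooth:
    def test_isolated_cpg_keeps_own_level(self):
        m = make_methylome([0.6])
        sm = smooth_methylome(m)
        assert sm.data["chr1"].smoothed[0] == pytest.approx(0.6)

    def test_equal_coverage_center_is_arithmetic_mean(self):
        m = make_methylome([0.0, 0.3, 0.6], coverages=[10, 10, 10])
        sm = smooth_methylome(m)
        assert sm.data["chr1"].smoothed[1] == pytest.approx(0.3)

    def test_coverage_weighted_center(self):
        m = make_methylome([0.2, 0.2, 0.8], coverages=[10, 10, 20])
        sm = smooth_methylome(m)
        # (0.2*10 + 0.2*10 + 0.8*20) / 40 = 0.5
        assert sm.data["chr1"].smoothed[1] == pytest.approx(0.5)

    def test_unweighted_flag(self):
        m = make_methylome([0.2, 0.2, 0.8], coverages=[10, 10, 20])
        sm = smooth_methylome(m, weighted=False)
        assert sm.data["chr1"].smoothed[1] == pytest.approx(0.4)

    def test_pmr_cpgs_masked_and_smoothing_truncated_at_gap(self):
        m = make_methylome([0.0, 0.0, 0.5, 0.5, 0.9, 0.9])
        pos = m.data["chr1"].pos
        pmr = [GenomicRegion("chr1", int(pos[2]), int(pos[3]) + 2, "PMR")]
        params = SegmentationParams(mask_margin_cpgs=0)
        sm = mask_and_smooth(m, pmr, params)
        c = sm.data["chr1"]
        assert len(c) == 4
        assert list(c.gap_before) == [False, False, True, False]
        # windows never reach across the masked gap
        assert c.smoothed[1] == pytest.approx(0.0)
        assert c.smoothed[2] == pytest.approx(0.9)

    def test_mask_margin_extends_beyond_region(self):
        m = make_methylome([0.5] * 10)
        pos = m.data["chr1"].pos
        pmr = [GenomicRegion("chr1", int(pos[4]), int(pos[5]) + 2, "PMR")]
        masked = mask_methylome(m, pmr, SegmentationParams(mask_margin_cpgs=2))
        assert list(masked.data["chr1"].pos) == list(pos[[0, 1, 8, 9]])


class TestRandomize:
    def test_level_multiset_preserved_and_deterministic(self, default_methylome):
        methylome, _ = default_methylome
        r1 = randomize_methylome(methylome, seed=5)
        r2 = randomize_methylome(methylome, seed=5)
        for chrom in methylome.chroms:
            a, b = methylome.data[chrom], r1.data[chrom]
            assert np.array_equal(a.pos, b.pos)
            pairs = lambda c: sorted(zip(c.meth.tolist(), c.total.tolist()))  # noqa: E731
            assert pairs(a) == pairs(b)
            assert np.array_equal(r1.data[chrom].meth, r2.data[chrom].meth)

    def test_different_seed_differs(self, default_methylome):
        methylome, _ = default_methylome
        r1 = randomize_methylome(methylome, seed=5)
        r2 = randomize_methylome(methylome, seed=6)
        assert any(
            not np.array_equal(r1.data[c].meth, r2.data[c].meth)
            for c in methylome.chroms
        )

    def test_single_cpg_chromosome_unchanged(self):
        m = make_methylome([0.4])
        r = randomize_methylome(m, seed=1)
        assert np.array_equal(r.data["chr1"].meth, m.data["chr1"].meth)


class TestDetectHypomethylated:
    def test_direct_threshold_example(self):
        sm = smoothed_from_values([0.9, 0.9, 0.2, 0.3, 0.4, 0.9])
        (region,) = detect_hypomethylated_regions(sm, 3, 0.5)
        assert region.n_cpg == 3
        c = sm.data["chr1"]
        assert (region.start, region.end) == (int(c.pos[2]), int(c.pos[4]) + 2)
        assert region.mean_meth == pytest.approx(0.3)

    def test_run_of_two_rejected(self):
        sm = smoothed_from_values([0.9, 0.2, 0.3, 0.9])
        assert detect_hypomethylated_regions(sm, 3, 0.5) == []

    def test_all_high_yields_nothing(self):
        sm = smoothed_from_values([0.8, 0.9, 0.7, 0.95])
        assert detect_hypomethylated_regions(sm, 3, 0.5) == []

    def test_single_smeared_low_cpg_rejected(self):
        # one unmethylated CpG drags three smoothed values under the cutoff
        # but carries no 3-CpG hypomethylated support
        cov = np.full(5, 10, dtype=np.int64)
        pos = 1000 + 100 * np.arange(5, dtype=np.int64)
        raw = np.array([0.9, 0.6, 0.0, 0.6, 0.9])
        smoothed = np.array([0.75, 0.5, 0.4, 0.5, 0.75])
        chrom = SmoothedChrom(
            pos=pos,
            smoothed=smoothed,
            meth=np.rint(raw * cov).astype(np.int64),
            total=cov,
            gap_before=np.zeros(5, dtype=bool),
        )
        sm = SmoothedMethylome("s", {"chr1": 2000}, {"chr1": chrom})
        assert detect_hypomethylated_regions(sm, 3, 0.5) == []

    def test_runs_do_not_cross_masked_gaps(self):
        sm = smoothed_from_values([0.2, 0.2, 0.2, 0.2], gaps=[2])
        assert detect_hypomethylated_regions(sm, 3, 0.5) == []
        sm2 = smoothed_from_values([0.2, 0.2, 0.2, 0.2], gaps=[3])
        (region,) = detect_hypomethylated_regions(sm2, 3, 0.5)
        assert region.n_cpg == 3

    def test_matches_brute_force_on_random_chromosomes(self):
        rng = np.random.default_rng(12)
        for _ in range(25):
            n = int(rng.integers(5, 400))
            chrom = random_smoothed_chrom(rng, n)
            sm = SmoothedMethylome("s", {"chr1": int(chrom.pos[-1]) + 10}, {"chr1": chrom})
            for min_cpgs, max_meth in ((3, 0.5), (4, 0.5), (3, 0.3)):
                got = [
                    (r.chrom, r.start, r.end, r.n_cpg)
                    for r in detect_hypomethylated_regions(sm, min_cpgs, max_meth)
                ]
                assert got == brute_force_hypo_regions(sm, min_cpgs, max_meth)


class TestClassify:
    @pytest.mark.parametrize("n_cpg,expected", [(30, "UMR"), (29, "LMR"), (150, "UMR"), (3, "LMR")])
    def test_cutoff_boundary(self, n_cpg, expected):
        r = GenomicRegion("chr1", 0, 1000, "raw", n_cpg=n_cpg, mean_meth=0.2)
        (out,) = classify_segments([r])
        assert out.region_class == expected

    def test_empty_input(self):
        assert classify_segments([]) == []

    def test_partition_exhaustive_and_exclusive(self, segmented):
        params, pmrs, smoothed = segmented
        raw = detect_hypomethylated_regions(smoothed, params.min_cpgs, params.max_meth)
        classed = classify_segments(raw, params.lmr_umr_cutoff)
        assert len(classed) == len(raw)
        assert {r.region_class for r in classed} <= {"LMR", "UMR"}


class TestCalibration:
    def test_pure_noise_methylome_fails_calibration(self):
        rng = np.random.default_rng(2)
        levels = rng.binomial(30, 0.85, size=3000) / 30
        m = make_methylome(levels, coverages=np.full(3000, 30))
        with pytest.raises(CalibrationError, match="best achieved"):
            calibrate_detection_params(
                m, [(3, 0.5), (5, 0.5)], seed=0, pmrs=[], params=SegmentationParams()
            )

    def test_zero_original_count_defines_fdr_one(self):
        # three planted low regions at level 0.2 in a high background:
        # detectable at (3, 0.5), never at (3, 0.0001)
        rng = np.random.default_rng(9)
        high = lambda n: rng.uniform(0.85, 0.95, n)  # noqa: E731
        levels = np.concatenate(
            [high(400), [0.2] * 10, high(400), [0.2] * 10, high(400), [0.2] * 10, high(400)]
        )
        m = make_methylome(levels, coverages=np.full(len(levels), 30))
        cal = calibrate_detection_params(
            m, [(3, 0.5), (3, 0.0001)], seed=0, params=SegmentationParams(), pmrs=[]
        )
        row = {(r["min_cpgs"], r["max_meth"]): r for r in cal.as_rows()}
        assert row[(3, 0.5)]["n_original"] == 3
        assert row[(3, 0.0001)]["n_original"] == 0
        assert row[(3, 0.0001)]["fdr"] == 1.0

    def test_default_grid_point_chosen_on_planted_methylome(
        self, default_methylome, segmented
    ):
        methylome, _ = default_methylome
        params, pmrs, _ = segmented
        cal = calibrate_detection_params(
            methylome,
            [(3, 0.5), (4, 0.5), (5, 0.5)],
            seed=7,
            params=params,
            pmrs=pmrs,
            n_randomizations=3,
        )
        assert cal.chosen == (3, 0.5)
        assert cal.fdr[0] < 0.05

    def test_fdr_nonincreasing_in_min_cpgs(self, default_methylome, segmented):
        methylome, _ = default_methylome
        params, pmrs, _ = segmented
        cal = calibrate_detection_params(
            methylome,
            [(3, 0.5), (4, 0.5), (5, 0.5)],
            seed=3,
            params=params,
            pmrs=pmrs,
            n_randomizations=10,
        )
        assert cal.fdr[0] >= cal.fdr[1] >= cal.fdr[2]

    def test_empty_grid_rejected(self, default_methylome):
        methylome, _ = default_methylome
        with pytest.raises(ValueError, match="empty"):
            calibrate_detection_params(methylome, [], seed=0, pmrs=[])


class TestMergeStages:
    def test_overlapping_same_family_intervals_merge(self):
        union = make_methylome([0.2] * 32, gap=10)
        pos = union.data["chr1"].pos
        a = [GenomicRegion("chr1", int(pos[0]), int(pos[11]) + 2, "LMR", 12, 0.2)]
        b = [GenomicRegion("chr1", int(pos[8]), int(pos[31]) + 2, "LMR", 24, 0.2)]
        merged = merge_stage_segmentations([a, b], union)
        assert len(merged) == 1
        # 32 CpGs in the union span: re-classified as UMR
        assert merged[0].n_cpg == 32
        assert merged[0].region_class == "UMR"

    def test_hypomethylated_and_pmr_families_do_not_merge(self):
        union = make_methylome([0.3] * 20, gap=10)
        pos = union.data["chr1"].pos
        a = [GenomicRegion("chr1", int(pos[0]), int(pos[9]) + 2, "LMR", 10, 0.3)]
        b = [GenomicRegion("chr1", int(pos[5]), int(pos[15]) + 2, "PMR", 11, 0.3)]
        merged = merge_stage_segmentations([a, b], union)
        assert sorted(r.region_class for r in merged) == ["LMR", "PMR"]

    def test_single_stage_identity_of_intervals(self, segmented):
        params, pmrs, smoothed = segmented
        raw = classify_segments(
            detect_hypomethylated_regions(smoothed, params.min_cpgs, params.max_meth)
        )
        union = make_methylome([0.5])  # counts recomputed against this methylome
        merged = merge_stage_segmentations([raw], union)
        assert [(r.chrom, r.start, r.end) for r in merged] == [
            (r.chrom, r.start, r.end) for r in sorted(raw, key=lambda r: (r.chrom, r.start))
        ]


class TestPoolingAndDeterminism:
    def test_pool_replicates_sums_counts(self):
        a = make_methylome([0.2, 0.4], coverages=[10, 10])
        b = make_methylome([1.0, 0.0], coverages=[5, 5])
        pooled = pool_replicates([a, b])
        assert list(pooled.data["chr1"].total) == [15, 15]
        assert list(pooled.data["chr1"].meth) == [7, 4]

    def test_full_segmentation_is_deterministic(self, default_methylome):
        methylome, _ = default_methylome
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out1 = segment_methylome(methylome, seed=1)
            out2 = segment_methylome(methylome, seed=1)
        assert out1[0] == out2[0]
        assert out1[1] == out2[1]
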
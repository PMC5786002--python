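"""Mark-track normalization, quantification and rank regression."""

import numpy as np
import pandas as pd
import pytest

from segmeth.io import GeneModel, GenomicRegion
from segmeth.marks import (
    MarkTrack,
    combine_mark_ratios,
    expression_rank_regression,
    mark_log2_ratio,
    normalize_to_geometric_mean,
    quantify_region_signal,
    read_bedgraph,
    write_bedgraph,
)
from segmeth.synthetic import simulate_de_table, simulate_genes, simulate_mark_ratios


def flat_track(value, span=100_000, mark="H3K27ac", sample="s", chrom="chr1"):
    return MarkTrack(
        sample_id=sample,
        mark=mark,
        data={
            chrom: (
                np.array([0], dtype=np.int64),
                np.array([span], dtype=np.int64),
                np.array([value], dtype=np.float64),
            )
        },
    )


class TestNormalize:
    def test_two_track_closed_form(self):
        a, b = flat_track(100 / 100_000), flat_track(400 / 100_000)
        normalize_to_geometric_mean([a, b])
        assert a.scale_factor == pytest.approx(2.0)
        assert b.scale_factor == pytest.approx(0.5)

    def test_equal_totals_give_unit_factors(self):
        tracks = [flat_track(0.5) for _ in range(3)]
        normalize_to_geometric_mean(tracks)
        assert all(t.scale_factor == pytest.approx(1.0) for t in tracks)

    def test_three_track_cube_root(self):
        tracks = [flat_track(v / 100_000) for v in (10, 100, 1000)]
        normalize_to_geometric_mean(tracks)
        assert [t.scale_factor for t in tracks] == pytest.approx([10.0, 1.0, 0.1])

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError, match="zero genome-wide"):
            normalize_to_geometric_mean([flat_track(0.0), flat_track(1.0)])

    def test_log_scaled_totals_conserved(self):
        rng = np.random.default_rng(0)
        tracks = [flat_track(v) for v in rng.uniform(0.1, 5.0, 6)]
        raw_log_sum = np.sum([np.log(t.genome_total) for t in tracks])
        normalize_to_geometric_mean(tracks)
        scaled = [t.genome_total * t.scale_factor for t in tracks]
        assert np.sum(np.log(scaled)) == pytest.approx(raw_log_sum)
        assert np.ptp(scaled) == pytest.approx(0.0, abs=1e-6)


class TestQuantify:
    gene = GeneModel("g1", "chr1", "+", 10_000, 14_000)

    def test_flat_promoter_area(self):
        track = flat_track(1.0)
        sig = quantify_region_signal(track, [self.gene], mode="promoter")
        assert sig["g1"] == pytest.approx(2000.0)

    def test_scale_factor_linearity(self):
        track = flat_track(1.0)
        track.scale_factor = 0.5
        sig = quantify_region_signal(track, [self.gene], mode="promoter")
        assert sig["g1"] == pytest.approx(1000.0)

    def test_piecewise_steps(self):
        track = MarkTrack(
            sample_id="s",
            mark="H3K4me3",
            data={
                "chr1": (
                    np.array([9000, 10_000], dtype=np.int64),
                    np.array([10_000, 20_000], dtype=np.int64),
                    np.array([2.0, 4.0]),
                )
            },
        )
        sig = quantify_region_signal(track, [self.gene], mode="promoter")
        assert sig["g1"] == pytest.approx(1000 * 2.0 + 1000 * 4.0)

    def test_auto_mode_follows_mark(self):
        genic = flat_track(1.0, mark="H3K36me3")
        sig = quantify_region_signal(genic, [self.gene], mode="auto")
        assert sig["g1"] == pytest.approx(4000.0)  # TSS..TES
        with pytest.raises(ValueError, match="no automatic target mode"):
            quantify_region_signal(flat_track(1.0, mark="5hmC"), [self.gene])

    def test_explicit_regions_mode(self):
        track = flat_track(2.0, mark="5hmC")
        regions = [GenomicRegion("chr1", 0, 500, "LMR")]
        sig = quantify_region_signal(track, regions=regions, mode="regions")
        assert sig["chr1:0-500"] == pytest.approx(1000.0)

    def test_coverage_rescaling_invariance_of_ratios(self):
        # multiplying one track's coverage everywhere by a constant leaves
        # all between-track signal ratios unchanged after renormalization
        # (raw scaled signals shift jointly by c**(1/n); ratios cancel it)
        def ratio(va, vb):
            a, b = flat_track(va), flat_track(vb, sample="t")
            normalize_to_geometric_mean([a, b])
            sa = quantify_region_signal(a, [self.gene], mode="promoter")["g1"]
            sb = quantify_region_signal(b, [self.gene], mode="promoter")["g1"]
            return sa / sb

        assert ratio(7.0, 1.3) == pytest.approx(ratio(0.7, 1.3))

    def test_negative_start_clipped_with_warning(self):
        near_start = GeneModel("g0", "chr1", "+", 500, 5000)
        with pytest.warns(UserWarning, match="clipped"):
            sig = quantify_region_signal(flat_track(1.0), [near_start], mode="promoter")
        assert sig["g0"] == pytest.approx(1500.0)

    def test_bedgraph_roundtrip(self, tmp_path):
        track = flat_track(2.5)
        write_bedgraph(track, tmp_path / "t.bedgraph")
        back = read_bedgraph(tmp_path / "t.bedgraph", "s", "H3K27ac")
        s, e, v = back.data["chr1"]
        assert (s[0], e[0], v[0]) == (0, 100_000, 2.5)


class TestCombine:
    @pytest.mark.parametrize(
        "cols,expected",
        [
            ({"a": [1.0], "b": [-1.0]}, [0.0]),
            ({"a": [2.5]}, [2.5]),
            ({"a": [2.0], "b": [0.0], "c": [1.0]}, [1.0]),
        ],
    )
    def test_log_scale_average(self, cols, expected):
        df = pd.DataFrame(cols)
        assert combine_mark_ratios(df).tolist() == pytest.approx(expected)


@pytest.fixture(scope="module")
def de_table():
    genes = simulate_genes({"chr1": 60_000_000}, n_genes=1000, seed=0)
    return simulate_de_table(genes, seed=0)


class TestRankRegression:
    def test_exact_cubic_gives_r2_one(self, de_table):
        de = de_table[de_table.q_value < 0.05]
        order = de.sort_values("log2fc").index
        rank = np.arange(1, len(order) + 1, dtype=float)
        y = 1e-6 * (rank - 50) ** 3 + 0.01 * rank
        ratios = pd.DataFrame(
            {"H3K27ac": y, "H3K36me3": y}, index=de_table.loc[order, "gene"]
        )
        res = expression_rank_regression(de_table, ratios)
        assert res.per_mark_r2["H3K27ac"] == pytest.approx(1.0)

    def test_independent_noise_explains_nothing(self, de_table):
        worst = 0.0
        for seed in range(20):
            ratios = simulate_mark_ratios(de_table, 0.0, seed=seed)
            res = expression_rank_regression(de_table, ratios)
            worst = max(worst, *res.per_mark_r2.values())
        assert worst < 0.02

    def test_planted_coupling_recovers_analytic_r2(self, de_table):
        # per-mark R^2 concentrates near rho^2; the two-mark combined model
        # near 2 rho^2 / (1 + rho^2) (best linear predictor from two marks
        # with independent noise)
        rho = 0.7
        per, comb = [], []
        for seed in range(20):
            ratios = simulate_mark_ratios(de_table, rho, seed=seed)
            res = expression_rank_regression(de_table, ratios)
            per.extend(res.per_mark_r2.values())
            comb.append(res.combined_r2)
        assert np.mean(per) == pytest.approx(rho**2, abs=0.05)
        assert np.mean(comb) == pytest.approx(2 * rho**2 / (1 + rho**2), abs=0.1)

    def test_constant_predictor_r2_zero_with_warning(self, de_table):
        ratios = pd.DataFrame(
            {"H3K27ac": 0.0, "H3K36me3": 1.0},
            index=pd.Index(de_table["gene"], name="gene"),
        )
        with pytest.warns(UserWarning, match="constant"):
            res = expression_rank_regression(de_table, ratios)
        assert res.per_mark_r2["H3K27ac"] == 0.0
        assert res.combined_r2 == 0.0

    def test_r2_invariant_under_gene_relabeling(self, de_table):
        ratios = simulate_mark_ratios(de_table, 0.5, seed=1)
        res = expression_rank_regression(de_table, ratios)
        relabel = {g: f"x_{g}" for g in de_table["gene"]}
        de2 = de_table.assign(gene=de_table["gene"].map(relabel))
        ratios2 = ratios.rename(index=relabel)
        res2 = expression_rank_regression(de2, ratios2)
        assert res2.per_mark_r2 == pytest.approx(res.per_mark_r2)
        assert res2.combined_r2 == pytest.approx(res.combined_r2)

    def test_too_few_differential_genes_errors(self, de_table):
        tiny = de_table.head(5)
        ratios = simulate_mark_ratios(tiny, 0.5, seed=0)
        with pytest.raises(ValueError, match=">= 10"):
            expression_rank_regression(tiny, ratios)


class TestMarkRatio:
    def test_ratio_recovers_planted_fold_change(self):
        gene = GeneModel("g1", "chr1", "+", 10_000, 14_000)
        num = flat_track(4.0, mark="H3K36me3")
        den = flat_track(1.0, mark="H3K36me3", sample="t")
        # skip normalization (factors 1) to isolate the ratio computation
        ratio = mark_log2_ratio(num, den, [gene], mode="genic")
        assert ratio["g1"] == pytest.approx(2.0, abs=0.1)
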
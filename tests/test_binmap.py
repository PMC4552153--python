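"""Bin bookkeeping, subtraction identities, ordering and correlations."""

import numpy as np
import pandas as pd
import pytest

from rjmap import binmap as bm
from rjmap import cgh, wheat_d
from rjmap import synthdata as sd


class TestBinLength:
    @pytest.mark.parametrize(
        "arm,interval,expected",
        [
            (224.0, (0.70, 1.00), 67.2),     # 1DS terminal
            (224.0, (0.59, 0.70), 24.64),    # 1DS interstitial
            (381.0, (0.18, 0.41), 87.63),    # 1DL interstitial
            (381.0, (0.41, 1.00), 224.79),   # 1DL terminal
        ],
    )
    def test_published_1d_bin_sizes(self, arm, interval, expected):
        assert bm.estimate_bin_length(arm, interval) == pytest.approx(expected, abs=0.01)

    def test_full_arm_interval_returns_arm_length(self):
        assert bm.estimate_bin_length(300.0, (0.0, 1.0)) == 300.0

    def test_degenerate_interval_rejected(self):
        with pytest.raises(ValueError):
            bm.estimate_bin_length(300.0, (0.5, 0.5))

    def test_tiling_bins_sum_to_arm_length(self):
        bps = [0.1, 0.35, 0.6, 0.85]
        edges = [0.0] + bps + [1.0]
        total = sum(
            bm.estimate_bin_length(413.7, (a, b))
            for a, b in zip(edges[:-1], edges[1:])
        )
        assert total == pytest.approx(413.7, abs=1e-6)


class TestSubtraction:
    def test_published_1d_rjm_cell(self):
        assert bm.pericentromeric_by_subtraction(3921, [67, 113, 273, 247]) == 3221

    def test_published_2d_gene_cell(self):
        assert bm.pericentromeric_by_subtraction(923, [82, 286, 259, 231]) == 65

    def test_exhausted_total_gives_zero(self):
        assert bm.pericentromeric_by_subtraction(10, [10]) == 0

    def test_negative_remainder_is_an_error(self):
        with pytest.raises(ValueError, match="identity"):
            bm.pericentromeric_by_subtraction(5, [3, 4])


class TestDensityAndSummary:
    def test_genome_wide_density(self):
        per_mb, kb = bm.marker_density(35_118, 4_900)
        assert per_mb == pytest.approx(7.17, abs=0.01)
        assert kb == pytest.approx(139.5, abs=0.1)

    def test_assayed_region_density(self):
        per_mb, kb = bm.marker_density(10_241, 2_500)
        assert per_mb == pytest.approx(4.10, abs=0.01)
        assert kb == pytest.approx(244.1, abs=0.1)

    def test_unit_density(self):
        assert bm.marker_density(10, 10.0) == (1.0, 1000.0)

    def test_zero_inputs_rejected(self):
        with pytest.raises(ValueError):
            bm.marker_density(0, 10.0)

    def test_summary_of_single_bin(self):
        s = bm.summarize_bins([42])
        assert s["mean"] == 42 and s["min"] == 42 and s["max"] == 42

    def test_summary_matches_direct_tabulation(self):
        rng = np.random.default_rng(3)
        counts = rng.integers(20, 600, size=40).tolist()
        s = bm.summarize_bins(counts)
        assert s["total"] == sum(counts)
        assert s["mean"] == pytest.approx(np.mean(counts))
        assert (s["min"], s["max"]) == (min(counts), max(counts))


class TestCoverage:
    def test_published_range(self):
        lo, hi = bm.coverage_fraction(2_500, (4_020, 4_950))
        assert lo == pytest.approx(50.5, abs=0.1)
        assert hi == pytest.approx(62.2, abs=0.1)

    def test_full_coverage(self):
        assert bm.coverage_fraction(100, (100, 100)) == (100.0, 100.0)

    def test_half_range(self):
        assert bm.coverage_fraction(1_000, (2_000, 4_000)) == (25.0, 50.0)


class TestOrdering:
    def test_sorted_by_cm(self):
        ordered, disc = bm.order_markers_in_bin({"a": 10.0, "b": 5.0, "c": 20.0})
        assert ordered == ["b", "a", "c"]
        assert disc == []

    def test_marker_inside_neighbour_interval_flagged(self):
        markers = {"a": 50.0, "b": 52.0, "c": 54.0, "stray": 20.0}
        ordered, disc = bm.order_markers_in_bin(markers, prev_interval=(15.0, 25.0))
        assert disc == ["stray"]
        assert ordered == ["a", "b", "c"]

    def test_outlier_without_neighbour_support_kept(self):
        markers = {"a": 50.0, "b": 52.0, "stray": 20.0}
        ordered, disc = bm.order_markers_in_bin(markers, prev_interval=(40.0, 45.0))
        assert disc == []
        assert ordered == ["stray", "a", "b"]

    def test_empty_input(self):
        assert bm.order_markers_in_bin({}) == ([], [])

    def test_partition_property(self):
        rng = np.random.default_rng(5)
        markers = {f"m{i}": float(rng.uniform(0, 100)) for i in range(30)}
        ordered, disc = bm.order_markers_in_bin(markers, (0.0, 10.0), (90.0, 100.0))
        assert sorted(ordered + disc) == sorted(markers)
        assert set(ordered).isdisjoint(disc)

    def test_genetic_length(self):
        assert bm.bin_genetic_length([5.0]) == 0.0
        assert bm.bin_genetic_length([5.0, 20.0]) == 15.0


class TestCorrelation:
    def test_perfect_positive_and_negative(self):
        x = [1.0, 2.0, 3.0, 4.0]
        r = bm.length_correlation(x, x)
        assert r["pearson_r"] == pytest.approx(1.0)
        r = bm.length_correlation(x, [-v for v in x])
        assert r["pearson_r"] == pytest.approx(-1.0)

    def test_independent_lengths_uncorrelated(self):
        rng = np.random.default_rng(12)
        x = rng.uniform(10, 400, size=40)
        y = rng.uniform(0, 50, size=40)
        r = bm.length_correlation(x, y)
        assert abs(r["pearson_r"]) < 0.3
        assert r["pearson_p"] > 0.05

    def test_constant_vector_reported_as_nan(self):
        r = bm.length_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert np.isnan(r["pearson_r"])


@pytest.fixture(scope="module")
def pipeline(small_library):
    genome = sd.simulate_genome(
        small_library,
        [("1D", 50_000, 0.45), ("2D", 50_000, 0.5), ("3D", 50_000, 0.5)],
        te_count=24, nesting_prob=0.2, gene_count=24, seed=8,
    )
    dels = {"1D": {"S": [0.5], "L": [0.3, 0.7]}, "2D": {"L": [0.4]},
            "3D": {"S": [0.6]}}
    panel = sd.build_line_panel(genome, dels)
    probes = sd.probes_from_truth(genome, seed=5)
    mat = sd.simulate_hybridization(
        panel, probes, genome, sd.SignalModel(seed=2)
    )
    assignments = cgh.assign_probes(mat, panel)
    arm_lengths = {}
    chrom_lengths = {}
    for name in genome.chrom_names:
        L = genome.length(name) / 1e6
        af = genome.arm_fractions[name]
        arm_lengths[(name, "S")] = af * L
        arm_lengths[(name, "L")] = (1 - af) * L
        chrom_lengths[name] = L
    bins = bm.bins_from_breakpoints(dels, arm_lengths, chrom_lengths)
    types = {p.id: p.probe_type for p in probes}
    binmap = bm.build_bin_map(assignments, types, bins)
    return genome, probes, assignments, binmap


class TestEndToEndBinMap:
    def test_subtraction_identity_holds_everywhere(self, pipeline):
        genome, probes, assignments, binmap = pipeline
        assigned = assignments[assignments["chromosome"] != cgh.UNASSIGNED]
        for chrom in genome.chrom_names:
            for ptype in ("rjm", "gene"):
                total = binmap.chromosome_totals.get(chrom, {}).get(ptype, 0)
                in_bins = sum(
                    binmap.bin_count(b.label, ptype)
                    for b in binmap.bins
                    if b.chromosome == chrom and b.kind != bm.PERICENTROMERIC_KIND
                )
                peri = binmap.pericentromeric_count(chrom, ptype)
                assert in_bins + peri == total

    def test_each_marker_in_at_most_one_bin(self, pipeline):
        *_, binmap = pipeline
        seen = set()
        for ms in binmap.markers.values():
            assert seen.isdisjoint(ms)
            seen.update(ms)

    def test_summary_frame_schema(self, pipeline):
        *_, binmap = pipeline
        df = binmap.summary()
        assert {"label", "kind", "length_mb", "n_gene", "n_rjm"} <= set(df.columns)
        assert (df["length_mb"] >= 0).all()

    def test_monotone_genetic_map_orders_without_discordance(self, pipeline):
        genome, probes, assignments, binmap = pipeline
        gmap = sd.simulate_genetic_map(
            genome, {p.id: p.genome_coords[0] for p in probes}, seed=1
        )
        ordered, stats = bm.order_within_bins(binmap, gmap)
        assert not ordered["discordant"].any()
        # the ordered markers partition the mapped bin members
        assert len(ordered) == sum(
            1 for ms in binmap.markers.values() for m in ms
        )

    def test_injected_swap_is_flagged_discordant(self):
        """Two adjacent, well-populated bins; swapping the cM positions of
        two interior markers flags exactly those two."""
        bins = [
            bm.DeletionBin("1D", "L", (0.3, 0.7), 80.0, "interstitial",
                           "1DL-0.30-0.70"),
            bm.DeletionBin("1D", "L", (0.7, 1.0), 60.0, "terminal",
                           "1DL-0.70-1.00"),
        ]
        markers = {
            "1DL-0.30-0.70": [f"a{i}" for i in range(5)],
            "1DL-0.70-1.00": [f"b{i}" for i in range(5)],
        }
        types = {m: "gene" for ms in markers.values() for m in ms}
        binmap = bm.BinMap(bins, markers, types,
                           {"1D": {"gene": 10}})
        cm = {f"a{i}": 10.0 + 2 * i for i in range(5)}
        cm.update({f"b{i}": 50.0 + 2 * i for i in range(5)})
        rows = [(m, "1D", c) for m, c in cm.items()]
        gmap = pd.DataFrame(rows, columns=["marker", "chromosome", "cm"])
        ordered, _ = bm.order_within_bins(binmap, gmap)
        assert not ordered["discordant"].any()
        # swap interior markers a2 (14 cM) and b2 (54 cM)
        gm = gmap.set_index("marker")
        gm.loc["a2", "cm"], gm.loc["b2", "cm"] = 54.0, 14.0
        ordered, _ = bm.order_within_bins(binmap, gm.reset_index())
        assert set(ordered[ordered["discordant"]]["marker"]) == {"a2", "b2"}

    def test_distal_bins_have_larger_genetic_spans(self, pipeline):
        genome, probes, assignments, binmap = pipeline
        gmap = sd.simulate_genetic_map(
            genome, {p.id: p.genome_coords[0] for p in probes}, seed=1
        )
        _, stats = bm.order_within_bins(binmap, gmap)
        sub = stats[(stats["chromosome"] == "1D") & (stats["n_ordered"] >= 2)]
        spans = dict(zip(sub["bin"], sub["genetic_span_cm"]))
        distal = [v for k, v in spans.items() if "0.70-1.00" in k]
        proximal = [v for k, v in spans.items() if "0.30-0.70" in k]
        if distal and proximal:
            assert max(distal) > min(proximal)


class TestReportArithmetic:
    def test_chromosome_summary_from_published_table(self):
        s = bm.summarize_chromosomes(wheat_d.CHROMOSOME_TABLE)
        assert s["probes_assigned"] == 41_610
        assert s["markers_assigned"] == 35_118

    def test_bin_mapping_summary_from_published_counts(self):
        s = bm.bin_mapping_summary(
            gene_probes_on_chromosomes=12_417,
            rjm_on_chromosomes=29_193,
            gene_probes_in_bins=10_892,
            rjm_in_bins=5_171,
            unique_gene_markers_in_bins=5_070,
            n_bins=40,
        )
        assert s["gene_probes_unbinned"] == 1_525
        assert s["probes_in_bins"] == 16_063
        assert s["unique_loci_in_bins"] == 10_241
        assert round(s["pct_rjm_binned"]) == 18
        assert round(s["mean_loci_per_bin"]) == 256
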
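"""Signal analysis: normalization, loss testing, ladder, assignment rules."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import hand_pooled_t_p
from rjmap import binmap as bm
from rjmap import cgh
from rjmap import synthdata as sd


class TestQuantileNormalize:
    def test_identical_columns_unchanged(self):
        df = pd.DataFrame({"a": [1.0, 5.0, 3.0], "b": [1.0, 5.0, 3.0]})
        out = cgh.quantile_normalize(df)
        pd.testing.assert_frame_equal(out, df)

    def test_rank_mean_by_hand(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [2.0, 4.0, 6.0]})
        out = cgh.quantile_normalize(df)
        assert list(out["a"]) == [1.5, 3.0, 4.5]
        assert list(out["b"]) == [1.5, 3.0, 4.5]

    def test_ties_get_mean_of_tied_rank_values(self):
        df = pd.DataFrame({"a": [1.0, 1.0, 2.0], "b": [2.0, 4.0, 6.0]})
        out = cgh.quantile_normalize(df)
        # reference = mean of sorted columns: [1.5, 2.5, 4.0]
        # tied entries (ranks 1 and 2) get (1.5 + 2.5)/2 = 2.0
        assert list(out["a"]) == [2.0, 2.0, 4.0]

    def test_sorted_columns_identical_after_normalization(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.lognormal(size=(200, 6)) * [1, 2, 3, 4, 5, 6])
        df.columns = [str(c) for c in df.columns]
        out = cgh.quantile_normalize(df)
        ref = np.sort(out.values[:, 0])
        for j in range(out.shape[1]):
            assert np.allclose(np.sort(out.values[:, j]), ref, atol=1e-9)

    def test_negative_intensities_rejected(self):
        df = pd.DataFrame({"a": [1.0, -1.0], "b": [1.0, 2.0]})
        with pytest.raises(ValueError):
            cgh.quantile_normalize(df)


class TestAverageReplicates:
    def _matrix(self, values):
        cols = {}
        for a in (1, 2):
            for s in (1, 2, 3):
                for ch in ("test", "ref"):
                    cols[f"L1.{a}.{s}.{ch}"] = values[(a, s, ch)]
        return sd.SignalMatrix(pd.DataFrame(cols, index=["p1"]))

    def test_constant_matrix_means_equal_constant(self):
        vals = {(a, s, ch): [7.0] for a in (1, 2) for s in (1, 2, 3)
                for ch in ("test", "ref")}
        out = cgh.average_replicates(self._matrix(vals))
        assert np.allclose(out["p1"].values, 7.0)

    def test_nan_spot_masked_from_mean(self):
        vals = {(a, s, ch): [2.0] for a in (1, 2) for s in (1, 2, 3)
                for ch in ("test", "ref")}
        vals[(1, 2, "test")] = [np.nan]
        vals[(1, 1, "test")] = [4.0]
        out = cgh.average_replicates(self._matrix(vals))
        assert out.loc[("L1", 1, "test"), "p1"] == pytest.approx((4.0 + 2.0) / 2)

    def test_hand_computed_spot_mean(self):
        vals = {(a, s, ch): [1.0] for a in (1, 2) for s in (1, 2, 3)
                for ch in ("test", "ref")}
        vals[(2, 1, "ref")] = [1.0]
        vals[(2, 2, "ref")] = [2.0]
        vals[(2, 3, "ref")] = [6.0]
        out = cgh.average_replicates(self._matrix(vals))
        assert out.loc[("L1", 2, "ref"), "p1"] == pytest.approx(3.0)

    def test_missing_channel_rejected(self):
        df = pd.DataFrame({"L1.1.1.test": [1.0], "L1.1.1.ref": [1.0],
                           "L2.1.1.test": [1.0]}, index=["p1"])
        with pytest.raises(ValueError, match="channel"):
            cgh.average_replicates(sd.SignalMatrix(df))


class TestLossTest:
    def test_no_difference_not_flagged(self):
        r = cgh.loss_test([2.0, 2.0, 2.0], [2.0, 2.0, 2.0], threshold=0.2)
        assert r.loss_fraction == 0.0
        assert not r.flagged

    def test_halved_signal_flagged_with_tiny_variance(self):
        test = [0.50, 0.51, 0.49, 0.50, 0.52, 0.48]
        ref = [1.00, 1.02, 0.98, 1.01, 0.99, 1.00]
        r = cgh.loss_test(test, ref, threshold=0.5)
        assert r.loss_fraction == pytest.approx(0.5, abs=0.01)
        assert r.p_value == pytest.approx(hand_pooled_t_p(test, ref))
        assert r.p_value < 1e-6
        assert r.flagged

    def test_p_rule_binds_at_high_variance(self):
        # loss 0.25 but noisy: the t-test cannot call it
        test = [0.3, 1.2, 0.4, 1.1]
        ref = [1.0, 1.0, 1.0, 1.0]
        r = cgh.loss_test(test, ref, threshold=0.2)
        assert r.loss_fraction == pytest.approx(0.25)
        assert r.p_value == pytest.approx(hand_pooled_t_p(test, ref))
        assert r.p_value > 0.05
        assert not r.flagged

    def test_zero_reference_mean_is_an_error(self):
        with pytest.raises(ZeroDivisionError):
            cgh.loss_test([1.0, 1.0], [0.0, 0.0])

    def test_single_replicate_rejected(self):
        with pytest.raises(ValueError):
            cgh.loss_test([1.0], [1.0, 1.0])

    def test_degenerate_zero_variance_difference_flagged(self):
        r = cgh.loss_test([0.0, 0.0, 0.0], [1.0, 1.0, 1.0], threshold=0.5)
        assert r.loss_fraction == 1.0
        assert r.p_value == 0.0
        assert r.flagged


class TestAssignmentRules:
    def test_single_flag_assigns_chromosome(self):
        flags = {f"{i}D": (i == 3) for i in range(1, 8)}
        assert cgh.assign_chromosome(flags) == "3D"

    @pytest.mark.parametrize("n_flags", [0, 2, 7])
    def test_ambiguous_flags_unassigned(self, n_flags):
        flags = {f"{i}D": (i <= n_flags) for i in range(1, 8)}
        assert cgh.assign_chromosome(flags) == cgh.UNASSIGNED

    def test_all_flagged_is_terminal_bin(self):
        flags = {("L", 0.18): True, ("L", 0.41): True}
        assert cgh.assign_bin("1D", flags) == "1DL-0.41-1.00"

    def test_prefix_flag_is_interstitial_bin(self):
        flags = {("L", 0.18): True, ("L", 0.41): False}
        assert cgh.assign_bin("1D", flags) == "1DL-0.18-0.41"

    def test_non_monotone_pattern_unassigned(self):
        flags = {("L", 0.18): False, ("L", 0.41): True}
        assert cgh.assign_bin("1D", flags) == cgh.UNASSIGNED

    def test_no_flags_is_pericentromeric(self):
        flags = {("L", 0.18): False, ("S", 0.5): False}
        assert cgh.assign_bin("1D", flags) == cgh.PERICENTROMERIC

    def test_cross_arm_flags_unassigned(self):
        flags = {("L", 0.18): True, ("S", 0.5): True}
        assert cgh.assign_bin("1D", flags) == cgh.UNASSIGNED


class TestStringencyLadder:
    def _panel_and_tables(self, losses_by_line, p=1e-6):
        """Three-chromosome panel; losses given per line for one probe."""
        lines = [sd.Line("CTRL", "control")]
        for c in ("1D", "2D", "3D"):
            lines.append(sd.Line(f"N{c}", "nulli_tetrasomic", chromosome=c))
        lines.append(sd.Line("1DL-30", "deletion", "1D", "L", 0.3))
        lines.append(sd.Line("1DL-70", "deletion", "1D", "L", 0.7))
        panel = sd.LinePanel(lines)
        cols = [l.name for l in lines if l.kind != "control"]
        loss = pd.DataFrame([[losses_by_line.get(c, 0.0) for c in cols]],
                            index=["p1"], columns=cols)
        pv = pd.DataFrame([[p] * len(cols)], index=["p1"], columns=cols)
        return panel, loss, pv

    def test_strong_loss_assigned_at_level_050(self):
        panel, loss, pv = self._panel_and_tables(
            {"N1D": 0.6, "1DL-30": 0.6, "1DL-70": 0.6})
        a = cgh.stringency_ladder(loss, pv, panel)[0]
        assert a.chromosome == "1D"
        assert a.stringency_level == 0.5
        assert a.bin_label == "1DL-0.70-1.00"

    def test_weak_loss_needs_level_020(self):
        panel, loss, pv = self._panel_and_tables({"N1D": 0.25, "1DL-30": 0.25})
        a = cgh.stringency_ladder(loss, pv, panel)[0]
        assert a.chromosome == "1D"
        assert a.stringency_level == 0.2
        assert a.bin_label == "1DL-0.30-0.70"

    def test_two_line_loss_never_clean(self):
        panel, loss, pv = self._panel_and_tables({"N1D": 0.25, "N2D": 0.25})
        a = cgh.stringency_ladder(loss, pv, panel)[0]
        assert a.chromosome == cgh.UNASSIGNED

    def test_no_deletion_flags_infers_pericentromeric(self):
        panel, loss, pv = self._panel_and_tables({"N1D": 0.9})
        a = cgh.stringency_ladder(loss, pv, panel)[0]
        assert a.bin_label == cgh.PERICENTROMERIC

    def test_increasing_thresholds_rejected(self):
        panel, loss, pv = self._panel_and_tables({"N1D": 0.9})
        with pytest.raises(ValueError):
            cgh.stringency_ladder(loss, pv, panel, thresholds=(0.2, 0.5))


class TestMonotonicity:
    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 10_000))
    def test_flagged_sets_nest_across_thresholds(self, seed):
        """Raising stringency never gains flags (same alpha)."""
        rng = np.random.default_rng(seed)
        loss = rng.uniform(-0.5, 1.0, size=200)
        p = rng.uniform(0, 0.2, size=200)
        prev = None
        for t in (0.2, 0.3, 0.4, 0.5):
            flagged = {i for i in range(200) if loss[i] >= t and p[i] < 0.05}
            if prev is not None:
                assert flagged <= prev
            prev = flagged

    @settings(max_examples=10, deadline=None)
    @given(st.integers(0, 10_000))
    def test_ladder_flags_nest_on_simulated_matrices(self, seed):
        rng = np.random.default_rng(seed)
        cols = {}
        for line in ("CTRL", "N1D", "N2D"):
            for a in (1, 2):
                for s in (1, 2, 3):
                    mu = 1000 * rng.uniform(0.2, 1.0) if line != "CTRL" else 1000
                    cols[f"{line}.{a}.{s}.test"] = mu * rng.lognormal(0, 0.2, 30)
                    cols[f"{line}.{a}.{s}.ref"] = 1000 * rng.lognormal(0, 0.2, 30)
        mat = sd.SignalMatrix(pd.DataFrame(cols, index=[f"p{i}" for i in range(30)]))
        lines = [sd.Line("CTRL", "control"),
                 sd.Line("N1D", "nulli_tetrasomic", chromosome="1D"),
                 sd.Line("N2D", "nulli_tetrasomic", chromosome="2D")]
        panel = sd.LinePanel(lines)
        ratios = cgh.spot_ratios(mat, panel)
        loss, p = cgh.loss_table(ratios, panel)
        for line in ("N1D", "N2D"):
            prev = None
            for t in (0.2, 0.3, 0.4, 0.5):
                flagged = set(loss.index[(loss[line] >= t) & (p[line] < 0.05)])
                if prev is not None:
                    assert flagged <= prev
                prev = flagged


class TestScreenAndConcordance:
    def test_genome_specific_screen_noise_free(self, small_genome):
        panel = sd.build_line_panel(small_genome, alt_genome_name="AABB")
        probes = sd.probes_from_truth(small_genome, n_rjm=10, n_gene_probes=5, seed=4)
        model = sd.SignalModel(lognormal_sd=0.0, dropout_rate=0.0,
                               cross_hyb=0.9, seed=1)
        mat = sd.simulate_hybridization(panel, probes, small_genome, model)
        keep = cgh.screen_genome_specific(mat, panel, "AABB")
        for p in probes:
            # junction probes go to background (loss 1.0) -> kept;
            # gene probes keep 90% homeologous signal (loss ~0.1) -> dropped
            assert keep[p.id] == (p.probe_type == "rjm")

    def test_identical_signals_dropped(self, small_genome):
        panel = sd.build_line_panel(small_genome, alt_genome_name="AABB")
        probes = sd.probes_from_truth(small_genome, n_rjm=5, seed=4)
        model = sd.SignalModel(lognormal_sd=0.0, dropout_rate=0.0, seed=1)
        mat = sd.simulate_hybridization(panel, probes, small_genome, model)
        # overwrite the alt line's test channel with the control dosage
        for c in mat.data.columns:
            line, a, s, ch = sd.SignalMatrix.parse_column(c)
            if line == "AABB" and ch == "test":
                mat.data[c] = mat.data[sd.SignalMatrix.column_name("CTRL", a, s, ch)]
        keep = cgh.screen_genome_specific(mat, panel, "AABB")
        assert not keep.any()

    def test_concordance_arithmetic(self):
        a = {f"p{i}": "1D" for i in range(10)}
        b = dict(a)
        for i in range(5):
            b[f"p{i}"] = "2D"
        n, agree, pct = cgh.concordance(a, b)
        assert (n, agree, pct) == (10, 5, 50.0)
        assert cgh.concordance(a, a) == (10, 10, 100.0)

    def test_concordance_empty_intersection_is_nan(self):
        n, agree, pct = cgh.concordance({"p": cgh.UNASSIGNED}, {"p": "1D"})
        assert n == 0 and np.isnan(pct)


@pytest.fixture(scope="module")
def genome3(small_library):
    """Three chromosomes: per-line losses touch <= 1/3 of probes, so the
    column medians the normalization relies on stay anchored (as with the
    seven chromosomes of a real nulli panel)."""
    return sd.simulate_genome(
        small_library,
        [("1D", 50_000, 0.45), ("2D", 50_000, 0.5), ("3D", 50_000, 0.5)],
        te_count=24, nesting_prob=0.2, gene_count=24, seed=8,
    )


class TestRecovery:
    """Chromosome/bin recovery against simulation truth (small fixture)."""

    def test_zero_noise_recovery_is_exact(self, genome3):
        dels = {"1D": {"S": [0.5], "L": [0.3, 0.7]}, "2D": {"L": [0.4]}}
        panel = sd.build_line_panel(genome3, dels)
        probes = sd.probes_from_truth(genome3, seed=5)
        model = sd.SignalModel(lognormal_sd=0.0, dropout_rate=0.0, seed=2)
        mat = sd.simulate_hybridization(panel, probes, genome3, model)
        res = cgh.assign_probes(mat, panel)
        for p in probes:
            chrom, start = p.genome_coords[0]
            arm, fl = genome3.arm_position(chrom, start + 26)
            row = res.loc[p.id]
            assert row["chromosome"] == chrom
            if chrom in dels:
                assert row["bin"] == bm.true_bin_of(arm, fl, dels[chrom], chrom)
            else:
                # 3D has no deletion lines: nothing to assay, no inference
                assert row["bin"] == cgh.UNASSIGNED

    def test_accounting_identity_per_chromosome(self, genome3):
        dels = {"1D": {"L": [0.3, 0.7]}}
        panel = sd.build_line_panel(genome3, dels)
        probes = sd.probes_from_truth(genome3, seed=5)
        model = sd.SignalModel(seed=3)
        mat = sd.simulate_hybridization(panel, probes, genome3, model)
        res = cgh.assign_probes(mat, panel)
        assigned = res[res["chromosome"] != cgh.UNASSIGNED]
        for chrom, sub in assigned.groupby("chromosome"):
            n_bin = (sub["bin"].str.startswith(chrom)).sum()
            n_peri = (sub["bin"] == cgh.PERICENTROMERIC).sum()
            n_un = (sub["bin"] == cgh.UNASSIGNED).sum()
            assert n_bin + n_peri + n_un == len(sub)
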
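import numpy as np
import pandas as pd
import pytest

from idrcond import smt


def track_df(frames_by_track):
    rows = [
        {"track_id": tid, "frame": f, "x": 0.0, "y": 0.0, "intensity": 1.0}
        for tid, frames in frames_by_track.items()
        for f in frames
    ]
    return pd.DataFrame(rows)


class TestExtractDwells:
    def test_span_times_interval(self):
        sample = smt.extract_dwells(track_df({1: range(3, 14)}), 0.15)
        assert sample.dwells == pytest.approx([1.65])

    def test_single_frame_track_excluded(self):
        sample = smt.extract_dwells(track_df({1: [5], 2: [7, 8]}), 0.15)
        assert len(sample) == 1

    def test_gap_counts_toward_dwell(self):
        # blink across a 2-frame gap: molecule presumed bound throughout
        sample = smt.extract_dwells(track_df({1: [5, 6, 9]}), 0.15)
        assert sample.dwells == pytest.approx([0.75])

    def test_duplicate_rows_rejected(self):
        with pytest.raises(smt.DwellExtractionError, match="duplicate"):
            smt.extract_dwells(track_df({1: [5, 5, 6]}), 0.15)

    def test_oversized_gap_rejected(self):
        with pytest.raises(smt.DwellExtractionError, match="gap"):
            smt.extract_dwells(track_df({1: [1, 2, 7]}), 0.15)

    def test_tracker_dialect_csv(self, tmp_path):
        p = tmp_path / "tracks.csv"
        pd.DataFrame(
            {
                "TRACK_ID": [0, 0],
                "FRAME": [0, 1],
                "POSITION_X": [1.0, 1.1],
                "POSITION_Y": [2.0, 2.0],
                "MEAN_INTENSITY": [9.0, 9.5],
            }
        ).to_csv(p, index=False)
        df = smt.read_track_csv(p)
        assert {"track_id", "frame", "x", "y", "intensity"} <= set(df.columns)


class TestSurvivalCurve:
    def test_quartile_example(self):
        t, s = smt.survival_curve(np.array([1.0, 2.0, 3.0, 4.0]))
        # S is right-continuous complement: S(2) = P(d > 2) = 0.5
        assert s[np.searchsorted(t, 2.0)] == pytest.approx(0.5)

    def test_single_step(self):
        t, s = smt.survival_curve(np.array([2.0, 2.0, 2.0]))
        assert t.tolist() == [0.0, 2.0]
        assert s.tolist() == [1.0, 0.0]

    def test_monotone_bounds(self):
        rng = np.random.default_rng(0)
        d = rng.exponential(2.0, 500)
        t, s = smt.survival_curve(d)
        assert s[0] == 1.0 and s[-1] == 0.0
        assert np.all(np.diff(s) <= 0)

    def test_exponential_closed_form(self):
        rng = np.random.default_rng(1)
        d = rng.exponential(2.0, 100_000)
        t, s = smt.survival_curve(d)
        idx = np.searchsorted(t, 2.0)
        assert s[idx] == pytest.approx(np.exp(-1), abs=0.01)

    def test_empty_sample(self):
        with pytest.raises(ValueError):
            smt.survival_curve(np.array([]))


class TestFitBiexponential:
    def test_noiseless_recovery(self):
        t = np.arange(0.15, 30, 0.15)
        s = 0.5 * np.exp(-t) + 0.5 * np.exp(-t / 10)
        fit = smt.fit_biexponential(
            np.concatenate(([0.0], t)), np.concatenate(([1.0], s))
        )
        assert fit.A == pytest.approx(0.5, abs=1e-3)
        assert fit.tau_ns == pytest.approx(1.0, abs=1e-3)
        assert fit.tau_s == pytest.approx(10.0, abs=1e-3)

    def test_single_exponential_degenerate_flag(self):
        t = np.arange(0.15, 20, 0.15)
        s = np.exp(-t / 2)
        fit = smt.fit_biexponential(
            np.concatenate(([0.0], t)), np.concatenate(([1.0], s))
        )
        assert fit.degenerate
        assert fit.tau_ns == pytest.approx(2.0, rel=0.05)
        assert fit.tau_s == pytest.approx(2.0, rel=0.05)

    def test_label_order_resolved(self):
        t = np.arange(0.15, 30, 0.15)
        s = 0.3 * np.exp(-t / 8) + 0.7 * np.exp(-t / 1.5)
        fit = smt.fit_biexponential(
            np.concatenate(([0.0], t)), np.concatenate(([1.0], s))
        )
        assert fit.tau_ns < fit.tau_s
        assert fit.A == pytest.approx(0.7, abs=1e-3)

    def test_too_few_points(self):
        with pytest.raises(ValueError, match="6 distinct"):
            smt.fit_biexponential(np.array([0, 1, 2]), np.array([1, 0.5, 0.2]))

    def test_simulated_mixture_recovery(self):
        from idrcond import synth

        sample, _ = synth.sim_dwells(synth.DwellSimConfig(n=10_000, seed=3))
        fit = smt.fit_dwell_sample(sample)
        assert fit.tau_ns == pytest.approx(1.2, rel=0.15)
        assert fit.tau_s == pytest.approx(7.0, rel=0.15)


class TestBinFractions:
    def test_direct_count(self):
        fracs = smt.dwell_bin_fractions(np.array([0.5, 2.0, 8.0, 12.0]))
        assert fracs == pytest.approx(
            {"<1.2s": 0.25, ">=1.2s": 0.75, ">=7s": 0.5, ">=10s": 0.25}
        )

    def test_all_short(self):
        fracs = smt.dwell_bin_fractions(np.array([0.3, 0.3]))
        assert fracs == pytest.approx(
            {"<1.2s": 1.0, ">=1.2s": 0.0, ">=7s": 0.0, ">=10s": 0.0}
        )

    def test_partition_and_nesting(self):
        rng = np.random.default_rng(2)
        fracs = smt.dwell_bin_fractions(rng.exponential(3.0, 2000) + 0.15)
        assert fracs["<1.2s"] + fracs[">=1.2s"] == pytest.approx(1.0)
        assert fracs[">=1.2s"] >= fracs[">=7s"] >= fracs[">=10s"]

    def test_mixture_tail_matches_closed_form(self):
        from idrcond import synth

        cfg = synth.DwellSimConfig(n=200_000, seed=4)
        sample, _ = synth.sim_dwells(cfg)
        fracs = smt.dwell_bin_fractions(sample)
        expected = 0.7 * np.exp(-7 / 1.2) + 0.3 * np.exp(-1.0)
        assert fracs[">=7s"] == pytest.approx(expected, abs=0.005)


class TestFoldChange:
    def test_identical_arms(self):
        rng = np.random.default_rng(5)
        vals = rng.normal(0.2, 0.01, 6)
        out = smt.fold_change_stats({"b": vals}, {"b": vals.copy()})
        assert out.loc["b", "fold_change"] == pytest.approx(1.0)
        assert out.loc["b", "p_value"] == pytest.approx(1.0)

    def test_halved_bin(self):
        out = smt.fold_change_stats(
            {"b": np.array([0.1, 0.11, 0.09])}, {"b": np.array([0.2, 0.22, 0.18])}
        )
        assert out.loc["b", "fold_change"] == pytest.approx(0.5)

    def test_zero_control_flagged(self):
        out = smt.fold_change_stats(
            {"b": np.array([0.1, 0.1])}, {"b": np.array([0.0, 0.0])}
        )
        assert out.loc["b", "undefined"]

    def test_simulated_reduction_detected(self):
        from idrcond import synth

        ctrl, cond = [], []
        for e in range(4):
            c, _ = synth.sim_dwells(synth.DwellSimConfig(n=4000, A=0.7, seed=40 + e))
            p, _ = synth.sim_dwells(synth.DwellSimConfig(n=4000, A=0.85, seed=50 + e))
            ctrl.append(smt.dwell_bin_fractions(c)[">=10s"])
            cond.append(smt.dwell_bin_fractions(p)[">=10s"])
        out = smt.fold_change_stats(
            {">=10s": np.array(cond)}, {">=10s": np.array(ctrl)}
        )
        assert out.loc[">=10s", "fold_change"] == pytest.approx(0.5, abs=0.12)
        assert out.loc[">=10s", "p_value"] < 0.05


class TestExpressionGate:
    def test_corr_fix(self):
        gate = smt.expression_gate(
            np.linspace(1, 1000, 1000), np.array([200.0]), np.array([100.0])
        )
        assert gate.corr_fix == pytest.approx(2.0)

    def test_percentile_bounds(self):
        gate = smt.expression_gate(
            np.arange(1.0, 1001.0), np.array([1.0]), np.array([1.0])
        )
        assert gate.lower == pytest.approx(10.99)
        assert gate.upper == pytest.approx(990.01)

    def test_exact_bound_excluded(self):
        gate = smt.ExpressionGate(10.0, 100.0, 1.0)
        keep = smt.apply_gate(np.array([10.0, 50.0, 100.0]), gate)
        assert keep.tolist() == [False, True, False]

    def test_fixed_intensities_rescaled(self):
        gate = smt.ExpressionGate(100.0, 400.0, 2.0)
        # fixed-scale 75 -> live 150, inside; fixed 250 -> live 500, outside
        keep = smt.apply_gate(np.array([75.0, 250.0]), gate, fixed=True)
        assert keep.tolist() == [True, False]

    def test_small_sample_warns(self):
        with pytest.warns(UserWarning, match="nuclei"):
            smt.expression_gate(np.arange(10.0), np.array([1.0]), np.array([1.0]))
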
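import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from idrcond import grammar
from idrcond.seqio import DEFAULT_GROUPS


def brute_force_delta(seq, set_x, set_y, windows):
    """Independent loop-based oracle for the patterning statistic."""
    n = len(seq)
    fx_all = sum(a in set_x for a in seq) / n
    fy_all = sum(a in set_y for a in seq) / n
    sigma_bar = (
        (fx_all - fy_all) ** 2 / (fx_all + fy_all) if fx_all + fy_all > 0 else 0.0
    )
    deltas = []
    for g in windows:
        sigmas = []
        for i in range(n - g + 1):
            win = seq[i : i + g]
            fx = sum(a in set_x for a in win) / g
            fy = sum(a in set_y for a in win) / g
            sigmas.append((fx - fy) ** 2 / (fx + fy) if fx + fy > 0 else 0.0)
        deltas.append(np.mean([(s - sigma_bar) ** 2 for s in sigmas]))
    return float(np.mean(deltas))


NEG, POS = DEFAULT_GROUPS["neg"], DEFAULT_GROUPS["pos"]


class TestChargeProfile:
    @pytest.mark.parametrize(
        "seq,window,expected",
        [
            ("KKKKK", 5, [1, 1, 1, 1, 1]),
            ("GGGGG", 5, [0, 0, 0, 0, 0]),
            ("KKGEE", 3, [2 / 3, 1 / 3, 0.0, -1 / 3, -2 / 3]),
        ],
    )
    def test_examples(self, seq, window, expected):
        assert grammar.charge_profile(seq, window) == pytest.approx(expected)

    def test_window_equal_length_gives_ncpr(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            seq = "".join(rng.choice(list("EKGSQ"), size=20))
            prof = grammar.charge_profile(seq, 20)
            ncpr = grammar.composition_features(seq)["NCPR"]
            assert prof == pytest.approx(np.full(20, ncpr))

    def test_too_short_sequence(self):
        with pytest.raises(ValueError):
            grammar.charge_profile("KK", 3)

    def test_values_bounded(self):
        rng = np.random.default_rng(1)
        seq = "".join(rng.choice(list("EKDRGS"), size=60))
        prof = grammar.charge_profile(seq, 5)
        assert np.all(prof >= -1) and np.all(prof <= 1)


class TestComposition:
    def test_symmetric_charges(self):
        feats = grammar.composition_features("EEKK")
        assert feats["NCPR"] == pytest.approx(0.0)
        assert feats["FCR"] == pytest.approx(1.0)

    def test_homopolymer(self):
        feats = grammar.composition_features("EEEE")
        assert feats["frac_E"] == 1.0
        assert feats["NCPR"] == -1.0

    def test_counts(self):
        feats = grammar.composition_features("DEKRST")
        assert feats["FCR"] == pytest.approx(4 / 6)
        assert sum(feats[f"frac_{a}"] for a in grammar.AA_ORDER) == pytest.approx(1.0)

    @settings(max_examples=30, deadline=None)
    @given(st.text(alphabet="EKGSQPDR", min_size=6, max_size=40), st.randoms())
    def test_permutation_invariant(self, seq, rnd):
        shuffled = "".join(rnd.sample(seq, len(seq)))
        assert grammar.composition_features(seq) == pytest.approx(
            grammar.composition_features(shuffled)
        )


class TestPatterningDelta:
    @pytest.mark.parametrize(
        "seq,windows,expected",
        [
            ("EEEEKKKK", (5,), 0.0656),
            ("EKEKEKEK", (5, 6), 0.0008),
            ("EEEEKKKK", (5, 6), 0.03691523),
        ],
    )
    def test_frozen_examples(self, seq, windows, expected):
        assert grammar.patterning_delta(seq, "neg", "pos", windows) == pytest.approx(
            expected, abs=1e-6
        )

    def test_matches_brute_force_on_random_sequences(self):
        rng = np.random.default_rng(2)
        for _ in range(25):
            seq = "".join(rng.choice(list("EKGSD"), size=int(rng.integers(8, 40))))
            got = grammar.patterning_delta(seq, "neg", "pos")
            assert got == pytest.approx(
                brute_force_delta(seq, NEG, POS, (5, 6)), abs=1e-12
            )

    def test_blocky_at_least_alternating_exhaustive(self):
        # across every arrangement of small fixed compositions, the
        # contiguous-blocks layout always beats the maximally alternating
        # one; for pure two-group compositions it is the global maximum
        for n_e, n_k, n_g in [(3, 3, 2), (4, 4, 0), (2, 3, 3), (5, 5, 0)]:
            pool = "E" * n_e + "K" * n_k + "G" * n_g
            deltas = {
                arr: grammar.patterning_delta("".join(arr), "neg", "pos", (5,))
                for arr in set(itertools.permutations(pool))
            }
            blocky = tuple("E" * n_e + "K" * n_k + "G" * n_g)
            alternating = tuple(
                [a for pair in zip("E" * n_e, "K" * n_k) for a in pair]
                + list("E" * (n_e - min(n_e, n_k)) + "K" * (n_k - min(n_e, n_k)))
                + list("G" * n_g)
            )
            assert deltas[blocky] >= deltas[alternating]
            if n_g == 0:
                assert deltas[blocky] == pytest.approx(max(deltas.values()))

    def test_not_permutation_invariant(self):
        assert grammar.patterning_delta("EEEEKKKK") != pytest.approx(
            grammar.patterning_delta("EKEKEKEK")
        )

    def test_no_group_residues_raises(self):
        with pytest.raises(grammar.UndefinedStatisticError):
            grammar.patterning_delta("GGGGGGGG", "neg", "pos")

    def test_segregation_against_complement(self):
        # Y=None scores X against everything else
        d = grammar.patterning_delta("EEEEGGGG", "neg", None, (5,))
        assert d == pytest.approx(
            brute_force_delta("EEEEGGGG", NEG, set("ACDFGHIKLMNPQRSTVWY") - NEG, (5,))
        )


class TestPatterningZscore:
    def test_homopolymer_degenerate(self):
        stat = grammar.patterning_zscore("K" * 20, "neg", "pos", 500, seed=0)
        assert stat.degenerate and stat.z == 0.0

    def test_blocky_above_null(self):
        stat = grammar.patterning_zscore(
            "EEEEEKKKKK" + "G" * 20, "neg", "pos", 10_000, seed=0
        )
        assert stat.z > 2

    def test_alternating_below_null(self):
        stat = grammar.patterning_zscore("EK" * 20, "neg", "pos", 10_000, seed=0)
        assert stat.z < 0

    def test_deterministic_given_seed(self):
        a = grammar.patterning_zscore("EEKKGG" * 5, seed=7, n_shuffles=500)
        b = grammar.patterning_zscore("EEKKGG" * 5, seed=7, n_shuffles=500)
        assert a.z == b.z

    def test_shuffled_sequences_center_on_null(self):
        # the z of freshly shuffled sequences averages ~0
        rng = np.random.default_rng(3)
        base = list("EEEEEKKKKK" + "G" * 10)
        zs = []
        for _ in range(200):
            rng.shuffle(base)
            zs.append(
                grammar.patterning_zscore("".join(base), n_shuffles=400, seed=5).z
            )
        assert abs(np.mean(zs)) < 0.2


class TestBackground:
    def test_query_at_mean_gives_zero(self):
        bg = grammar.build_background(["EEKKGGSS", "EEKKGGSS", "EKGS" * 2])
        z, _ = grammar.composition_zscores("EEKKGGSS", bg)
        # query equal to two of three background members sits near the mean
        feats = grammar.composition_features("EEKKGGSS")
        mean_match = {k: v for k, v in feats.items() if v == bg.mean[k]}
        for k in mean_match:
            if bg.sd[k] > 0:
                assert z[k] == pytest.approx(0.0)

    def test_identical_background_degenerate(self):
        bg = grammar.build_background(["EEKK", "EEKK"])
        z, degen = grammar.composition_zscores("EKGS", bg)
        assert all(degen.values())
        assert all(v == 0.0 for v in z.values())

    def test_synthetic_normal_background_recovers_z(self):
        rng = np.random.default_rng(4)
        seqs = []
        for _ in range(500):
            frac = np.clip(rng.normal(0.05, 0.01), 0, 0.5)
            n_e = int(round(1000 * frac))
            seqs.append("E" * n_e + "G" * (1000 - n_e))
        bg = grammar.build_background(seqs)
        z, _ = grammar.composition_zscores("E" * 70 + "G" * 930, bg)
        assert z["frac_E"] == pytest.approx(2.0, abs=0.2)

    def test_empty_background_rejected(self):
        with pytest.raises(ValueError):
            grammar.build_background([])


@pytest.fixture(scope="module")
def background():
    from idrcond import synth

    return grammar.build_background(synth.sim_idrome(n=100, seed=11))


class TestGrammarReport:

    def test_blocky_toy_masks_neg_segregation(self, background):
        rep = grammar.grammar_report(
            "E" * 12 + "G" * 20 + "E" * 12 + "K" * 8,
            background,
            n_shuffles=500,
            seed=0,
        )
        assert rep.display_mask["patt_neg_vs_other"]
        assert rep.patterning_z["patt_neg_vs_other"] > 1

    def test_all_gly_idr_degenerate_patterning(self, background):
        rep = grammar.grammar_report("G" * 40, background, n_shuffles=500, seed=0)
        assert rep.composition_z["frac_E"] <= 0
        assert rep.degenerate["patt_pos_vs_neg"]

    def test_shuffle_keeps_composition_changes_patterning(self, background):
        seq = "EEEEEKKKKK" + "GS" * 10
        rng = np.random.default_rng(5)
        shuffled = "".join(rng.permutation(list(seq)))
        rep_a = grammar.grammar_report(seq, background, n_shuffles=500, seed=0)
        rep_b = grammar.grammar_report(shuffled, background, n_shuffles=500, seed=0)
        assert rep_a.composition_z == pytest.approx(rep_b.composition_z)
        assert rep_a.patterning_z != pytest.approx(rep_b.patterning_z)

    def test_display_mask_definition_and_json(self, background):
        rep = grammar.grammar_report("EEKKGS" * 6, background, n_shuffles=500, seed=0)
        for k, v in rep.all_z.items():
            assert rep.display_mask[k] == (abs(v) >= 1)
        assert "composition_z" in rep.to_json()
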
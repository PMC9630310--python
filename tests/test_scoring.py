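"""CFD/MIT/specificity formulas, rank composites, CFD-CasRx estimation."""

import numpy as np
import pandas as pd
import pytest

import crisprkit as ck
from crisprkit import fixtures as fx
from crisprkit.offtargets import AlignmentHit
from crisprkit.scoring import MismatchWeightTable, MitWeights


def _hit(mismatches, pam="AGG"):
    return AlignmentHit(
        guide_id="g", subject_id="s", pam_coordinate=0, strand="+",
        n_mismatches=len(mismatches), mismatch_positions=tuple(mismatches),
        pam_observed=pam, canonical_pam=True,
    )


@pytest.fixture
def table():
    return MismatchWeightTable(
        w={(5, "A", "C"): 0.5, (10, "G", "T"): 0.4, (12, "A", "G"): 0.9},
        L=20,
    )


class TestCfd:
    def test_perfect_match_is_one(self, table):
        assert ck.cfd_score(_hit([]), table) == 1.0

    def test_product_over_mismatches(self, table):
        hit = _hit([(5, "A", "C"), (10, "G", "T")])
        assert ck.cfd_score(hit, table) == pytest.approx(0.2)

    def test_additional_mismatch_strictly_decreases(self, table):
        one = ck.cfd_score(_hit([(5, "A", "C")]), table)
        two = ck.cfd_score(_hit([(5, "A", "C"), (12, "A", "G")]), table)
        assert two < one

    def test_missing_entry_names_the_triple(self, table):
        with pytest.raises(KeyError, match=r"p=7.*RNA=A.*DNA=T"):
            ck.cfd_score(_hit([(7, "A", "T")]), table)

    def test_pam_weight_factor_applied(self):
        t = MismatchWeightTable(w={}, L=20, pam_weights={"AGG": 1.0, "AAG": 0.25})
        assert ck.cfd_score(_hit([], pam="AAG"), t) == 0.25

    def test_position_beyond_table_rejected(self, table):
        with pytest.raises(ValueError, match="beyond"):
            ck.cfd_score(_hit([(21, "A", "C")]), table)


class TestMit:
    @pytest.fixture
    def weights(self):
        return MitWeights(c={p: w for p, w in zip(range(1, 20),
                          [0.8, 0.5, 0.9, 0.7, 0.8, 0.5, 0.6, 0.9, 0.4, 0.5,
                           0.8, 0.7, 0.6, 0.5, 0.9, 0.8, 0.7, 0.6, 0.5])}, L=19)

    def test_perfect_match_is_one(self, weights):
        assert ck.mit_score(_hit([]), weights) == 1.0

    def test_two_mismatch_hand_value(self):
        # c5=0.8, c10=0.5, L=19, mismatches at 5 and 10: d=5,
        # score = 0.4 * 1/((14/19)*4 + 1) * 1/4
        weights = MitWeights(c={5: 0.8, 10: 0.5}, L=19)
        hit = _hit([(5, "A", "C"), (10, "G", "T")])
        expected = 0.4 * (1.0 / ((14 / 19) * 4 + 1)) / 4
        assert ck.mit_score(hit, weights) == pytest.approx(expected)

    def test_single_mismatch_distance_factor_is_one(self, weights):
        assert ck.mit_score(_hit([(3, "A", "C")]), weights) == pytest.approx(0.9)

    def test_nonincreasing_in_mismatch_count(self, weights):
        rng = np.random.default_rng(1)
        prev = 1.0
        positions = []
        for p in [2, 7, 13, 18]:
            positions.append((p, "A", "C"))
            score = ck.mit_score(_hit(list(positions)), weights)
            assert score <= prev + 1e-12
            prev = score


class TestSpecificity:
    def test_no_offtargets_scores_one(self):
        assert ck.specificity_score([]) == 1.0

    def test_one_additional_perfect_match_scores_half(self):
        assert ck.specificity_score([1.0]) == 0.5

    def test_quarter_cutting_likelihood(self):
        assert ck.specificity_score([0.25]) == pytest.approx(0.8)

    def test_appending_positive_scores_strictly_decreases(self):
        scores = []
        prev = 1.0
        for c in [0.1, 0.5, 1.0, 0.3]:
            scores.append(c)
            now = ck.specificity_score(scores)
            assert now < prev
            prev = now

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            ck.specificity_score([1.2])


class TestComposite:
    def test_two_method_hand_example(self):
        df = pd.DataFrame({"A": [0.9, 0.5, 0.1], "B": [0.2, 0.8, 0.5]},
                          index=["g1", "g2", "g3"])
        s = ck.composite_on_target(df, ["A", "B"])
        assert list(s) == pytest.approx([2.0, 2.5, 1.5])

    def test_single_method_is_monotone(self):
        df = pd.DataFrame({"A": [0.3, 0.9, 0.1, 0.5]})
        s = ck.composite_on_target(df, ["A"])
        assert (s.sort_values().index == df["A"].sort_values().index).all()

    def test_duplicated_column_equals_single(self):
        df = pd.DataFrame({"A": [0.3, 0.9, 0.1], "B": [0.3, 0.9, 0.1]})
        assert (ck.composite_on_target(df, ["A", "B"])
                == ck.composite_on_target(df, ["A"])).all()

    def test_permutation_invariance(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame({"A": rng.random(10), "B": rng.random(10)},
                          index=[f"g{i}" for i in range(10)])
        s1 = ck.composite_on_target(df, ["A", "B"])
        perm = df.sample(frac=1, random_state=1)
        s2 = ck.composite_on_target(perm, ["A", "B"])
        assert (s1.sort_index() == s2.sort_index()).all()

    def test_missing_values_rescaled(self):
        # method B scores only 2 of 4 guides; its top rank must be scaled up
        # to the top rank of the full method
        df = pd.DataFrame({"A": [0.1, 0.2, 0.3, 0.4],
                           "B": [np.nan, np.nan, 0.5, 0.9]})
        s = ck.composite_on_target(df, ["A", "B"])
        assert s[3] == pytest.approx((4 + 4) / 2)
        assert s[2] == pytest.approx((3 + 2) / 2)

    def test_all_missing_column_dropped_with_warning(self):
        df = pd.DataFrame({"A": [0.1, 0.2], "B": [np.nan, np.nan]})
        with pytest.warns(UserWarning, match="dropped"):
            s = ck.composite_on_target(df, ["A", "B"])
        assert list(s) == [1.0, 2.0]


class TestFrameshift:
    def test_uniform_lengths_give_two_thirds(self):
        dist = {k: 1 / 30 for k in range(1, 31)}
        assert ck.frameshift_proportion(dist) == pytest.approx(20 / 30)

    def test_inframe_only_gives_zero(self):
        assert ck.frameshift_proportion({3: 0.5, -6: 0.5}) == 0.0

    def test_half_and_half(self):
        assert ck.frameshift_proportion({1: 0.5, 3: 0.5}) == 0.5

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError):
            ck.frameshift_proportion({0: 1.0})

    def test_unnormalised_rejected(self):
        with pytest.raises(ValueError):
            ck.frameshift_proportion({1: 0.4})


class TestCasrxWeights:
    def test_zero_delta_gives_unit_weights(self):
        df = pd.DataFrame({"position": list(range(1, 24)) * 3,
                           "delta_lfc": 0.0})
        w = ck.estimate_casrx_mismatch_weights(df, pm_median_lfc=2.0)
        assert all(v == pytest.approx(1.0, abs=1e-9) for v in w.values())

    def test_total_loss_gives_zero_weights(self):
        df = pd.DataFrame({"position": list(range(1, 24)) * 3,
                           "delta_lfc": -2.0})
        w = ck.estimate_casrx_mismatch_weights(df, pm_median_lfc=2.0)
        assert all(v == pytest.approx(0.0, abs=1e-9) for v in w.values())

    def test_recovers_planted_profile(self):
        screen = fx.make_screen_table(seed=101, n_sm=500)
        w = ck.estimate_casrx_mismatch_weights(
            screen.sm_delta_table(), screen.pm_median_lfc
        )
        for p, truth in screen.true_weights.items():
            assert w[p] == pytest.approx(truth, abs=0.05)

    def test_noiseless_recovery_within_smoothing_bias(self):
        screen = fx.make_screen_table(seed=55, n_sm=800, noise_sd=0.0,
                                      pm_lfc_sd=0.0)
        w = ck.estimate_casrx_mismatch_weights(
            screen.sm_delta_table(), screen.pm_median_lfc
        )
        for p, truth in screen.true_weights.items():
            assert w[p] == pytest.approx(truth, abs=0.02)

    def test_nonfinite_rows_dropped_with_warning(self):
        df = pd.DataFrame({"position": [1, 2, 3, 4, 5, 6],
                           "delta_lfc": [0, 0, np.nan, 0, 0, 0]})
        with pytest.warns(UserWarning, match="non-finite"):
            ck.estimate_casrx_mismatch_weights(df, pm_median_lfc=1.0)

    def test_requires_two_positions(self):
        df = pd.DataFrame({"position": [5, 5], "delta_lfc": [0.0, 0.1]})
        with pytest.raises(ValueError, match="distinct"):
            ck.estimate_casrx_mismatch_weights(df, pm_median_lfc=1.0)


class TestPredictLfc:
    def test_no_mismatch_unchanged(self):
        assert ck.predict_mismatch_lfc(2.0, {1: 0.5}, []) == 2.0

    def test_single_mismatch(self):
        assert ck.predict_mismatch_lfc(2.0, {3: 0.5}, [3]) == 1.0

    def test_double_equals_product_of_singles_over_pm(self):
        w = {3: 0.5, 7: 0.8}
        pm = 2.0
        dm = ck.predict_mismatch_lfc(pm, w, [3, 7])
        s1 = ck.predict_mismatch_lfc(pm, w, [3])
        s2 = ck.predict_mismatch_lfc(pm, w, [7])
        assert dm == pytest.approx(s1 * s2 / pm)

    def test_unknown_position_named(self):
        with pytest.raises(KeyError, match="9"):
            ck.predict_mismatch_lfc(1.0, {1: 0.5}, [9])
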
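import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from phosforest.features import (
    FeatureSchema,
    ach_features,
    asa_features,
    ctd_encode,
    ctd_features,
    encode,
    family_lengths,
    information_gain,
    overlapping_properties,
    pseudo_accessibility,
    qso_features,
    relative_entropy,
    sequence_features,
    shannon_entropy,
    socn_features,
)

AA20 = "ACDEFGHIKLMNPQRSTVWY"
windows9 = st.text(alphabet=AA20, min_size=9, max_size=9)


class TestSchema:
    def test_window9_block_ranges_and_total(self):
        s = FeatureSchema.for_window(9)
        assert s.total_length == 593
        assert dict((f, (a, b)) for f, a, b in s.blocks) == {
            "H": (1, 1), "RE": (2, 2), "IG": (3, 3), "ASA": (4, 12),
            "OP": (13, 102), "ACH": (103, 106), "SF": (107, 286),
            "CTD": (287, 433), "SOCN": (434, 493), "QSO": (494, 593),
        }

    @pytest.mark.parametrize("w", [5, 7, 9, 11, 15, 21])
    def test_blocks_contiguous_cover_everything(self, w):
        s = FeatureSchema.for_window(w)
        prev = 0
        for _, start, stop in s.blocks:
            assert start == prev + 1 and stop >= start
            prev = stop
        assert prev == s.total_length == len(s.names)

    def test_names_follow_global_indices(self):
        s = FeatureSchema.for_window(9)
        assert s.names[0] == "H_1"
        assert s.names[568] == "QSO_569"
        assert s.names[-1] == "QSO_593"

    def test_even_or_tiny_window_rejected(self):
        with pytest.raises(ValueError):
            FeatureSchema.for_window(8)
        with pytest.raises(ValueError):
            FeatureSchema.for_window(1)

    def test_json_round_trip(self, tmp_path):
        import json

        s = FeatureSchema.for_window(7)
        s.to_json(tmp_path / "schema.json")
        loaded = FeatureSchema.from_dict(json.loads((tmp_path / "schema.json").read_text()))
        assert loaded == s


class TestEntropyFamily:
    def test_single_residue_type_entropy_zero(self):
        assert shannon_entropy("S" * 9) == 0.0

    def test_nine_distinct_residues_reach_the_maximum(self):
        assert round(shannon_entropy("ACDEFGHIK"), 2) == 3.17

    def test_placeholder_excluded_from_probabilities(self):
        expected = -(0.8 * math.log2(0.8) + 0.2 * math.log2(0.2))
        assert shannon_entropy("AAAASXXXX") == pytest.approx(expected)

    def test_relative_entropy_zero_iff_uniform(self):
        assert relative_entropy("ACDEFGHIK", 9) == pytest.approx(0.0)

    def test_relative_entropy_single_type(self):
        assert relative_entropy("S" * 9, 9) == pytest.approx(math.log2(9))

    def test_relative_entropy_two_types(self):
        expected = (5 / 9) * math.log2(5) + (4 / 9) * math.log2(4)
        assert relative_entropy("AAAAASSSS", 9) == pytest.approx(expected)

    def test_all_placeholder_window_is_zero_with_warning(self):
        with pytest.warns(UserWarning):
            assert shannon_entropy("X" * 9) == 0.0

    @given(windows9)
    def test_ig_is_h_minus_re_and_h_bounded(self, win):
        h = shannon_entropy(win)
        assert information_gain(win, 9) == pytest.approx(h - relative_entropy(win, 9))
        assert 0.0 <= h <= math.log2(9) + 1e-12

    @given(windows9, st.randoms(use_true_random=False))
    def test_composition_metrics_permutation_invariant(self, win, rnd):
        shuffled = list(win)
        rnd.shuffle(shuffled)
        shuffled = "".join(shuffled)
        assert shannon_entropy(shuffled) == pytest.approx(shannon_entropy(win))
        assert relative_entropy(shuffled, 9) == pytest.approx(relative_entropy(win, 9))
        np.testing.assert_allclose(ctd_features(shuffled)[:3], ctd_features(win)[:3])


class TestBitEncodings:
    def test_histidine_overlapping_code(self):
        assert "".join(str(int(b)) for b in overlapping_properties("H")) == "1101101000"

    def test_proline_overlapping_code(self):
        assert "".join(str(int(b)) for b in overlapping_properties("P")) == "0000000101"

    def test_lengths_at_window9(self):
        win = "KAGVSPHED"
        assert len(overlapping_properties(win)) == 90
        assert len(sequence_features(win)) == 180

    def test_placeholder_is_all_zero(self):
        assert not overlapping_properties("X").any()
        assert not sequence_features("X").any()

    @given(windows9)
    def test_one_hot_blocks_sum_to_one(self, win):
        sf = sequence_features(win).reshape(9, 20)
        assert (sf.sum(axis=1) == 1).all()

    def test_alanine_sets_first_bit_of_its_block(self):
        assert sequence_features("A")[0] == 1.0 and sequence_features("A")[1:].sum() == 0


class TestAch:
    def test_window9_yields_four_features(self):
        assert len(ach_features("KAGVSPHED")) == 4

    def test_innermost_subwindow_vsp(self):
        # V + S + P Eisenberg: (1.08 - 0.18 + 0.12) / 3
        assert ach_features("KAGVSPHED")[0] == pytest.approx(0.34)

    def test_all_placeholder_subwindow_is_zero(self):
        assert ach_features("XXXXXXXXX")[0] == 0.0

    def test_ordered_smallest_subwindow_first(self):
        vals = ach_features("KAGVSPHED")
        full = sum({"K": -1.5, "A": 0.62, "G": 0.48, "V": 1.08, "S": -0.18,
                    "P": 0.12, "H": -0.4, "E": -0.74, "D": -0.9}.values()) / 9
        assert vals[-1] == pytest.approx(full)


class TestCtd:
    def test_hydrophobicity_encoding_worked_example(self):
        assert ctd_encode("MVKELRTA") == "33113122"

    def test_composition_of_group3(self):
        vec = ctd_features("MVKELRTA")
        assert vec[2] == pytest.approx(3 / 8)  # three '3' codes of eight

    def test_transition_1_3(self):
        vec = ctd_features("MVKELRTA")
        assert vec[4] == pytest.approx(3 / 7)  # 31,13,31 among 7 adjacent pairs

    def test_distribution_of_group3(self):
        # '3' occurs at stripped positions 1,2,5 of 8
        vec = ctd_features("MVKELRTA")
        d3 = vec[6 + 10 : 6 + 15]
        np.testing.assert_allclose(d3, [1 / 8 * 100, 1 / 8 * 100, 2 / 8 * 100,
                                        5 / 8 * 100, 5 / 8 * 100])

    def test_length_147(self):
        assert len(ctd_features("KAGVSPHED")) == 147

    @given(windows9)
    def test_composition_blocks_sum_to_one_without_placeholders(self, win):
        vec = ctd_features(win)
        for p in range(7):
            assert vec[21 * p : 21 * p + 3].sum() == pytest.approx(1.0)


class TestSequenceOrder:
    def test_socn_has_60_values_and_zero_beyond_window(self):
        tau = socn_features("KAGVSPHED")
        assert len(tau) == 60
        assert (tau[8:30] == 0).all() and (tau[38:60] == 0).all()

    def test_identical_residues_give_zero_coupling(self):
        assert not socn_features("AAAAAAAAA").any()

    def test_two_residue_toy_window_single_term(self):
        from phosforest._scales import AA_TO_INDEX, DISTANCE_MATRICES

        tau = socn_features("KD" + "X" * 7)
        d = DISTANCE_MATRICES[0][1][AA_TO_INDEX["K"], AA_TO_INDEX["D"]]
        assert tau[0] == pytest.approx(d**2)

    def test_qso_has_100_values(self):
        assert len(qso_features("KAGVSPHED")) == 100

    def test_qso_identical_residues_reduce_to_frequency(self):
        q = qso_features("SSSSSSSSS")
        assert q[AA20.index("S")] == pytest.approx(1.0)
        assert q.sum() == pytest.approx(1.0)

    @given(windows9)
    def test_qso_nonnegative_and_frequency_block_bounded(self, win):
        q = qso_features(win)
        assert (q >= 0).all()
        assert q[:20].sum() <= 1.0 + 1e-12

    def test_order_sensitivity(self):
        # a permutation changes tau_1 while composition metrics do not
        a, b = "AKAKAKAKA", "AAAAKKKKA"
        assert socn_features(a)[0] != pytest.approx(socn_features(b)[0])


class TestAsa:
    def test_profile_slicing_interior(self):
        profile = list(np.arange(1.0, 21.0))
        vals = asa_features("KAGVSPHED", profile, center_position=10)
        np.testing.assert_allclose(vals, np.arange(6.0, 15.0))

    def test_terminal_window_pads_zero(self):
        profile = [1.0] * 20
        vals = asa_features("XXSAAAAAA", profile, center_position=3)
        assert (vals[:2] == 0).all() and (vals[2:] == 1).all()

    def test_fallback_is_deterministic(self):
        a = asa_features("KAGVSPHED")
        b = asa_features("KAGVSPHED")
        np.testing.assert_array_equal(a, b)
        assert (a >= 0).all()

    def test_pseudo_accessibility_prefers_hydrophilic(self):
        vals = pseudo_accessibility("RRRRRRIIIIII")
        assert vals[:3].mean() > vals[-3:].mean()


class TestEncode:
    def test_window9_full_vector(self):
        vec = encode("KAGVSPHED")
        assert len(vec.values) == 593

    def test_leading_entries_match_standalone_functions(self):
        win = "KAGVSPHED"
        vec = encode(win).values
        assert vec[0] == pytest.approx(shannon_entropy(win))
        assert vec[1] == pytest.approx(relative_entropy(win, 9))
        assert vec[2] == pytest.approx(information_gain(win, 9))

    def test_deterministic_for_identical_inputs(self):
        np.testing.assert_array_equal(encode("KAGVSPHED").values, encode("KAGVSPHED").values)

    @pytest.mark.parametrize("w", [5, 7, 9, 11])
    def test_family_lengths_recomputed_per_window_size(self, w):
        lengths = family_lengths(w)
        assert lengths["OP"] == 10 * w and lengths["SF"] == 20 * w
        assert lengths["ACH"] == (w - 1) // 2
        vec = encode("A" * ((w - 1) // 2) + "S" + "A" * ((w - 1) // 2))
        assert len(vec.values) == sum(lengths.values())

    @given(st.text(alphabet=AA20 + "X", min_size=9, max_size=9))
    def test_total_on_any_sanitized_window(self, win):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            vec = encode(win)
        assert np.isfinite(vec.values).all()
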
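import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mixtox import featurize as fz

smiles_like = st.text(alphabet="CNO()=#.123", min_size=1, max_size=30)


class TestConcatenation:
    def test_period_separator(self):
        assert fz.concat_mixture_smiles("C=CC#N", "CCO") == "C=CC#N.CCO"

    def test_order_sensitive(self):
        assert fz.concat_mixture_smiles("CCO", "C=CC#N") != fz.concat_mixture_smiles(
            "C=CC#N", "CCO"
        )

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            fz.concat_mixture_smiles("", "C")

    def test_component_order_normalization_swaps_payloads(self):
        id1, id2, (s1, s2) = fz.normalize_component_order(
            "zeta", "alpha", ("smiZ", "smiA")
        )
        assert (id1, id2) == ("alpha", "zeta")
        assert (s1, s2) == ("smiA", "smiZ")


class TestVocabulary:
    def test_first_appearance_order(self):
        v = fz.build_vocabulary(["C=CC#N"])
        assert v.char_to_index == {"C": 1, "=": 2, "#": 3, "N": 4}

    def test_single_char_corpus(self):
        assert fz.build_vocabulary(["C"]).char_to_index == {"C": 1}

    def test_order_continues_across_strings(self):
        v = fz.build_vocabulary(["C=CC#N", "(N)"])
        assert v.char_to_index["("] == 5 and v.char_to_index[")"] == 6

    @settings(derandomize=True, max_examples=30)
    @given(st.lists(smiles_like, min_size=1, max_size=10))
    def test_deterministic(self, corpus):
        assert (
            fz.build_vocabulary(corpus).char_to_index
            == fz.build_vocabulary(corpus).char_to_index
        )

    def test_json_round_trip(self):
        v = fz.build_vocabulary(["C=CC#N."])
        assert fz.SmilesVocabulary.from_json(v.to_json()).char_to_index == \
            v.char_to_index


class TestOneHot:
    def test_row_per_character(self):
        v = fz.build_vocabulary(["C=CC#N"])
        t = fz.one_hot_encode(["C=CC#N"], v)
        assert t.data.shape == (1, 6, 4)
        assert t.data[0, 0, 0] == 1  # 'C' -> index 1
        assert t.data[0, 1, 1] == 1  # '=' -> index 2
        assert t.data.sum() == 6

    def test_padding_rows_are_zero_and_decode_round_trips(self):
        v = fz.build_vocabulary(["CCO"])
        t = fz.one_hot_encode(["CCO"], v, L=5)
        assert t.data[0, 3:].sum() == 0
        assert t.decode() == ["CCO"]

    def test_row_sums_equal_lengths(self):
        strings = ["C", "CC", "CCO"]
        v = fz.build_vocabulary(strings)
        t = fz.one_hot_encode(strings, v)
        assert np.array_equal(t.data.sum(axis=(1, 2)), t.lengths)

    def test_out_of_vocabulary_names_character_and_position(self):
        v = fz.build_vocabulary(["CC"])
        with pytest.raises(ValueError, match=r"'O' at position 1"):
            fz.one_hot_encode(["CO"], v)

    def test_too_long_rejected(self):
        v = fz.build_vocabulary(["CCCC"])
        with pytest.raises(ValueError, match="exceeds"):
            fz.one_hot_encode(["CCCC"], v, L=3)

    @settings(derandomize=True, max_examples=30)
    @given(st.lists(smiles_like, min_size=1, max_size=20))
    def test_encode_decode_identity(self, strings):
        v = fz.build_vocabulary(strings)
        t = fz.one_hot_encode(strings, v)
        assert t.decode() == strings

    def test_persistence_round_trip(self, tmp_path):
        strings = ["C=CC#N", "CCO"]
        t = fz.one_hot_encode(strings, fz.build_vocabulary(strings), L=10)
        fz.save_tensor(t, tmp_path / "tensor")
        back = fz.load_tensor(tmp_path / "tensor")
        assert np.array_equal(back.data, t.data)
        assert back.decode() == strings


def _dv(cid, values, names=None):
    names = names or [f"d{i}" for i in range(len(values))]
    return fz.DescriptorVector(chem_id=cid, values=np.array(values, float),
                               names=names)


class TestMixDescriptors:
    def test_equal_vectors_convex_combination(self):
        d = _dv("a", [1.0, 2.0, 3.0])
        out = fz.mix_descriptors("sum", (0.5, 0.5), d, _dv("b", [1.0, 2.0, 3.0]))
        assert np.allclose(out.values, d.values)

    def test_degenerate_weight(self):
        d1, d2 = _dv("a", [4.0, 0.0]), _dv("b", [0.0, 4.0])
        out = fz.mix_descriptors("sum", (1.0, 0.0), d1, d2)
        assert np.allclose(out.values, d1.values)

    def test_weighted_sum_arithmetic(self):
        out = fz.mix_descriptors(
            "sum", (0.25, 0.75), _dv("a", [4.0, 0.0]), _dv("b", [0.0, 4.0])
        )
        assert np.allclose(out.values, [1.0, 3.0])

    @pytest.mark.parametrize("method", ["sum", "diff", "norm"])
    def test_symmetric_under_simultaneous_swap(self, method):
        d1, d2 = _dv("a", [1.0, -2.0, 0.5]), _dv("b", [3.0, 1.0, -1.0])
        out1 = fz.mix_descriptors(method, (0.3, 0.7), d1, d2)
        out2 = fz.mix_descriptors(method, (0.7, 0.3), d2, d1)
        assert np.allclose(out1.values, out2.values)

    @settings(derandomize=True, max_examples=50)
    @given(
        st.floats(min_value=0, max_value=1),
        st.lists(st.floats(min_value=-10, max_value=10), min_size=1, max_size=5),
        st.lists(st.floats(min_value=-10, max_value=10), min_size=1, max_size=5),
    )
    def test_sum_matches_elementwise_oracle(self, x1, v1, v2):
        n = min(len(v1), len(v2))
        v1, v2 = v1[:n], v2[:n]
        out = fz.mix_descriptors("sum", (x1, 1 - x1), _dv("a", v1), _dv("b", v2))
        oracle = [x1 * a + (1 - x1) * b for a, b in zip(v1, v2)]
        assert np.allclose(out.values, oracle)

    def test_name_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            fz.mix_descriptors(
                "sum", (0.5, 0.5),
                _dv("a", [1.0], ["x"]), _dv("b", [1.0], ["y"]),
            )


class TestImputation:
    def test_median_fill(self):
        df = pd.DataFrame({"a": [1.0, np.nan, 3.0]})
        assert fz.impute_descriptors(df)["a"].tolist() == [1.0, 2.0, 3.0]

    def test_all_nan_column_dropped_with_warning(self):
        df = pd.DataFrame({"a": [1.0, 2.0], "b": [np.nan, np.nan]})
        with pytest.warns(UserWarning, match="all-NaN"):
            out = fz.impute_descriptors(df)
        assert list(out.columns) == ["a"]

    def test_finite_input_unchanged(self):
        df = pd.DataFrame({"a": [1.0, 2.0], "b": [0.5, -1.5]})
        pd.testing.assert_frame_equal(fz.impute_descriptors(df), df)
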
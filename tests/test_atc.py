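"""ATC parsing and the three hierarchical similarity measures."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from atcpred import (
    NpSimParams,
    atc_similarity_matrix,
    level_weight,
    np_sim,
    parse_atc_code,
    rnp_sim,
    shared_levels,
    whs,
)
from atcpred.errors import LookupMissingError, ValidationError

# strategy: syntactically valid level-4 ATC codes
atc_codes = st.builds(
    lambda a, d, b, c: f"{a}{d:02d}{b}{c}",
    st.sampled_from("ABCDEFG"),
    st.integers(1, 12),
    st.sampled_from("ABCD"),
    st.sampled_from("ABCD"),
)
levels = st.integers(1, 4)


class TestParsing:
    @pytest.mark.parametrize(
        "code,level,prefixes",
        [
            ("A03AA", 4, ("A", "A03", "A03A", "A03AA")),
            ("A03AA", 1, ("A",)),
            ("B01AC06", 4, ("B", "B01", "B01A", "B01AC")),  # level-5 input truncates
        ],
    )
    def test_prefix_decomposition(self, code, level, prefixes):
        parsed = parse_atc_code(code, level)
        assert parsed.prefixes == prefixes
        assert parsed.code == prefixes[-1]
        assert parsed.level == level

    @given(atc_codes, levels)
    def test_prefixes_nest(self, code, level):
        parsed = parse_atc_code(code, level)
        assert len(parsed.prefixes) == level
        for shorter, longer in zip(parsed.prefixes, parsed.prefixes[1:]):
            assert longer.startswith(shorter) and len(longer) > len(shorter)

    @pytest.mark.parametrize(
        "code,level",
        [("", 1), ("A03AA", 5), ("A03AA", 0), ("A0", 2), ("103AA", 4),
         ("AX3AA", 4), ("A033A", 4)],
    )
    def test_malformed_input_rejected(self, code, level):
        with pytest.raises(ValidationError):
            parse_atc_code(code, level)

    def test_error_names_offending_position(self):
        with pytest.raises(ValidationError, match="position 1"):
            parse_atc_code("AX3AA", 4)


class TestSharedLevels:
    def test_worked_example(self):
        # the two level-4 codes agree on their level-1 and level-2 prefixes only
        assert shared_levels("A03AA", "A03BB", 4) == 2

    @given(atc_codes, levels)
    def test_identical_codes_share_everything(self, code, k):
        assert shared_levels(code, code, k) == k

    def test_level1_mismatch_empties_intersection(self):
        assert shared_levels("A03AA", "B03AA", 4) == 0

    def test_equals_prefix_set_intersection(self):
        # nesting means the count equals an explicit set intersection
        for a, b in [("A03AA", "A03AB"), ("A03AA", "A04AA"), ("C01AA", "C01AB")]:
            pa, pb = parse_atc_code(a, 4), parse_atc_code(b, 4)
            assert shared_levels(a, b, 4) == len(set(pa.prefixes) & set(pb.prefixes))

    def test_bad_level_rejected(self):
        with pytest.raises(ValidationError):
            shared_levels("A03AA", "A03BB", 5)


class TestLevelWeight:
    @pytest.mark.parametrize("k,n,expected", [(4, 0, 0), (4, 2, 25), (1, 1, 1),
                                              (4, 4, 30), (3, 2, 13)])
    def test_direct_summation(self, k, n, expected):
        assert level_weight(k, n) == expected

    @given(levels, st.data())
    def test_increments_are_squares_and_shrink(self, k, data):
        n = data.draw(st.integers(0, k - 1))
        inc = level_weight(k, n + 1) - level_weight(k, n)
        assert inc == (k - n) ** 2
        if n + 1 < k:
            assert level_weight(k, n + 2) - level_weight(k, n + 1) < inc

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            level_weight(4, 5)
        with pytest.raises(ValidationError):
            level_weight(4, -1)


class TestWhs:
    def test_worked_example_value(self):
        # N=2, W4^2=25, W4^4=30 -> (2*25+16)/(2*30+16); regression-locked derivation
        assert whs("A03AA", "A03BB", 4) == pytest.approx(66 / 76, abs=1e-12)

    @given(atc_codes, levels)
    def test_self_similarity_is_one(self, code, k):
        assert whs(code, code, k) == 1.0

    @given(atc_codes, atc_codes, levels)
    def test_symmetry_and_range(self, a, b, k):
        v, w = whs(a, b, k), whs(b, a, k)
        assert v == w
        lower = k * k / (2 * level_weight(k, k) + k * k)
        assert lower <= v <= 1.0

    def test_lower_bound_attained_at_level1_mismatch(self):
        for k in (1, 2, 3, 4):
            v = whs("A03AA", "B03AA", k)
            assert v == pytest.approx(k * k / (2 * level_weight(k, k) + k * k))

    def test_strictly_increasing_in_shared_depth(self):
        pairs = [("A03AA", "B03AA"), ("A03AA", "A04AA"),
                 ("A03AA", "A03BB"), ("A03AA", "A03AB"), ("A03AA", "A03AA")]
        values = [whs(a, b, 4) for a, b in pairs]  # N = 0, 1, 2, 3, 4
        assert all(x < y for x, y in zip(values, values[1:]))


class TestRnpSim:
    @pytest.mark.parametrize(
        "a,b,k,expected",
        [("A03AA", "A03BB", 4, 5 / 9), ("A03AA", "A03AA", 3, 1.0),
         ("A03AA", "B01AA", 1, 1 / 3)],
    )
    def test_values(self, a, b, k, expected):
        assert rnp_sim(a, b, k) == pytest.approx(expected, abs=1e-12)

    @given(atc_codes, atc_codes)
    def test_level1_identity_with_whs(self, a, b):
        assert whs(a, b, 1) == rnp_sim(a, b, 1)

    @given(atc_codes, atc_codes, levels)
    def test_monotone_in_shared_depth_at_fixed_k(self, a, b, k):
        n = shared_levels(a, b, k)
        assert rnp_sim(a, b, k) == pytest.approx((2 * n + 1) / (2 * k + 1))


class TestNpSim:
    def test_identical_frequency_one(self):
        p = NpSimParams({"A03AA": 1.0})
        assert np_sim("A03AA", "A03AA", p, 4) == pytest.approx(1.0)

    def test_tree_distance_decay(self):
        p = NpSimParams({"A03AA": 1.0, "A03BB": 1.0})
        # two disagreeing levels -> 4 tree edges through the common ancestor
        assert np_sim("A03AA", "A03BB", p, 4) == pytest.approx(math.exp(-0.25 * 4))

    def test_rare_codes_exceed_one(self):
        # unbounded above: inverse-frequency weights multiply
        p = NpSimParams({"A03AA": 0.5, "A03BB": 0.25})
        assert np_sim("A03AA", "A03AA", p, 4) == pytest.approx(4.0)  # w=2 squared
        # frequencies 0.5 and 0.25 at distance zero give 2 * 4 = 8
        assert p.weight("A03AA") * p.weight("A03BB") * math.exp(0) == pytest.approx(8.0)

    def test_missing_code_raises_lookup_error(self):
        with pytest.raises(LookupMissingError):
            np_sim("A03AA", "A03BB", NpSimParams({"A03AA": 1.0}), 4)

    def test_frequencies_estimated_from_pair_list(self):
        p = NpSimParams.from_pairs(["A03AA", "A03AA", "A03AB", "B01AA"], level=2)
        assert p.code_frequency == {"A03": 0.75, "B01": 0.25}
        with pytest.raises(ValidationError):
            NpSimParams({"A03": 0.0})


class TestSimilarityMatrix:
    def test_single_code_unit(self):
        df = atc_similarity_matrix(["A03AA"], "whs", 4)
        assert df.shape == (1, 1) and df.iloc[0, 0] == 1.0

    def test_truncation_collapses_duplicates(self):
        df = atc_similarity_matrix(["A03AA", "A03AB"], "whs", 2)
        assert list(df.index) == ["A03"]

    def test_input_duplicates_rejected(self):
        with pytest.raises(ValidationError):
            atc_similarity_matrix(["A03AA", "A03AA"], "whs", 4)

    @pytest.mark.parametrize("measure", ["whs", "rnpsim"])
    def test_matches_elementwise_calls(self, measure):
        codes = ["A03AA", "A03BB", "B01AC", "A04AA"]
        fn = whs if measure == "whs" else rnp_sim
        df = atc_similarity_matrix(codes, measure, 2)
        for a, b in itertools.product(df.index, repeat=2):
            assert df.loc[a, b] == pytest.approx(fn(a, b, 2))
        assert np.allclose(np.diag(df.values), 1.0)

    def test_npsim_matrix_uses_params(self):
        codes = ["A03AA", "A03BB"]
        params = NpSimParams.from_pairs(codes * 2, level=4)
        df = atc_similarity_matrix(codes, "npsim", 4, params)
        assert df.loc["A03AA", "A03BB"] == pytest.approx(
            np_sim("A03AA", "A03BB", params, 4)
        )
        with pytest.raises(ValidationError):
            atc_similarity_matrix(codes, "npsim", 4)
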
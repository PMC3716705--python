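import itertools

import numpy as np
import pytest

from tmfr.profile import PositionProfile
from tmfr.scoring import (
    ALPHA_PARAMETER_VECTOR,
    BETA_MAPPINGS,
    BETA_PARAMETER_VECTOR,
    AmbiguousParameterMappingError,
    ParameterSet,
    asa_term,
    fitness_cost,
    gap_penalties_at,
    orientation_term,
    paper_parameters,
    profile_term,
    segment_term,
)


def make_position(segment="I", orientation=0, asa=0.5, freq=None, log_odds=None):
    if freq is None:
        freq = np.full(20, 0.05)
    if log_odds is None:
        log_odds = np.zeros(20)
    return PositionProfile(freq, log_odds, segment, orientation, asa)


class TestProfileTerm:
    def test_uniform_frequency_averages_log_odds(self):
        a = make_position(freq=np.full(20, 0.05))
        b = make_position(log_odds=np.ones(20))
        assert profile_term(a, b) == pytest.approx(1.0)

    def test_delta_frequency_selects_template_value(self):
        freq = np.zeros(20)
        freq[7] = 1.0
        lo = np.arange(20.0)
        assert profile_term(make_position(freq=freq), make_position(log_odds=lo)) == 7.0

    def test_matches_bruteforce_dot_product(self, rng):
        for _ in range(20):
            f = rng.dirichlet(np.ones(20))
            lo = rng.normal(0, 2, 20)
            expected = sum(f[r] * lo[r] for r in range(20))
            got = profile_term(make_position(freq=f), make_position(log_odds=lo))
            assert got == pytest.approx(expected, abs=1e-12)


class TestSegmentOrientationAsaTerms:
    def test_segment_match_and_mismatch(self):
        h = make_position("H", +1)
        o = make_position("O", 0)
        assert segment_term(h, h) == 1.0
        assert segment_term(h, o) == -1.0

    def test_segment_term_symmetric_over_all_code_pairs(self):
        codes = {"H": +1, "B": -1, "I": 0, "O": 0, "U": 0}
        for a, b in itertools.product(codes, repeat=2):
            x = make_position(a, codes[a])
            y = make_position(b, codes[b])
            assert segment_term(x, y) == segment_term(y, x)
            assert segment_term(x, y) == (1.0 if a == b else -1.0)

    @pytest.mark.parametrize(
        "oa,ob,expected",
        [(+1, +1, 1.0), (-1, -1, 1.0), (+1, -1, -1.0), (-1, +1, -1.0),
         (0, +1, 0.0), (0, -1, 0.0), (+1, 0, 0.0), (0, 0, 0.0)],
    )
    def test_orientation_truth_table(self, oa, ob, expected):
        a = make_position("H" if oa else "I", oa)
        b = make_position("H" if ob else "I", ob)
        assert orientation_term(a, b) == expected

    @pytest.mark.parametrize(
        "aa,ab,expected", [(0.3, 0.3, 1.0), (0.0, 1.0, 0.0), (0.2, 0.5, 0.7)]
    )
    def test_asa_similarity(self, aa, ab, expected):
        assert asa_term(make_position(asa=aa), make_position(asa=ab)) == pytest.approx(expected)


class TestFitnessCost:
    def test_zero_weights_reduce_to_shift(self):
        params = ParameterSet(0, 0, 0, 0, 3.7, 2, 1, 1, 0.5)
        a, b = make_position("H", 1), make_position("O", 0)
        assert fitness_cost(a, b, params) == pytest.approx(3.7)

    def test_direct_arithmetic(self):
        params = ParameterSet(1, 1, 1, 1, 0.0, 2, 1, 1, 0.5)
        freq = np.zeros(20)
        freq[0] = 1.0
        lo = np.full(20, 2.0)
        a = make_position("H", +1, asa=0.5, freq=freq)
        b = make_position("H", +1, asa=0.5, log_odds=lo)
        # terms: profile 2.0, segment 1, orientation 1, asa 1 -> cost -5
        assert fitness_cost(a, b, params) == pytest.approx(-5.0)

    def test_monotone_decreasing_in_each_term(self):
        params = ParameterSet(1, 1, 1, 1, 0.0, 2, 1, 1, 0.5)
        base_b = make_position("H", +1, asa=0.5)
        a = make_position("H", +1, asa=0.5)
        baseline = fitness_cost(a, base_b, params)
        # worsen each term in turn; the cost must strictly rise
        worse_segment = make_position("O", 0, asa=0.5)
        worse_asa = make_position("H", +1, asa=0.9)
        worse_orientation = make_position("H", -1, asa=0.5)
        for worse in (worse_segment, worse_asa, worse_orientation):
            assert fitness_cost(a, worse, params) > baseline


class TestGapPenalties:
    def test_tm_vs_loop_vs_unknown(self, rng, random_profile_factory):
        from tmfr.profile import assemble_profile

        freq = np.full((3, 20), 0.05)
        profile = assemble_profile(
            "p", "AAA", freq, np.zeros((3, 20)), "HIU", np.full(3, 0.5)
        )
        params = paper_parameters("alpha")
        assert gap_penalties_at(profile, 0, params) == (12.1, 1.6)
        assert gap_penalties_at(profile, 1, params) == (8.6, 1.1)
        assert gap_penalties_at(profile, 2, params) == (8.6, 1.1)
        with pytest.raises(IndexError):
            gap_penalties_at(profile, 3, params)


class TestParameterPresets:
    def test_alpha_vector_verbatim(self):
        params = paper_parameters("alpha")
        assert params.as_vector() == tuple(float(v) for v in ALPHA_PARAMETER_VECTOR)
        assert params.w_profile == 1.6
        assert params.shift == 4
        assert params.gap_open_tm > params.gap_open_non  # 12.1 > 8.6

    def test_beta_vector_stored_verbatim(self):
        assert BETA_PARAMETER_VECTOR == (1.5, 9.2, 4.3, 3.6, 5, 9.2, 11.8, 1.6, 8.3, 1.1)

    def test_beta_without_mapping_refuses(self):
        with pytest.raises(AmbiguousParameterMappingError):
            paper_parameters("beta")

    @pytest.mark.parametrize("mapping", sorted(BETA_MAPPINGS))
    def test_beta_mappings_drop_nothing_silently(self, mapping):
        params = paper_parameters("beta", beta_mapping=mapping)
        used = [BETA_PARAMETER_VECTOR[i] for i in BETA_MAPPINGS[mapping]]
        assert params.as_vector() == tuple(float(v) for v in used)
        assert params.gap_open_tm > params.gap_open_non

    def test_constraint_enforced_at_construction(self):
        with pytest.raises(ValueError, match="gap_open_tm"):
            ParameterSet(1, 1, 1, 1, 0, 2.0, 1.0, 3.0, 1.0)
        with pytest.raises(ValueError, match="nonnegative"):
            ParameterSet(-1, 1, 1, 1, 0, 4.0, 1.0, 2.0, 1.0)

    def test_yaml_roundtrip(self):
        params = paper_parameters("alpha")
        assert ParameterSet.from_yaml(params.to_yaml()) == params
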
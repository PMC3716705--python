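import numpy as np
import pytest

from tmfr.aligner import Alignment, adjusted_score, align, raw_score
from tmfr.scoring import ParameterSet, paper_parameters
from tmfr.synthetic_data import GeneratorConfig, generate_ancestor
from tmfr.training import random_parameter_set

from _bruteforce import brute_force_best


class TestAlignBasics:
    def test_self_alignment_is_identity(self, rng):
        config = GeneratorConfig(n_tm_segments=3, loop_length_range=(3, 10), seed=5)
        profile = generate_ancestor(config, rng)
        aln = align(profile, profile, paper_parameters("alpha"))
        assert aln.pairs == tuple((i, i) for i in range(len(profile)))
        assert aln.gap_runs == ()
        assert aln.raw_score < 0

    def test_empty_profile_and_bad_mode_rejected(self, rng, random_profile_factory):
        from tmfr.profile import assemble_profile

        p = random_profile_factory(rng, 5)
        with pytest.raises(ValueError, match="mode"):
            align(p, p, paper_parameters("alpha"), mode="bogus")
        empty = assemble_profile(
            "e", "", np.empty((0, 20)), np.empty((0, 20)), "", np.empty(0)
        )
        with pytest.raises(ValueError, match="empty"):
            align(empty, p, paper_parameters("alpha"))

    def test_cross_class_rejected(self, rng, random_profile_factory):
        a = random_profile_factory(rng, 8, "a", alphabet="HIO")
        b = random_profile_factory(rng, 8, "b", alphabet="BIO")
        with pytest.raises(ValueError, match="cross-class"):
            align(a, b, paper_parameters("alpha"))

    def test_pairs_strictly_increasing_invariant(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            Alignment("t", "m", 3, 3, ((0, 1), (1, 1)), (), 0.0, 0.0)


class TestBruteForceOracle:
    @pytest.mark.parametrize("mode", ["global", "glocal_template", "glocal_both"])
    def test_dp_equals_enumeration_small(self, mode, rng, random_profile_factory):
        for _ in range(25):
            n, m = rng.integers(1, 7, size=2)
            target = random_profile_factory(rng, int(n), "t")
            template = random_profile_factory(rng, int(m), "p")
            params = random_parameter_set(rng)
            aln = align(target, template, params, mode=mode)
            expected = brute_force_best(target, template, params, mode=mode)
            assert aln.raw_score == pytest.approx(expected, abs=1e-9)

    def test_glocal_embedding_covers_full_target(self, rng, random_profile_factory):
        template = random_profile_factory(rng, 20, "tpl", alphabet="HIO")
        # carve the target out of the middle of the template
        from tmfr.profile import assemble_profile

        arrays = template.feature_arrays()
        lo_slice = slice(5, 13)
        target = assemble_profile(
            "tgt",
            template.sequence[lo_slice],
            arrays["freq"][lo_slice],
            arrays["log_odds"][lo_slice],
            template.topology_string()[lo_slice],
            arrays["asa"][lo_slice],
        )
        params = ParameterSet(1, 1, 1, 1, 0.0, 4, 1, 2, 0.5)
        aln = align(target, template, params, mode="glocal_template")
        assert [t for t, _ in aln.pairs] == list(range(len(target)))
        assert aln.pairs == tuple((i, i + 5) for i in range(len(target)))
        # template overhangs are free: no penalised gap runs recorded
        assert aln.gap_runs == ()


class TestRawScore:
    def test_identity_self_alignment_sums_costs(self, rng, random_profile_factory):
        p = random_profile_factory(rng, 10)
        params = ParameterSet(1, 1, 1, 1, 0.0, 4, 1, 2, 0.5)
        aln = align(p, p, params)
        # every self pair scores segment+orientation(+TM)+asa maximal
        assert aln.raw_score < 0
        assert raw_score(aln, p, p, params) == pytest.approx(aln.raw_score, abs=1e-6)

    @pytest.mark.parametrize("mode", ["global", "glocal_template", "glocal_both"])
    def test_recompute_matches_reported(self, mode, rng, random_profile_factory):
        for _ in range(33):
            n, m = rng.integers(2, 30, size=2)
            target = random_profile_factory(rng, int(n), "t")
            template = random_profile_factory(rng, int(m), "p")
            params = random_parameter_set(rng)
            aln = align(target, template, params, mode=mode)
            assert raw_score(aln, target, template, params) == pytest.approx(
                aln.raw_score, abs=1e-6
            )


class TestAdjustedScore:
    def test_equal_lengths_unchanged(self):
        assert adjusted_score(-12.5, 80, 80) == -12.5

    def test_additive_penalty(self):
        assert adjusted_score(-10.0, 100, 95, kappa=1.0) == pytest.approx(-5.0)

    def test_nondecreasing_in_length_difference(self):
        scores = [adjusted_score(-10.0, 100, 100 + d) for d in range(0, 40, 5)]
        assert scores == sorted(scores)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            adjusted_score(0.0, 0, 5)
        with pytest.raises(ValueError):
            adjusted_score(0.0, 5, 5, kappa=-1)


class TestAlignmentProperties:
    def test_symmetric_costs_give_symmetric_global_scores(self, rng, random_profile_factory):
        # with w_profile = 0 every per-pair term is symmetric in its arguments
        params = ParameterSet(0.0, 1.0, 1.0, 1.0, 1.0, 4, 1, 2, 0.5)
        for _ in range(10):
            a = random_profile_factory(rng, int(rng.integers(3, 12)), "a")
            b = random_profile_factory(rng, int(rng.integers(3, 12)), "b")
            fwd = align(a, b, params, mode="global")
            rev = align(b, a, params, mode="global")
            assert fwd.raw_score == pytest.approx(rev.raw_score, abs=1e-9)

    def test_scaling_gaps_never_adds_gapped_columns(self, rng, random_profile_factory):
        for _ in range(25):
            a = random_profile_factory(rng, int(rng.integers(5, 25)), "a")
            b = random_profile_factory(rng, int(rng.integers(5, 25)), "b")
            params = random_parameter_set(rng)
            doubled = ParameterSet(
                params.w_profile, params.w_segment, params.w_orientation,
                params.w_asa, params.shift,
                2 * params.gap_open_tm, 2 * params.gap_ext_tm,
                2 * params.gap_open_non, 2 * params.gap_ext_non,
            )
            n_gap = sum(r[2] for r in align(a, b, params).gap_runs)
            n_gap_doubled = sum(r[2] for r in align(a, b, doubled).gap_runs)
            assert n_gap_doubled <= n_gap

    def test_self_alignment_beats_random_templates(self, rng, random_profile_factory):
        params = ParameterSet(1, 1, 1, 1, 0.0, 4, 1, 2, 0.5)
        p = random_profile_factory(rng, 15, "self")
        self_score = align(p, p, params).raw_score
        for _ in range(5):
            q = random_profile_factory(rng, 15, "other")
            assert self_score <= align(p, q, params).raw_score
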
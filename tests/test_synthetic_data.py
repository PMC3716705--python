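import re

import numpy as np
import pytest

from tmfr.synthetic_data import (
    HYDROPHOBIC,
    GeneratorConfig,
    evolve_member,
    generate_ancestor,
    generate_benchmark,
)


class TestGeneratorConfig:
    def test_class_defaults_for_tm_lengths(self):
        assert GeneratorConfig(tm_class="alpha").tm_length_range == (17, 25)
        assert GeneratorConfig(tm_class="beta").tm_length_range == (11, 14)

    def test_invalid_rates_rejected(self):
        with pytest.raises(ValueError):
            GeneratorConfig(substitution_rate=1.5)
        with pytest.raises(ValueError):
            GeneratorConfig(n_tm_segments=1)


class TestGenerateAncestor:
    def test_topology_structure_and_tm_lengths(self):
        config = GeneratorConfig(n_tm_segments=4, seed=11)
        profile = generate_ancestor(config)
        topo = profile.topology_string()
        assert re.fullmatch(r"I+(H+[IO]+){4}", topo)
        for run in re.findall(r"H+", topo):
            assert 17 <= len(run) <= 25

    def test_beta_uses_strand_letter_and_lengths(self):
        config = GeneratorConfig(tm_class="beta", n_tm_segments=6, seed=3)
        profile = generate_ancestor(config)
        topo = profile.topology_string()
        assert "H" not in topo and "B" in topo
        assert profile.tm_class == "beta"
        for run in re.findall(r"B+", topo):
            assert 11 <= len(run) <= 14

    def test_same_seed_identical(self):
        config = GeneratorConfig(seed=7)
        a = generate_ancestor(config)
        b = generate_ancestor(config)
        assert a.sequence == b.sequence
        assert a.topology_string() == b.topology_string()
        np.testing.assert_array_equal(
            a.feature_arrays()["freq"], b.feature_arrays()["freq"]
        )

    def test_membrane_positions_are_buried_and_hydrophobic(self):
        # pooled over many generations: TM accessibility below loop
        # accessibility, and hydrophobic residues >= 60% of TM frequency mass
        tm_asa, loop_asa = [], []
        tm_freq_mass = 0.0
        n_tm = 0
        hyd_idx = [i for i, aa in enumerate("ARNDCQEGHILKMFPSTWYV") if aa in HYDROPHOBIC]
        rng = np.random.default_rng(99)
        for k in range(50):
            profile = generate_ancestor(GeneratorConfig(seed=k), rng)
            arrays = profile.feature_arrays()
            is_tm = arrays["is_tm"]
            tm_asa.extend(arrays["asa"][is_tm])
            loop_asa.extend(arrays["asa"][~is_tm])
            tm_freq_mass += arrays["freq"][is_tm][:, hyd_idx].sum()
            n_tm += int(is_tm.sum())
        assert n_tm >= 1000
        assert np.mean(tm_asa) < np.mean(loop_asa)
        assert tm_freq_mass / n_tm >= 0.60


class TestEvolveMember:
    def test_zero_rates_give_identity(self):
        config = GeneratorConfig(substitution_rate=0.0, indel_rate=0.0, seed=1)
        ancestor = generate_ancestor(config)
        member, aln, identity = evolve_member(ancestor, config, seed=2)
        assert member.sequence == ancestor.sequence
        assert identity == 1.0
        assert aln.pairs == tuple((i, i) for i in range(len(ancestor)))

    def test_full_substitution_keeps_identity_alignment(self):
        config = GeneratorConfig(substitution_rate=1.0, indel_rate=0.0, seed=1)
        ancestor = generate_ancestor(config)
        member, aln, identity = evolve_member(ancestor, config, seed=2)
        assert len(member) == len(ancestor)
        assert aln.pairs == tuple((i, i) for i in range(len(ancestor)))
        # residues resampled from the emitting compositions still collide
        # at roughly the composition's self-collision rate (~0.1)
        assert 0.0 < identity < 0.35

    def test_true_alignment_structure(self, rng):
        config = GeneratorConfig(substitution_rate=0.3, indel_rate=0.1, seed=1)
        ancestor = generate_ancestor(config)
        for k in range(30):
            member, aln, identity = evolve_member(ancestor, config, seed=k)
            last_t = last_m = -1
            for t, m in aln.pairs:
                assert t > last_t and m > last_m
                last_t, last_m = t, m
                assert member.topology_string()[t] == ancestor.topology_string()[m]
            assert 0.0 <= identity <= 1.0

    def test_indels_prefer_loops(self):
        config = GeneratorConfig(
            substitution_rate=0.0, indel_rate=0.3, n_tm_segments=4, seed=1
        )
        ancestor = generate_ancestor(config)
        anc_topo = ancestor.topology_string()
        tm_del = loop_del = 0
        tm_total = anc_topo.count("H")
        loop_total = len(anc_topo) - tm_total
        for k in range(40):
            _, aln, _ = evolve_member(ancestor, config, seed=k)
            aligned = {m for _, m in aln.pairs}
            for i, ch in enumerate(anc_topo):
                if i not in aligned:
                    if ch == "H":
                        tm_del += 1
                    else:
                        loop_del += 1
        assert loop_del / loop_total > 3 * (tm_del / tm_total)


class TestGenerateBenchmark:
    def test_shapes_and_labels(self):
        config = GeneratorConfig(seed=0)
        bm = generate_benchmark(2, 2, config, seed=5)
        assert len(bm.library) == 2 and len(bm.targets) == 2
        for target in bm.targets:
            fam = bm.target_labels[target.id]
            assert fam in bm.fold_labels.values()
            ref = bm.references[target.id]
            assert ref.target_id == target.id
        assert len(bm.identities) == 4

    def test_same_seed_reproducible(self):
        config = GeneratorConfig(seed=0)
        a = generate_benchmark(3, 2, config, seed=9)
        b = generate_benchmark(3, 2, config, seed=9)
        assert [p.sequence for p in a.targets] == [p.sequence for p in b.targets]
        assert a.identities == b.identities

    def test_within_family_identity_exceeds_between(self):
        config = GeneratorConfig(substitution_rate=0.3, indel_rate=0.05, seed=0)
        bm = generate_benchmark(4, 2, config, seed=21)
        within, between = [], []
        for (tid, mid), value in bm.identities.items():
            if bm.target_labels[tid] == bm.fold_labels[mid]:
                within.append(value)
            else:
                between.append(value)
        assert np.mean(within) > np.mean(between)
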
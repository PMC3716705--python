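"""Synthetic transmembrane-protein families with known ground truth.

The generator emulates the statistical structure the aligner assumes:
alternating inside/outside loops around membrane-spanning segments of
realistic lengths (helices 17-25 residues; strands 11-14), strongly
hydrophobic compositions and low accessibility inside the membrane,
hydrophilic loops with higher accessibility, per-position frequency
vectors (Dirichlet draws around the emitting composition) with log-odds
taken against a uniform background, and homologs produced by recorded
substitutions and indels — indels fall preferentially in loops, with a
10% relative propensity inside TM segments, mirroring the biological
prior the segment-dependent gap penalties exploit.

All randomness flows from a single seed through ``numpy`` seed-sequence
spawning (one child stream per family, one grandchild per member), so
every artefact is reproducible bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib
import numpy as np

from .aligner import Alignment
from .io_formats import AMINO_ACIDS
from .profile import ProteinProfile, assemble_profile

_BACKGROUND = 0.05  # uniform background frequency for log-odds

#: Emitting composition inside membrane-spanning segments: the hydrophobic
#: set {A, I, L, F, V, M} carries ~72% of the mass.
_TM_WEIGHTS = {
    "A": 0.12, "I": 0.13, "L": 0.18, "F": 0.10, "V": 0.13, "M": 0.06,
    "G": 0.06, "W": 0.03, "C": 0.02, "T": 0.04, "S": 0.04, "Y": 0.03,
    "P": 0.01, "N": 0.01, "Q": 0.01, "D": 0.005, "E": 0.005, "K": 0.005,
    "R": 0.005, "H": 0.01,
}
#: Emitting composition in loops: hydrophilic/charged-biased.
_LOOP_WEIGHTS = {
    "S": 0.08, "T": 0.06, "N": 0.07, "Q": 0.06, "D": 0.07, "E": 0.08,
    "K": 0.08, "R": 0.07, "G": 0.08, "P": 0.06, "H": 0.03, "A": 0.06,
    "L": 0.05, "I": 0.03, "V": 0.03, "F": 0.02, "Y": 0.03, "M": 0.02,
    "W": 0.01, "C": 0.01,
}

HYDROPHOBIC = frozenset("AILFVM")

_DIRICHLET_CONC = 25.0  # concentration of per-position frequency draws


def _composition(weights: dict[str, float]) -> np.ndarray:
    v = np.array([weights[aa] for aa in AMINO_ACIDS])
    return v / v.sum()

TM_COMPOSITION = _composition(_TM_WEIGHTS)
LOOP_COMPOSITION = _composition(_LOOP_WEIGHTS)


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for one synthetic family.

    Defaults follow the field's segment-length conventions: helices span
    17-25 residues, strands 11-14; loops span 3-30 residues.
    """

    tm_class: str = "alpha"
    n_tm_segments: int = 4
    tm_length_range: tuple[int, int] | None = None  # class default if None
    loop_length_range: tuple[int, int] = (3, 30)
    n_homologs: int = 3
    substitution_rate: float = 0.3
    indel_rate: float = 0.05
    mean_indel_length: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tm_class not in ("alpha", "beta"):
            raise ValueError("tm_class must be 'alpha' or 'beta'")
        if self.n_tm_segments < 2:
            raise ValueError("n_tm_segments must be >= 2")
        for rate in (self.substitution_rate, self.indel_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        if self.tm_length_range is None:
            default = (17, 25) if self.tm_class == "alpha" else (11, 14)
            object.__setattr__(self, "tm_length_range", default)
        for lo, hi in (self.tm_length_range, self.loop_length_range):
            if not 1 <= lo <= hi:
                raise ValueError("length ranges must be non-empty")

    @property
    def tm_letter(self) -> str:
        return "H" if self.tm_class == "alpha" else "B"


@dataclass(frozen=True)
class SyntheticFamily:
    """An ancestral template and its evolved members.

    ``members`` holds ``(profile, alignment_to_ancestor, fractional_identity)``
    triples; the alignment's target is the member, its template the
    ancestor.
    """

    family_id: str
    ancestor: ProteinProfile
    members: tuple[tuple[ProteinProfile, Alignment, float], ...]


@dataclass(frozen=True)
class Benchmark:
    """A multi-family benchmark: template library, targets, true labels."""

    families: tuple[SyntheticFamily, ...]
    library: tuple[ProteinProfile, ...]
    targets: tuple[ProteinProfile, ...]
    fold_labels: dict[str, str]          # template id -> family id
    target_labels: dict[str, str]        # target id -> family id
    references: dict[str, Alignment]     # target id -> alignment to its template
    identities: dict[tuple[str, str], float] = field(default_factory=dict)


def _segment_arrays(topology: str):
    chars = np.frombuffer(topology.encode("ascii"), dtype=np.uint8)
    return np.isin(chars, np.frombuffer(b"HB", dtype=np.uint8))


def _draw_position(rng: np.random.Generator, is_tm: bool):
    """One position's (residue, freq, log_odds, asa)."""
    comp = TM_COMPOSITION if is_tm else LOOP_COMPOSITION
    freq = rng.dirichlet(comp * _DIRICHLET_CONC)
    freq = np.maximum(freq, 1e-9)
    freq = freq / freq.sum()
    residue = AMINO_ACIDS[rng.choice(20, p=freq)]
    log_odds = np.log(freq / _BACKGROUND)
    if is_tm:
        asa = float(rng.beta(1.5, 8.5))   # mean ~0.15, membrane-buried
    else:
        asa = float(rng.beta(5.0, 5.0))   # mean 0.5, solvent-exposed
    return residue, freq, log_odds, asa


def generate_topology(config: GeneratorConfig, rng: np.random.Generator) -> str:
    """Alternating loop/TM/loop/... topology string, starting inside."""
    lo_t, hi_t = config.tm_length_range
    lo_l, hi_l = config.loop_length_range
    parts = []
    loop_chars = "IO"
    for k in range(config.n_tm_segments):
        parts.append(loop_chars[k % 2] * int(rng.integers(lo_l, hi_l + 1)))
        parts.append(config.tm_letter * int(rng.integers(lo_t, hi_t + 1)))
    parts.append(loop_chars[config.n_tm_segments % 2]
                 * int(rng.integers(lo_l, hi_l + 1)))
    return "".join(parts)


def generate_ancestor(
    config: GeneratorConfig,
    rng: np.random.Generator | None = None,
    profile_id: str = "ancestor",
) -> ProteinProfile:
    """Draw one ancestral protein profile under the study conditions."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    topology = generate_topology(config, rng)
    is_tm = _segment_arrays(topology)
    seq = []
    freqs = []
    log_odds = []
    asa = []
    for i in range(len(topology)):
        r, f, lo, a = _draw_position(rng, bool(is_tm[i]))
        seq.append(r)
        freqs.append(f)
        log_odds.append(lo)
        asa.append(a)
    return assemble_profile(
        profile_id, "".join(seq), np.asarray(freqs), np.asarray(log_odds),
        topology, np.asarray(asa),
    )


#: Relative indel propensity inside TM segments (gaps in the membrane are
#: rare but not forbidden).
TM_INDEL_PROPENSITY = 0.1


def evolve_member(
    ancestor: ProteinProfile,
    config: GeneratorConfig,
    seed: int | np.random.Generator,
    member_id: str = "member",
) -> tuple[ProteinProfile, Alignment, float]:
    """Evolve one homolog from an ancestor, recording the true alignment.

    Substitutions redraw the residue, frequency vector and accessibility
    from the position's segment composition; indels have geometric
    lengths (mean ``mean_indel_length``) and fall in TM segments with
    only :data:`TM_INDEL_PROPENSITY` of the loop propensity.  The
    returned alignment pairs member positions (target) with ancestor
    positions (template); ``fractional_identity`` is the number of
    aligned identical residues over the ancestor length.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p_geo = 1.0 / max(config.mean_indel_length, 1.0)
    anc = ancestor.feature_arrays()
    anc_topology = ancestor.topology_string()

    seq: list[str] = []
    freqs: list[np.ndarray] = []
    log_odds: list[np.ndarray] = []
    asa: list[float] = []
    topo: list[str] = []
    pairs: list[tuple[int, int]] = []  # (member index, ancestor index)
    identical = 0

    i = 0
    L = len(ancestor)
    while i < L:
        is_tm = bool(anc["is_tm"][i])
        indel_p = config.indel_rate * (TM_INDEL_PROPENSITY if is_tm else 1.0)
        roll = rng.random()
        if roll < indel_p / 2.0:
            # deletion: skip a run of ancestor positions
            length = int(rng.geometric(p_geo))
            i += length
            continue
        if roll < indel_p:
            # insertion: new positions drawn from the local composition
            length = int(rng.geometric(p_geo))
            for _ in range(length):
                r, f, lo, a = _draw_position(rng, is_tm)
                seq.append(r)
                freqs.append(f)
                log_odds.append(lo)
                asa.append(a)
                topo.append(anc_topology[i])
            # fall through: the current ancestor position is still copied
        if rng.random() < config.substitution_rate:
            r, f, lo, a = _draw_position(rng, is_tm)
        else:
            r = ancestor.sequence[i]
            f = anc["freq"][i]
            lo = anc["log_odds"][i]
            a = float(anc["asa"][i])
        pairs.append((len(seq), i))
        if r == ancestor.sequence[i]:
            identical += 1
        seq.append(r)
        freqs.append(f)
        log_odds.append(lo)
        asa.append(a)
        topo.append(anc_topology[i])
        i += 1

    profile = assemble_profile(
        member_id, "".join(seq), np.asarray(freqs), np.asarray(log_odds),
        "".join(topo), np.asarray(asa),
    )
    alignment = Alignment(
        target_id=member_id,
        template_id=ancestor.id,
        target_len=len(profile),
        template_len=L,
        pairs=tuple(pairs),
        gap_runs=(),
        raw_score=float("nan"),
        adjusted_score=float("nan"),
        mode="glocal_both",
    )
    return profile, alignment, identical / L


def generate_family(
    config: GeneratorConfig,
    family_id: str,
    rng: np.random.Generator,
) -> SyntheticFamily:
    """One ancestor plus ``config.n_homologs`` evolved members."""
    streams = rng.spawn(config.n_homologs + 1)
    ancestor = generate_ancestor(config, streams[0], profile_id=family_id)
    members = tuple(
        evolve_member(ancestor, config, streams[k + 1], f"{family_id}_m{k}")
        for k in range(config.n_homologs)
    )
    return SyntheticFamily(family_id, ancestor, members)


def sequence_identity(a: str, b: str) -> float:
    """Fraction of identical columns in a global edit-distance alignment.

    Computed with edlib — independent of this package's profile aligner —
    and used as the similarity label for score-correlation analyses.
    """
    result = edlib.align(a, b, mode="NW", task="path")
    nice = edlib.getNiceAlignment(result, a, b)
    matched = nice["matched_aligned"]
    return matched.count("|") / len(matched)


def compose_alignments(
    member_to_anc: Alignment, template_to_anc: Alignment,
) -> list[tuple[int, int]]:
    """Compose two member->ancestor alignments into member->member pairs."""
    anc_to_template = {a: t for t, a in template_to_anc.pairs}
    return [
        (t, anc_to_template[a])
        for t, a in member_to_anc.pairs
        if a in anc_to_template
    ]


def generate_benchmark(
    n_families: int,
    members_per_family: int,
    config: GeneratorConfig,
    seed: int | None = None,
) -> Benchmark:
    """Build a fold-recognition benchmark of distinct synthetic families.

    The first member of each family becomes the library template; the
    remaining members are targets.  References are the generator-recorded
    target-to-template alignments composed through the ancestor, and
    ``identities`` holds the edlib sequence identity of every
    target/template pair.
    """
    if n_families < 2:
        raise ValueError("need at least 2 families")
    if members_per_family < 2:
        raise ValueError("need at least 2 members per family (template + target)")
    if seed is None:
        seed = config.seed
    root = np.random.default_rng(np.random.SeedSequence(seed))
    fam_config = GeneratorConfig(
        **{**config.__dict__, "n_homologs": members_per_family}
    )
    families = tuple(
        generate_family(fam_config, f"fam{f}", stream)
        for f, stream in enumerate(root.spawn(n_families))
    )

    library: list[ProteinProfile] = []
    targets: list[ProteinProfile] = []
    fold_labels: dict[str, str] = {}
    target_labels: dict[str, str] = {}
    references: dict[str, Alignment] = {}
    for family in families:
        template, template_aln, _ = family.members[0]
        library.append(template)
        fold_labels[template.id] = family.family_id
        for profile, aln, _ in family.members[1:]:
            targets.append(profile)
            target_labels[profile.id] = family.family_id
            pairs = compose_alignments(aln, template_aln)
            references[profile.id] = Alignment(
                target_id=profile.id,
                template_id=template.id,
                target_len=len(profile),
                template_len=len(template),
                pairs=tuple(pairs),
                gap_runs=(),
                raw_score=float("nan"),
                adjusted_score=float("nan"),
                mode="glocal_both",
            )

    identities = {
        (target.id, template.id): sequence_identity(
            target.sequence, template.sequence
        )
        for target in targets
        for template in library
    }
    return Benchmark(
        families=families,
        library=tuple(library),
        targets=tuple(targets),
        fold_labels=fold_labels,
        target_labels=target_labels,
        references=references,
        identities=identities,
    )
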
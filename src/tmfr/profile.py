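"""Position profiles for transmembrane proteins.

A protein is represented by one :class:`PositionProfile` per residue,
bundling the four features the aligner scores: the sequence-derived
residue frequency vector, the PSSM log-odds vector, the topology segment
code (``H``/``B`` membrane-spanning, ``I`` inside loop, ``O`` outside
loop, ``U`` unknown), the TM-segment orientation (+1 for segments crossing
the membrane outside-to-inside, -1 for the opposite direction, 0 for
non-TM positions) and the predicted relative accessibility.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .io_formats import AccessibilityRecord, PssmRecord, TopologyRecord

TM_CODES = frozenset("HB")

#: Segment kinds, mapped from topology characters.
TM, INSIDE, OUTSIDE, UNKNOWN = "TM", "INSIDE", "OUTSIDE", "UNKNOWN"
_KIND_OF_CHAR = {"H": TM, "B": TM, "I": INSIDE, "O": OUTSIDE, "U": UNKNOWN}


@dataclass(frozen=True)
class PositionProfile:
    """Feature bundle for one residue position."""

    freq: np.ndarray          # 20-vector, sums to 1
    log_odds: np.ndarray      # 20-vector
    segment: str              # one of H B I O U
    orientation: int          # -1 / 0 / +1; 0 iff segment not in {H, B}
    asa: float                # relative accessibility in [0, 1]

    def __post_init__(self) -> None:
        f = np.asarray(self.freq, dtype=float)
        if f.shape != (20,) or abs(float(f.sum()) - 1.0) > 1e-6 or (f < 0).any():
            raise ValueError("freq must be a nonnegative 20-vector summing to 1")
        if (self.segment in TM_CODES) == (self.orientation == 0):
            raise ValueError(
                f"orientation {self.orientation} inconsistent with segment "
                f"{self.segment!r}: TM positions need +/-1, others 0"
            )
        if not 0.0 <= self.asa <= 1.0:
            raise ValueError(f"asa {self.asa} outside [0, 1]")
        object.__setattr__(self, "freq", f)
        object.__setattr__(self, "log_odds", np.asarray(self.log_odds, dtype=float))


@dataclass(frozen=True)
class Segment:
    """A maximal run of one segment kind, as a 0-based half-open interval."""

    kind: str
    start: int
    end: int
    orientation: int = 0


@dataclass(frozen=True)
class ProteinProfile:
    id: str
    sequence: str
    positions: tuple[PositionProfile, ...]
    segments: tuple[Segment, ...]
    tm_class: str  # "alpha" or "beta"

    def __len__(self) -> int:
        return len(self.positions)

    def topology_string(self) -> str:
        return "".join(p.segment for p in self.positions)

    # Cached dense feature arrays for the aligner (built lazily).
    _arrays: dict = field(default_factory=dict, compare=False, repr=False)

    def feature_arrays(self) -> dict:
        """Dense per-position arrays: freq (L,20), log_odds (L,20),
        segment codes (L,), orientation (L,), asa (L,), is_tm (L,)."""
        if not self._arrays:
            seg = np.frombuffer(
                self.topology_string().encode("ascii"), dtype=np.uint8
            )
            self._arrays.update(
                freq=np.asarray([p.freq for p in self.positions]),
                log_odds=np.asarray([p.log_odds for p in self.positions]),
                segment=seg,
                orientation=np.asarray([p.orientation for p in self.positions]),
                asa=np.asarray([p.asa for p in self.positions]),
                is_tm=np.isin(seg, np.frombuffer(b"HB", dtype=np.uint8)),
            )
        return self._arrays


def frequencies_from_pssm(pssm: PssmRecord, position: int) -> np.ndarray:
    """Residue frequency vector for one PSSM row.

    Uses the weighted observed percentages divided by 100 and renormalised;
    for all-zero percentage rows (which PSI-BLAST emits at some positions)
    falls back to ``softmax(log_odds / 2)`` so the row stays usable.
    """
    if not 0 <= position < len(pssm):
        raise IndexError(f"position {position} out of range for PSSM of length {len(pssm)}")
    row = pssm.percentages[position]
    if row.sum() > 0:
        return row / row.sum()
    z = pssm.log_odds[position] / 2.0
    z = z - z.max()
    e = np.exp(z)
    return e / e.sum()


def derive_segments(topology: TopologyRecord) -> list[Segment]:
    """Split a topology string into maximal same-character runs.

    Orientations are left at 0; :func:`assign_orientations` fills them in.
    """
    s = topology.topology
    segments: list[Segment] = []
    start = 0
    for i in range(1, len(s) + 1):
        if i == len(s) or _KIND_OF_CHAR[s[i]] != _KIND_OF_CHAR[s[start]] or s[i] != s[start]:
            segments.append(Segment(_KIND_OF_CHAR[s[start]], start, i))
            start = i
    return segments


def assign_orientations(segments: list[Segment]) -> list[Segment]:
    """Set TM-segment orientations from their flanking loops.

    A TM segment crossing outside-to-inside is +1; inside-to-outside is -1.
    Rules, in order: the preceding determined loop decides (OUTSIDE -> +1,
    INSIDE -> -1); otherwise the following loop (INSIDE -> +1, OUTSIDE ->
    -1); TM segments flanked only by UNKNOWN/sequence ends alternate away
    from the nearest determined TM segment, and a chain with no determined
    member starts at +1.  Non-TM segments are 0.  Idempotent: orientations
    are recomputed from kinds alone.
    """
    segs = [replace(s, orientation=0) for s in segments]
    tm_positions = [i for i, s in enumerate(segs) if s.kind == TM]
    if not tm_positions:
        return segs
    order = {seg_i: k for k, seg_i in enumerate(tm_positions)}
    determined: dict[int, int] = {}
    for i in tm_positions:
        prev_kind = segs[i - 1].kind if i > 0 else None
        next_kind = segs[i + 1].kind if i + 1 < len(segs) else None
        if prev_kind == OUTSIDE:
            determined[i] = +1
        elif prev_kind == INSIDE:
            determined[i] = -1
        elif next_kind == INSIDE:
            determined[i] = +1
        elif next_kind == OUTSIDE:
            determined[i] = -1
    oriented: dict[int, int] = dict(determined)
    for i in tm_positions:
        if i in oriented:
            continue
        k = order[i]
        nearest = min(
            determined,
            key=lambda j: (abs(order[j] - k), order[j]),
            default=None,
        )
        if nearest is None:
            oriented[i] = +1 if k % 2 == 0 else -1
        else:
            gap = abs(order[nearest] - k)
            oriented[i] = determined[nearest] * (-1) ** gap
    return [
        replace(s, orientation=oriented.get(i, 0)) for i, s in enumerate(segs)
    ]


def segments_for(topology: TopologyRecord) -> list[Segment]:
    """Segments with orientations, in one call."""
    return assign_orientations(derive_segments(topology))


def assemble_profile(
    seq_id: str,
    sequence: str,
    freq: np.ndarray,
    log_odds: np.ndarray,
    topology: str | TopologyRecord,
    asa: np.ndarray,
) -> ProteinProfile:
    """Build a :class:`ProteinProfile` from dense feature arrays.

    Shared by :func:`build_protein_profile` (file-derived features) and the
    synthetic generator (features drawn directly).
    """
    topo = topology if isinstance(topology, TopologyRecord) else TopologyRecord(topology)
    for name, length in (
        ("pssm", len(freq)),
        ("topology", len(topo)),
        ("asa", len(asa)),
    ):
        if length != len(sequence):
            raise ValueError(
                f"{name} length {length} does not match sequence length "
                f"{len(sequence)} for {seq_id!r}"
            )
    segments = tuple(segments_for(topo))
    orientation = np.zeros(len(sequence), dtype=int)
    for seg in segments:
        orientation[seg.start:seg.end] = seg.orientation
    positions = tuple(
        PositionProfile(
            freq=np.asarray(freq[i], dtype=float),
            log_odds=np.asarray(log_odds[i], dtype=float),
            segment=topo.topology[i],
            orientation=int(orientation[i]),
            asa=float(asa[i]),
        )
        for i in range(len(sequence))
    )
    tm_class = "beta" if "B" in topo.topology else "alpha"
    return ProteinProfile(seq_id, sequence, positions, segments, tm_class)


def build_protein_profile(
    seq_id: str,
    sequence: str,
    pssm: PssmRecord,
    topology: TopologyRecord,
    asa: AccessibilityRecord,
) -> ProteinProfile:
    """Assemble the four per-residue features into one profile.

    All four inputs must share the sequence length; a mismatch raises a
    ``ValueError`` naming the offending input.
    """
    if len(pssm) != len(sequence):
        raise ValueError(
            f"pssm length {len(pssm)} does not match sequence length "
            f"{len(sequence)} for {seq_id!r}"
        )
    freq = np.asarray(
        [frequencies_from_pssm(pssm, i) for i in range(len(pssm))]
    )
    return assemble_profile(
        seq_id, sequence, freq, pssm.log_odds, topology, np.asarray(asa.asa)
    )
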
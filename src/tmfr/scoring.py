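"""The TMFR scoring function.

Four per-position-pair fitness terms — profile compatibility, segment-type
match, TM-orientation match, and accessibility similarity — are combined
with trainable weights ``w1..w4`` and a constant shift into a *cost*:

    cost(i, j) = shift - (w1*profile + w2*segment + w3*orientation + w4*asa)

The dynamic program minimises total cost, so a lower raw score means a
better alignment; the shift makes weak matches cost-positive so that gaps
compete with them.  Gap penalties are segment-dependent: opening a gap
against a membrane-spanning residue costs significantly more than against
a loop residue, while gaps inside TM segments remain allowed.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import yaml

from .profile import TM_CODES, PositionProfile, ProteinProfile

#: Trained parameter vector for alpha-helical TM proteins, in the order
#: (w1, w2, w3, w4, shift, gap_open_tm, gap_ext_tm, gap_open_non,
#: gap_ext_non).  The order is this package's documented reading of the
#: published 9-tuple; see :func:`paper_parameters`.
ALPHA_PARAMETER_VECTOR = (1.6, 8.4, 6.7, 3.2, 4, 12.1, 1.6, 8.6, 1.1)

#: Trained parameter vector for beta-barrel TM proteins, kept verbatim.
#: It has ten values where nine parameters are defined; which value is
#: surplus is not recoverable, so using it requires an explicit mapping
#: (see :data:`BETA_MAPPINGS`).
BETA_PARAMETER_VECTOR = (1.5, 9.2, 4.3, 3.6, 5, 9.2, 11.8, 1.6, 8.3, 1.1)

#: Named 10->9 index mappings for the beta vector.  Each maps the nine
#: parameter slots (same order as :data:`ALPHA_PARAMETER_VECTOR`) to
#: indices of the 10-value vector.  Both candidates keep the TM open
#: penalty above the non-TM open penalty.
BETA_MAPPINGS: dict[str, tuple[int, ...]] = {
    # treat the sixth printed value as surplus
    "skip_sixth": (0, 1, 2, 3, 4, 6, 7, 8, 9),
    # treat the last printed value as surplus
    "skip_last": (0, 1, 2, 3, 4, 5, 6, 7, 8),
}


class AmbiguousParameterMappingError(ValueError):
    """Raised when the beta preset is requested without a mapping choice."""


@dataclass(frozen=True)
class ParameterSet:
    """The nine trainable scoring parameters.

    ``w_profile..w_asa`` weight the four fitness terms; ``shift`` is the
    constant subtracted-from offset; the four gap penalties are the
    open/extend costs for TM and non-TM segments.  Construction enforces
    ``gap_open_tm > gap_open_non`` (the TM open penalty is significantly
    larger than the non-TM one) and nonnegativity.
    """

    w_profile: float
    w_segment: float
    w_orientation: float
    w_asa: float
    shift: float
    gap_open_tm: float
    gap_ext_tm: float
    gap_open_non: float
    gap_ext_non: float

    def __post_init__(self) -> None:
        for name in ("w_profile", "w_segment", "w_orientation", "w_asa",
                     "gap_open_tm", "gap_ext_tm", "gap_open_non", "gap_ext_non"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if not self.gap_open_tm > self.gap_open_non:
            raise ValueError(
                f"gap_open_tm ({self.gap_open_tm}) must exceed gap_open_non "
                f"({self.gap_open_non})"
            )

    def as_vector(self) -> tuple[float, ...]:
        return (
            self.w_profile, self.w_segment, self.w_orientation, self.w_asa,
            self.shift, self.gap_open_tm, self.gap_ext_tm,
            self.gap_open_non, self.gap_ext_non,
        )

    @classmethod
    def from_vector(cls, vector) -> "ParameterSet":
        return cls(*map(float, vector))

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "ParameterSet":
        return cls(**yaml.safe_load(text))


def paper_parameters(
    tm_class: str, beta_mapping: str | None = None
) -> ParameterSet:
    """Published trained parameter presets.

    ``tm_class="alpha"`` returns the 9-value alpha vector under this
    package's documented order (w1..w4, shift, gap_open_tm, gap_ext_tm,
    gap_open_non, gap_ext_non).  The beta vector has ten printed values
    for nine parameters, so ``tm_class="beta"`` refuses to guess: pass
    ``beta_mapping`` naming one of :data:`BETA_MAPPINGS` to choose which
    value is surplus.  No value is ever dropped silently.
    """
    if tm_class == "alpha":
        return ParameterSet.from_vector(ALPHA_PARAMETER_VECTOR)
    if tm_class == "beta":
        if beta_mapping is None:
            raise AmbiguousParameterMappingError(
                "the published beta vector has 10 values for 9 parameters; "
                "pass beta_mapping=" + " or ".join(map(repr, BETA_MAPPINGS))
                + " to choose the mapping explicitly"
            )
        try:
            index = BETA_MAPPINGS[beta_mapping]
        except KeyError:
            raise AmbiguousParameterMappingError(
                f"unknown beta mapping {beta_mapping!r}; choose from "
                + ", ".join(BETA_MAPPINGS)
            ) from None
        return ParameterSet.from_vector(
            [BETA_PARAMETER_VECTOR[i] for i in index]
        )
    raise ValueError(f"tm_class must be 'alpha' or 'beta', got {tm_class!r}")


# ---------------------------------------------------------------------------
# Fitness terms (per position pair)
# ---------------------------------------------------------------------------

def profile_term(target_pos: PositionProfile, template_pos: PositionProfile) -> float:
    """Sequence-profile compatibility: target frequencies dotted with the
    template's log-odds.  Deliberately asymmetric."""
    return float(target_pos.freq @ template_pos.log_odds)


def segment_term(target_pos: PositionProfile, template_pos: PositionProfile) -> float:
    """Segment-type match: +1 for identical codes, -1 otherwise."""
    return 1.0 if target_pos.segment == template_pos.segment else -1.0


def orientation_term(target_pos: PositionProfile, template_pos: PositionProfile) -> float:
    """TM-orientation match: +1 same direction, -1 opposite, 0 whenever a
    non-TM position is involved (that comparison is not considered)."""
    a, b = target_pos.orientation, template_pos.orientation
    if a == 0 or b == 0:
        return 0.0
    return 1.0 if a == b else -1.0


def asa_term(target_pos: PositionProfile, template_pos: PositionProfile) -> float:
    """Accessibility similarity: 1 - |a_target - a_template|, in [0, 1]."""
    return 1.0 - abs(target_pos.asa - template_pos.asa)


def fitness_cost(
    target_pos: PositionProfile,
    template_pos: PositionProfile,
    params: ParameterSet,
) -> float:
    """Cost of pairing two positions (lower is better)."""
    return params.shift - (
        params.w_profile * profile_term(target_pos, template_pos)
        + params.w_segment * segment_term(target_pos, template_pos)
        + params.w_orientation * orientation_term(target_pos, template_pos)
        + params.w_asa * asa_term(target_pos, template_pos)
    )


def gap_penalties_at(
    profile: ProteinProfile, position: int, params: ParameterSet
) -> tuple[float, float]:
    """``(open, extend)`` penalties governing a gap that skips ``position``.

    Residues inside membrane-spanning segments take the TM pair, all
    others (including unknown-topology residues) the non-TM pair.  The
    governing residue is the one present in the gapped column, i.e. the
    residue the gap skips.
    """
    if not 0 <= position < len(profile):
        raise IndexError(
            f"position {position} out of range for profile of length {len(profile)}"
        )
    if profile.positions[position].segment in TM_CODES:
        return params.gap_open_tm, params.gap_ext_tm
    return params.gap_open_non, params.gap_ext_non


def gap_penalty_vectors(
    profile: ProteinProfile, params: ParameterSet
) -> tuple[np.ndarray, np.ndarray]:
    """Per-residue (open, extend) penalty vectors for a whole profile."""
    is_tm = profile.feature_arrays()["is_tm"]
    open_pen = np.where(is_tm, params.gap_open_tm, params.gap_open_non)
    ext_pen = np.where(is_tm, params.gap_ext_tm, params.gap_ext_non)
    return open_pen, ext_pen


def cost_matrix(
    target: ProteinProfile, template: ProteinProfile, params: ParameterSet
) -> np.ndarray:
    """Dense fitness-cost matrix, ``C[i, j] = fitness_cost(i, j, params)``.

    Vectorised equivalent of calling :func:`fitness_cost` per pair.
    """
    t = target.feature_arrays()
    m = template.feature_arrays()
    prof = t["freq"] @ m["log_odds"].T
    seg = np.where(t["segment"][:, None] == m["segment"][None, :], 1.0, -1.0)
    ot, om = t["orientation"][:, None], m["orientation"][None, :]
    orient = np.where(
        (ot == 0) | (om == 0), 0.0, np.where(ot == om, 1.0, -1.0)
    )
    asa = 1.0 - np.abs(t["asa"][:, None] - m["asa"][None, :])
    return params.shift - (
        params.w_profile * prof
        + params.w_segment * seg
        + params.w_orientation * orient
        + params.w_asa * asa
    )
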
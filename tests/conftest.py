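import numpy as np
import pytest

from tmfr.profile import assemble_profile
from tmfr.scoring import ParameterSet


def make_random_profile(rng, length, pid="p", alphabet="HIOU"):
    """A random profile with arbitrary legal topology — no biological
    structure, for exercising the aligner and scoring machinery."""
    topo = "".join(rng.choice(list(alphabet), size=length))
    freq = rng.dirichlet(np.ones(20), size=length)
    log_odds = rng.normal(0.0, 1.0, size=(length, 20))
    asa = rng.uniform(0.0, 1.0, size=length)
    seq = "".join(rng.choice(list("ACDEFGHIKL"), size=length))
    return assemble_profile(pid, seq, freq, log_odds, topo, asa)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_profile_factory():
    return make_random_profile


@pytest.fixture
def simple_params():
    """Friendly parameters: all weights 1, mild gaps."""
    return ParameterSet(1.0, 1.0, 1.0, 1.0, 0.0, 4.0, 1.0, 2.0, 0.5)


def make_pssm_text(rows, sequence, columns=None, percentages=None):
    """Assemble ASCII PSSM content from explicit rows (for fixtures)."""
    from tmfr.io_formats import AMINO_ACIDS

    columns = columns or AMINO_ACIDS
    letters = "   ".join(columns)
    lines = [
        "",
        "Last position-specific scoring matrix computed, weighted observed "
        "percentages rounded down, information per position, and relative "
        "weight of gapless real matches to pseudocounts",
        f"            {letters}   {letters}",
    ]
    for i, residue in enumerate(sequence):
        lo = " ".join(f"{v:>3d}" if float(v) == int(v) else f"{v:.3f}"
                      for v in rows[i])
        pc_row = percentages[i] if percentages is not None else [5] * 20
        pc = " ".join(f"{v:>3d}" if float(v) == int(v) else f"{v:.3f}"
                      for v in pc_row)
        lines.append(f"{i + 1:5d} {residue} {lo} {pc}  0.36 0.12")
    lines += ["", "                      K         Lambda", "Standard Ungapped    0.1377     0.3187", ""]
    return "\n".join(lines)
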
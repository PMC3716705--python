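"""Readers and writers for every on-disk format the tool touches.

Formats
-------
* PSI-BLAST ASCII PSSM (the ``-out_ascii_pssm`` dialect): parsed into a
  :class:`PssmRecord`.  Real PSI-BLAST output carries integer log-odds and
  integer percentages; the parser also tolerates floating-point values so
  that regenerated (synthetic) matrices round-trip losslessly.
* Topology strings over the alphabet ``{H, B, I, O, U}``: one character per
  residue, either as a single line or a 2-column TSV.
* Per-residue relative accessibility in ``[0, 1]``: 2-column TSV.
* Pairwise alignments: gapped FASTA (two records) and a pair-list TSV.
* Profile bundles: ``<id>.fasta`` / ``.pssm`` / ``.topo`` / ``.asa`` in one
  directory, plus an optional JSON sidecar caching the assembled profile.

All on-disk position indices are 1-based; everything in memory is 0-based.
"""

from __future__ import annotations

import io
import json
import os
from dataclasses import dataclass

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: Canonical amino-acid order used for every in-memory 20-vector.  This is
#: the column order PSI-BLAST prints in its ASCII PSSM header.
AMINO_ACIDS = "ARNDCQEGHILKMFPSTWYV"
AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

TOPOLOGY_ALPHABET = frozenset("HBIOU")


class FormatError(ValueError):
    """Raised when an on-disk file violates its format contract."""


# ---------------------------------------------------------------------------
# PSI-BLAST ASCII PSSM
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PssmRecord:
    """A parsed position-specific scoring matrix.

    Attributes
    ----------
    sequence:
        Query amino-acid string, one letter per matrix row.
    log_odds:
        ``(L, 20)`` array of log-odds scores in canonical column order.
    percentages:
        ``(L, 20)`` array of weighted observed percentages in ``[0, 100]``.
        Rows may be all-zero (PSI-BLAST emits these for some positions);
        otherwise a row sums to 100 within PSI-BLAST's rounding slack.
    """

    sequence: str
    log_odds: np.ndarray
    percentages: np.ndarray

    def __post_init__(self) -> None:
        lo = np.asarray(self.log_odds, dtype=float)
        pc = np.asarray(self.percentages, dtype=float)
        if lo.shape != (len(self.sequence), 20) or pc.shape != lo.shape:
            raise FormatError(
                f"PSSM shape mismatch: sequence length {len(self.sequence)}, "
                f"log-odds {lo.shape}, percentages {pc.shape}"
            )
        sums = pc.sum(axis=1)
        bad = ~((sums == 0.0) | (np.abs(sums - 100.0) <= 2.0))
        if bad.any():
            row = int(np.nonzero(bad)[0][0])
            raise FormatError(
                f"PSSM percentages row {row + 1} sums to {sums[row]:g}, "
                "expected 100 +/- 2 or all-zero"
            )
        object.__setattr__(self, "log_odds", lo)
        object.__setattr__(self, "percentages", pc)

    def __len__(self) -> int:
        return len(self.sequence)


def _format_number(x: float) -> str:
    if float(x) == int(x):
        return str(int(x))
    return f"{x:.4f}"


def parse_pssm(text: str) -> PssmRecord:
    """Parse PSI-BLAST ``-out_ascii_pssm`` content.

    The column order is taken from the file's own label line (40 residue
    letters: 20 for log-odds, 20 for percentages) and mapped onto the
    canonical :data:`AMINO_ACIDS` order — a permuted label line yields
    correspondingly permuted matrices, never a silent assumption of
    alphabetical order.  Footer statistics (K, Lambda) are ignored.
    """
    lines = text.splitlines()
    label_idx = None
    columns: list[str] = []
    for i, line in enumerate(lines):
        tokens = line.split()
        if len(tokens) == 40 and all(t in AA_INDEX for t in tokens):
            label_idx = i
            columns = tokens
            break
    if label_idx is None:
        raise FormatError("no PSSM column-label line (40 residue letters) found")

    seq_chars: list[str] = []
    log_rows: list[list[float]] = []
    pct_rows: list[list[float]] = []
    expected_pos = 0
    for lineno, line in enumerate(lines[label_idx + 1:], start=label_idx + 2):
        tokens = line.split()
        if not tokens:
            continue
        if not tokens[0].lstrip("-").isdigit():
            break  # footer statistics
        if len(tokens) < 42:
            raise FormatError(
                f"line {lineno}: PSSM data row has {len(tokens)} fields, "
                "expected at least 42 (index, residue, 40 values)"
            )
        expected_pos += 1
        if int(tokens[0]) != expected_pos:
            raise FormatError(
                f"line {lineno}: position index {tokens[0]} out of order "
                f"(expected {expected_pos})"
            )
        residue = tokens[1]
        if len(residue) != 1 or not residue.isalpha():
            raise FormatError(f"line {lineno}: bad residue field {residue!r}")
        try:
            values = [float(t) for t in tokens[2:42]]
        except ValueError as exc:
            raise FormatError(f"line {lineno}: non-numeric PSSM value: {exc}") from None
        seq_chars.append(residue)
        log_rows.append(values[:20])
        pct_rows.append(values[20:])

    if not seq_chars:
        raise FormatError("PSSM file contains no data rows")

    # Map file column order onto canonical order.
    perm_lo = [AA_INDEX[c] for c in columns[:20]]
    perm_pc = [AA_INDEX[c] for c in columns[20:]]
    log_odds = np.empty((len(seq_chars), 20))
    percentages = np.empty((len(seq_chars), 20))
    log_odds[:, perm_lo] = np.asarray(log_rows)
    percentages[:, perm_pc] = np.asarray(pct_rows)
    return PssmRecord("".join(seq_chars), log_odds, percentages)


def format_pssm(record: PssmRecord) -> str:
    """Render a :class:`PssmRecord` in the ASCII PSSM layout.

    ``parse_pssm(format_pssm(r))`` reproduces ``r`` exactly (values are
    written in full precision when non-integral).
    """
    out = io.StringIO()
    out.write("\n")
    out.write(
        "Last position-specific scoring matrix computed, weighted observed "
        "percentages rounded down, information per position, and relative "
        "weight of gapless real matches to pseudocounts\n"
    )
    letters = "   ".join(AMINO_ACIDS)
    out.write(f"            {letters}   {letters}\n")
    for i, residue in enumerate(record.sequence):
        lo = " ".join(f"{_format_number(v):>7s}" for v in record.log_odds[i])
        pc = " ".join(f"{_format_number(v):>7s}" for v in record.percentages[i])
        out.write(f"{i + 1:5d} {residue} {lo} {pc}  0.00 0.00\n")
    out.write("\n")
    return out.getvalue()


# ---------------------------------------------------------------------------
# Topology strings
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TopologyRecord:
    """Per-residue membrane topology over ``{H, B, I, O, U}``.

    A protein is either alpha-type (helices, ``H``) or beta-type (strands,
    ``B``); a record never mixes the two TM letters.
    """

    topology: str

    def __post_init__(self) -> None:
        for pos, ch in enumerate(self.topology, start=1):
            if ch not in TOPOLOGY_ALPHABET:
                raise FormatError(
                    f"illegal topology character {ch!r} at position {pos}"
                )
        if "H" in self.topology and "B" in self.topology:
            raise FormatError("topology mixes H (helix) and B (strand) segments")

    def __len__(self) -> int:
        return len(self.topology)


def read_topology(text: str) -> TopologyRecord:
    """Read a topology string from single-line or 2-column TSV form."""
    stripped = [ln for ln in text.splitlines() if ln.strip()]
    if not stripped:
        raise FormatError("empty topology input")
    if len(stripped) == 1 and "\t" not in stripped[0]:
        return TopologyRecord(stripped[0].strip())
    chars: list[str] = []
    for lineno, line in enumerate(stripped, start=1):
        fields = line.split("\t")
        if len(fields) != 2:
            raise FormatError(f"line {lineno}: expected 2 TSV fields")
        pos = int(fields[0])
        if pos != len(chars) + 1:
            raise FormatError(f"line {lineno}: position {pos} out of order")
        chars.append(fields[1].strip())
    return TopologyRecord("".join(chars))


def write_topology(record: TopologyRecord) -> str:
    """Write a topology record in single-line form (newline-terminated)."""
    return record.topology + "\n"


# ---------------------------------------------------------------------------
# Accessibility tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AccessibilityRecord:
    """Predicted relative accessibility, one value in ``[0, 1]`` per residue."""

    asa: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.asa, dtype=float)
        if arr.ndim != 1:
            raise FormatError("accessibility must be a 1-D vector")
        if ((arr < 0.0) | (arr > 1.0)).any():
            pos = int(np.nonzero((arr < 0.0) | (arr > 1.0))[0][0])
            raise FormatError(
                f"accessibility value {arr[pos]:g} at position {pos + 1} "
                "outside [0, 1]"
            )
        object.__setattr__(self, "asa", arr)

    def __len__(self) -> int:
        return len(self.asa)


def read_asa(text: str) -> AccessibilityRecord:
    """Read an accessibility table (TSV: 1-based position, value)."""
    values: list[float] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != 2:
            raise FormatError(f"line {lineno}: expected 2 TSV fields")
        pos = int(fields[0])
        if pos != len(values) + 1:
            raise FormatError(
                f"line {lineno}: missing or out-of-order position "
                f"(got {pos}, expected {len(values) + 1})"
            )
        values.append(float(fields[1]))
    if not values:
        raise FormatError("empty accessibility input")
    return AccessibilityRecord(np.asarray(values))


def write_asa(record: AccessibilityRecord) -> str:
    """Write an accessibility table to 6 decimal places."""
    return "".join(
        f"{i + 1}\t{v:.6f}\n" for i, v in enumerate(record.asa)
    )


# ---------------------------------------------------------------------------
# Alignment renderings
# ---------------------------------------------------------------------------

def alignment_to_fasta(alignment, target_id: str, target_seq: str,
                       template_id: str, template_seq: str) -> str:
    """Render an alignment as pairwise gapped FASTA (two records).

    Unpaired residues between (or outside) aligned pairs are emitted as
    gap columns: template-side residues first, then target-side residues,
    a fixed order so output is byte-reproducible.
    """
    trow: list[str] = []
    mrow: list[str] = []
    ti = mi = 0
    for t, m in alignment.pairs:
        while mi < m:
            trow.append("-")
            mrow.append(template_seq[mi])
            mi += 1
        while ti < t:
            trow.append(target_seq[ti])
            mrow.append("-")
            ti += 1
        trow.append(target_seq[ti])
        mrow.append(template_seq[mi])
        ti += 1
        mi += 1
    while mi < len(template_seq):
        trow.append("-")
        mrow.append(template_seq[mi])
        mi += 1
    while ti < len(target_seq):
        trow.append(target_seq[ti])
        mrow.append("-")
        ti += 1
    records = [
        SeqRecord(Seq("".join(trow)), id=target_id, description=""),
        SeqRecord(Seq("".join(mrow)), id=template_id, description=""),
    ]
    buf = io.StringIO()
    SeqIO.write(records, buf, "fasta")
    return buf.getvalue()


def alignment_to_tsv(alignment, target_id: str, template_id: str) -> str:
    """Render an alignment as a TSV of 1-based aligned position pairs."""
    out = io.StringIO()
    out.write(f"# target\t{target_id}\n")
    out.write(f"# template\t{template_id}\n")
    out.write(f"# raw_score\t{alignment.raw_score:.6f}\n")
    out.write(f"# adjusted_score\t{alignment.adjusted_score:.6f}\n")
    for t, m in alignment.pairs:
        out.write(f"{t + 1}\t{m + 1}\n")
    return out.getvalue()


def read_alignment_tsv(text: str) -> tuple[list[tuple[int, int]], float, float]:
    """Read back an alignment TSV; returns (pairs, raw_score, adjusted_score)."""
    pairs: list[tuple[int, int]] = []
    raw = adj = float("nan")
    for line in text.splitlines():
        if not line.strip():
            continue
        if line.startswith("#"):
            fields = line[1:].strip().split("\t")
            if fields[0] == "raw_score":
                raw = float(fields[1])
            elif fields[0] == "adjusted_score":
                adj = float(fields[1])
            continue
        t, m = line.split("\t")
        pairs.append((int(t) - 1, int(m) - 1))
    return pairs, raw, adj


def write_alignment(alignment, target, template) -> tuple[str, str]:
    """Produce both renderings of an alignment.

    Parameters are the alignment and the two profiles (anything with
    ``id`` and ``sequence`` attributes).  Returns ``(fasta, tsv)``.
    """
    fasta = alignment_to_fasta(
        alignment, target.id, target.sequence, template.id, template.sequence
    )
    tsv = alignment_to_tsv(alignment, target.id, template.id)
    return fasta, tsv


def write_ranking(result, path=None) -> str:
    """Render a ranking report TSV (rank, template_id, raw, adjusted)."""
    out = io.StringIO()
    out.write("rank\ttemplate_id\traw_score\tadjusted_score\n")
    for rank, (template_id, raw, adj) in enumerate(result.entries, start=1):
        out.write(f"{rank}\t{template_id}\t{raw:.6f}\t{adj:.6f}\n")
    text = out.getvalue()
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


# ---------------------------------------------------------------------------
# Profile bundles
# ---------------------------------------------------------------------------

def write_fasta(seq_id: str, sequence: str) -> str:
    buf = io.StringIO()
    SeqIO.write([SeqRecord(Seq(sequence), id=seq_id, description="")], buf, "fasta")
    return buf.getvalue()


def read_fasta(text: str) -> tuple[str, str]:
    records = list(SeqIO.parse(io.StringIO(text), "fasta"))
    if len(records) != 1:
        raise FormatError(f"expected exactly one FASTA record, found {len(records)}")
    return records[0].id, str(records[0].seq)


def write_bundle(profile, directory: str | os.PathLike, sidecar: bool = True) -> None:
    """Write a profile bundle (``<id>.fasta/.pssm/.topo/.asa`` [+ sidecar]).

    The PSSM percentages are the profile's frequency vectors times 100, so
    a bundle written from an assembled profile reads back to the same
    frequencies (the JSON sidecar preserves them to full precision).
    """
    os.makedirs(directory, exist_ok=True)
    base = os.path.join(str(directory), profile.id)
    with open(base + ".fasta", "w") as fh:
        fh.write(write_fasta(profile.id, profile.sequence))
    freq = np.asarray([p.freq for p in profile.positions])
    log_odds = np.asarray([p.log_odds for p in profile.positions])
    record = PssmRecord(profile.sequence, log_odds, freq * 100.0)
    with open(base + ".pssm", "w") as fh:
        fh.write(format_pssm(record))
    with open(base + ".topo", "w") as fh:
        fh.write(profile.topology_string() + "\n")
    asa = np.asarray([p.asa for p in profile.positions])
    with open(base + ".asa", "w") as fh:
        fh.write(write_asa(AccessibilityRecord(asa)))
    if sidecar:
        payload = {
            "id": profile.id,
            "sequence": profile.sequence,
            "topology": profile.topology_string(),
            "freq": freq.tolist(),
            "log_odds": log_odds.tolist(),
            "asa": asa.tolist(),
        }
        with open(base + ".profile.json", "w") as fh:
            json.dump(payload, fh)


def read_bundle(directory: str | os.PathLike, seq_id: str, use_sidecar: bool = True):
    """Read a profile bundle back into a ``ProteinProfile``.

    Prefers the JSON sidecar when present (exact frequencies); otherwise
    assembles the profile from the four component files.
    """
    from .profile import assemble_profile, build_protein_profile

    base = os.path.join(str(directory), seq_id)
    sidecar_path = base + ".profile.json"
    if use_sidecar and os.path.exists(sidecar_path):
        with open(sidecar_path) as fh:
            payload = json.load(fh)
        return assemble_profile(
            payload["id"],
            payload["sequence"],
            np.asarray(payload["freq"]),
            np.asarray(payload["log_odds"]),
            payload["topology"],
            np.asarray(payload["asa"]),
        )
    with open(base + ".fasta") as fh:
        seq_id_read, sequence = read_fasta(fh.read())
    with open(base + ".pssm") as fh:
        pssm = parse_pssm(fh.read())
    with open(base + ".topo") as fh:
        topo = read_topology(fh.read())
    with open(base + ".asa") as fh:
        asa = read_asa(fh.read())
    return build_protein_profile(seq_id_read, sequence, pssm, topo, asa)


def list_bundle_ids(directory: str | os.PathLike) -> list[str]:
    """IDs of all profile bundles in a directory (by ``.fasta`` presence)."""
    return sorted(
        name[:-6]
        for name in os.listdir(str(directory))
        if name.endswith(".fasta")
    )
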
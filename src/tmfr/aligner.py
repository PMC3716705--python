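"""Local-global dynamic programming with segment-dependent affine gaps.

Three DP layers are kept per cell: ``M`` (the cell's two residues are
paired), ``Y`` (the target residue is skipped — gap character in the
template row) and ``X`` (the template residue is skipped — gap character
in the target row).  The recurrence minimises total cost; a gap run costs
the *open* penalty of its first skipped residue plus the *extend* penalty
of each further skipped residue, with the penalty class (TM vs non-TM)
chosen per skipped residue.  Gaps may open inside membrane-spanning
segments — they are only penalised harder, never forbidden.

Modes
-----
``global``
    Every residue of both sequences is consumed; end gaps are penalised.
``glocal_template`` (default)
    Fold-recognition threading: the target aligns in full, while end gaps
    in the template are free (template overhangs cost nothing).
``glocal_both``
    End gaps are free in both sequences: the aligned core starts and ends
    with a pair, leading/trailing residues of either sequence cost
    nothing, and at least one pair is required.

Ties are broken deterministically: pair over gap, gap-in-template over
gap-in-target, then the lower template index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .profile import ProteinProfile
from .scoring import ParameterSet, cost_matrix, gap_penalty_vectors

_INF = np.inf
#: Layer indices, in tie-break preference order (pair, gap-in-template,
#: gap-in-target).
_M, _Y, _X = 0, 1, 2

MODES = ("global", "glocal_template", "glocal_both")


@dataclass(frozen=True)
class Alignment:
    """An optimal pairwise alignment and its scores.

    ``pairs`` are 0-based ``(target_index, template_index)`` tuples,
    strictly increasing in both coordinates.  ``gap_runs`` lists the
    *penalised* gap runs as ``(sequence, start, length)`` where
    ``sequence`` names the sequence whose residues the run skips; free
    end gaps (glocal modes) are not listed.  ``raw_score`` is the total
    cost of the DP path (lower is better); ``adjusted_score`` adds the
    length-difference correction.
    """

    target_id: str
    template_id: str
    target_len: int
    template_len: int
    pairs: tuple[tuple[int, int], ...]
    gap_runs: tuple[tuple[str, int, int], ...]
    raw_score: float
    adjusted_score: float
    mode: str = "glocal_template"

    def __post_init__(self) -> None:
        last_t = last_m = -1
        for t, m in self.pairs:
            if t <= last_t or m <= last_m:
                raise ValueError("alignment pairs must be strictly increasing")
            last_t, last_m = t, m


def _affine_prefix(open_pen: np.ndarray, ext_pen: np.ndarray) -> np.ndarray:
    """Cost of skipping residues ``0..j-1`` as one run, for j = 0..L."""
    L = len(open_pen)
    out = np.empty(L + 1)
    out[0] = 0.0
    if L:
        out[1] = open_pen[0]
        out[2:] = open_pen[0] + np.cumsum(ext_pen[1:])
    return out


def align(
    target: ProteinProfile,
    template: ProteinProfile,
    params: ParameterSet,
    mode: str = "glocal_template",
    kappa: float = 1.0,
) -> Alignment:
    """Optimal minimum-cost alignment of a target to a template.

    Raises on empty profiles, unknown modes and cross-class pairs
    (alpha-helical vs beta-barrel proteins are never aligned).
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
    if len(target) == 0 or len(template) == 0:
        raise ValueError("cannot align empty profiles")
    if target.tm_class != template.tm_class:
        raise ValueError(
            f"cross-class alignment rejected: target is {target.tm_class}, "
            f"template is {template.tm_class}"
        )

    n, m = len(target), len(template)
    C = cost_matrix(target, template, params)
    open_t, ext_t = gap_penalty_vectors(template, params)   # skipped template residue
    open_i, ext_i = gap_penalty_vectors(target, params)     # skipped target residue

    M = np.full((n + 1, m + 1), _INF)
    X = np.full((n + 1, m + 1), _INF)
    Y = np.full((n + 1, m + 1), _INF)
    M[0, 0] = 0.0
    start_free = mode == "glocal_both"
    if mode == "global":
        X[0, 1:] = _affine_prefix(open_t, ext_t)[1:]
        Y[1:, 0] = _affine_prefix(open_i, ext_i)[1:]
    elif mode == "glocal_template":
        X[0, 1:] = 0.0
        Y[1:, 0] = _affine_prefix(open_i, ext_i)[1:]
    # glocal_both: no free row/column — cores start at any pair instead.

    # Prefix sums of template extend penalties, for the in-row X scan:
    # skipping residues k..j-1 by extension costs E[j] - E[k].
    E = np.concatenate(([0.0], np.cumsum(ext_t)))

    for i in range(1, n + 1):
        prev_best = np.minimum(np.minimum(M[i - 1], X[i - 1]), Y[i - 1])
        base = np.minimum(prev_best[:-1], 0.0) if start_free else prev_best[:-1]
        M[i, 1:] = C[i - 1] + base
        # Y opens only after a pair (X may follow Y, not vice versa): the
        # unaligned block between two pairs is canonically ordered as one
        # target-skip run then one template-skip run, so each run is
        # charged exactly one open — matching the alignment-space cost
        # model for any penalty values.
        Y[i, 1:] = np.minimum(
            M[i - 1, 1:] + open_i[i - 1],
            Y[i - 1, 1:] + ext_i[i - 1],
        )
        if i == 1 and mode == "glocal_template":
            # a target-skip run may also start right after the free
            # template prefix
            Y[1, 1:] = np.minimum(Y[1, 1:], X[0, 1:] + open_i[0])
        # X[i, j] = min_k<=j ( open-entry at k + extensions k..j-1 ):
        # a min-plus prefix scan over c[k] = min(M, Y)[i, k-1] + open_t[k-1].
        c = np.full(m + 1, _INF)
        c[1:] = np.minimum(M[i, :-1], Y[i, :-1]) + open_t
        X[i] = E + np.minimum.accumulate(c - E)

    layers = (M, Y, X)
    eps = 1e-9

    def better(value: float, best: float) -> bool:
        return value < best - eps

    # Choose the end state per mode (lowest template index wins ties; the
    # layer tuple order encodes the match > gap-in-template > gap-in-target
    # preference).
    if mode == "global":
        end_i, end_j = n, m
        best_val, best_layer = _INF, _M
        for layer in (_M, _Y, _X):
            v = layers[layer][n, m]
            if better(v, best_val):
                best_val, best_layer = v, layer
    elif mode == "glocal_template":
        best_val, best_layer, end_j = _INF, _M, m
        for j in range(0, m + 1):
            for layer in (_M, _Y):
                v = layers[layer][n, j]
                if better(v, best_val):
                    best_val, best_layer, end_j = v, layer, j
        end_i = n
    else:  # glocal_both: restrict ends to pair cells, enforcing >= 1 pair
        best_val, end_i, end_j = _INF, 1, 1
        for i in range(1, n + 1):
            for j in range(1, m + 1):
                if better(M[i, j], best_val):
                    best_val, end_i, end_j = M[i, j], i, j
        best_layer = _M
        if not np.isfinite(best_val):
            raise ValueError("glocal_both alignment must contain at least one pair")

    pairs, gap_runs = _traceback(
        layers, C, open_t, ext_t, open_i, ext_i, mode, end_i, end_j, best_layer, eps
    )
    raw = float(best_val)
    adjusted = adjusted_score(raw, n, m, kappa)
    return Alignment(
        target_id=target.id,
        template_id=template.id,
        target_len=n,
        template_len=m,
        pairs=tuple(pairs),
        gap_runs=tuple(gap_runs),
        raw_score=raw,
        adjusted_score=adjusted,
        mode=mode,
    )


def _traceback(layers, C, open_t, ext_t, open_i, ext_i, mode,
               i, j, layer, eps):
    M, Y, X = layers
    pairs: list[tuple[int, int]] = []
    runs: list[tuple[str, int, int]] = []
    run_seq: str | None = None
    run_start = run_len = 0

    def flush_run():
        nonlocal run_seq, run_start, run_len
        if run_seq is not None:
            runs.append((run_seq, run_start, run_len))
            run_seq = None

    free_x_row0 = mode == "glocal_template"
    free_y_col0 = False
    start_free = mode == "glocal_both"
    _START = -1

    while i > 0 or j > 0:
        if layer == _M:
            pairs.append((i - 1, j - 1))
            flush_run()
            target_val = M[i, j] - C[i - 1, j - 1]
            i, j = i - 1, j - 1
            cands = [(_M, M[i, j]), (_Y, Y[i, j]), (_X, X[i, j])]
            if start_free:
                cands.append((_START, 0.0))
            layer = _pick(cands, target_val, eps)
            if layer == _START:
                break
        elif layer == _X:
            if i == 0 and free_x_row0:
                break  # free template prefix
            # penalised column skipping template residue j-1
            if run_seq == "template":
                run_start, run_len = j - 1, run_len + 1
            else:
                flush_run()
                run_seq, run_start, run_len = "template", j - 1, 1
            target_val = X[i, j]
            j -= 1
            if j == 0 and i == 0:
                break
            cands = [
                (_M, M[i, j] + open_t[j]),
                (_Y, Y[i, j] + open_t[j]),
                (_X, X[i, j] + ext_t[j]),
            ]
            if i == 0:
                # row 0: only X is populated left of us
                cands = [(_X, X[i, j] + (0.0 if free_x_row0 else ext_t[j]))]
                if j == 0:
                    break
            layer = _pick(cands, target_val, eps)
        else:  # _Y
            if j == 0 and free_y_col0:
                break
            if run_seq == "target":
                run_start, run_len = i - 1, run_len + 1
            else:
                flush_run()
                run_seq, run_start, run_len = "target", i - 1, 1
            target_val = Y[i, j]
            i -= 1
            if i == 0 and j == 0:
                break
            cands = [
                (_M, M[i, j] + open_i[i]),
                (_Y, Y[i, j] + ext_i[i]),
            ]
            if i == 0 and free_x_row0:
                # run opened straight after the free template prefix
                cands.append((_X, X[i, j] + open_i[i]))
            if j == 0:
                cands = [(_Y, Y[i, j] + (0.0 if free_y_col0 else ext_i[i]))]
                if i == 0:
                    break
            layer = _pick(cands, target_val, eps)

    flush_run()
    pairs.reverse()
    runs.reverse()
    return pairs, runs


def _pick(candidates, target_val, eps):
    """First candidate (in preference order) matching the DP cell value."""
    best_layer, best_val = None, _INF
    for layer, value in candidates:
        if value < best_val - eps:
            best_layer, best_val = layer, value
    for layer, value in candidates:
        if abs(value - target_val) <= eps:
            return layer
    return best_layer  # numerical fallback: closest consistent choice


def raw_score(
    alignment: Alignment,
    target: ProteinProfile,
    template: ProteinProfile,
    params: ParameterSet,
) -> float:
    """Recompute the path cost of an alignment from scratch.

    Sums the fitness cost over aligned pairs plus, for every penalised gap
    run, the open penalty of its first skipped residue and the extend
    penalty of each further one.  Agrees with the DP-reported
    ``raw_score`` to 1e-6 (self-consistency contract).
    """
    C = cost_matrix(target, template, params)
    total = float(sum(C[t, m] for t, m in alignment.pairs))
    for seq, start, length in alignment.gap_runs:
        profile = template if seq == "template" else target
        open_pen, ext_pen = gap_penalty_vectors(profile, params)
        total += open_pen[start] + float(ext_pen[start + 1:start + length].sum())
    return total


def adjusted_score(
    raw: float, target_len: int, template_len: int, kappa: float = 1.0
) -> float:
    """Length-adjusted score: ``raw + kappa * |L_target - L_template|``.

    Penalises (raises) the score as the length difference grows, so
    templates of similar length to the target are favoured in ranking.
    """
    if target_len < 1 or template_len < 1:
        raise ValueError("lengths must be >= 1")
    if kappa < 0:
        raise ValueError("kappa must be nonnegative")
    return raw + kappa * abs(target_len - template_len)
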
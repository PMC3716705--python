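"""Independent brute-force alignment oracle for small instances.

Enumerates every monotone pair set (every possible alignment) explicitly
and computes its cost directly from the scoring definitions — no dynamic
programming, no sharing of code paths with the aligner beyond the scoring
primitives it is meant to check.
"""

from itertools import combinations

from tmfr.scoring import fitness_cost, gap_penalties_at


def _run_cost(profile, params, start, end):
    """Cost of skipping profile positions [start, end) as one gap run."""
    if start >= end:
        return 0.0
    total = gap_penalties_at(profile, start, params)[0]
    for pos in range(start + 1, end):
        total += gap_penalties_at(profile, pos, params)[1]
    return total


def brute_force_best(target, template, params, mode="glocal_template"):
    """Minimum alignment cost by exhaustive enumeration.

    Only feasible for lengths of about 6 or less.
    """
    n, m = len(target), len(template)
    C = [
        [
            fitness_cost(target.positions[i], template.positions[j], params)
            for j in range(m)
        ]
        for i in range(n)
    ]
    free_target_ends = mode == "glocal_both"
    free_template_ends = mode in ("glocal_template", "glocal_both")

    def alignment_cost(pairs):
        cost = sum(C[t][mm] for t, mm in pairs)
        # internal gap runs between consecutive pairs
        for (t1, m1), (t2, m2) in zip(pairs, pairs[1:]):
            cost += _run_cost(target, params, t1 + 1, t2)
            cost += _run_cost(template, params, m1 + 1, m2)
        first_t, first_m = pairs[0]
        last_t, last_m = pairs[-1]
        if not free_target_ends:
            cost += _run_cost(target, params, 0, first_t)
            cost += _run_cost(target, params, last_t + 1, n)
        if not free_template_ends:
            cost += _run_cost(template, params, 0, first_m)
            cost += _run_cost(template, params, last_m + 1, m)
        return cost

    best = None
    if mode != "glocal_both":
        # the empty alignment: both sequences fully gapped (target run is
        # always penalised; template run only in global mode)
        best = _run_cost(target, params, 0, n)
        if mode == "global":
            best += _run_cost(template, params, 0, m)
    for k in range(1, min(n, m) + 1):
        for t_idx in combinations(range(n), k):
            for m_idx in combinations(range(m), k):
                cost = alignment_cost(list(zip(t_idx, m_idx)))
                if best is None or cost < best:
                    best = cost
    return best
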
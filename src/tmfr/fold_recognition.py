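"""Template ranking and fold-recognition metrics.

A target is aligned against every template in a library; templates are
ranked by ascending score (lower is better).  Ranking uses the
length-adjusted score by default, with raw-score ranking available, since
the method reports both.  Top-k recognition accuracy and the raw-score /
structure-similarity correlation are computed from the rankings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .aligner import align
from .profile import ProteinProfile
from .scoring import ParameterSet


@dataclass(frozen=True)
class RankingResult:
    """Templates ordered for one target, best (lowest score) first.

    ``entries`` are ``(template_id, raw_score, adjusted_score)`` tuples
    sorted ascending by the ranking score with lexicographic template-id
    tie-breaking, so the order is deterministic.
    """

    target_id: str
    entries: tuple[tuple[str, float, float], ...]
    rank_by: str = "adjusted"

    def rank_of(self, template_id: str) -> int:
        """1-based rank of a template; raises if absent."""
        for rank, (tid, _, _) in enumerate(self.entries, start=1):
            if tid == template_id:
                return rank
        raise KeyError(template_id)


def rank_templates(
    target: ProteinProfile,
    library: list[ProteinProfile],
    params: ParameterSet,
    mode: str = "glocal_template",
    kappa: float = 1.0,
    rank_by: str = "adjusted",
    exclude_self: bool = False,
) -> RankingResult:
    """Align a target to every library template and rank the results.

    ``rank_by`` is ``"adjusted"`` (default) or ``"raw"``.  With
    ``exclude_self`` the library entry whose id equals the target's is
    skipped (self-alignments are removed in benchmarking).
    """
    if rank_by not in ("adjusted", "raw"):
        raise ValueError(f"rank_by must be 'adjusted' or 'raw', got {rank_by!r}")
    if not library:
        raise ValueError("template library is empty")
    entries = []
    for template in library:
        if exclude_self and template.id == target.id:
            continue
        aln = align(target, template, params, mode=mode, kappa=kappa)
        entries.append((template.id, aln.raw_score, aln.adjusted_score))
    if not entries:
        raise ValueError("library contains only the target itself")
    key_index = 2 if rank_by == "adjusted" else 1
    entries.sort(key=lambda e: (e[key_index], e[0]))
    return RankingResult(target.id, tuple(entries), rank_by=rank_by)


def topk_accuracy(
    rankings: list[RankingResult],
    fold_labels: dict[str, str],
    target_labels: dict[str, str],
    k: int,
) -> float:
    """Percentage of targets whose top-k templates include a fold match.

    ``fold_labels`` maps template ids to fold ids, ``target_labels`` maps
    target ids likewise; every ranked template and target must be
    labelled.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if not rankings:
        raise ValueError("no rankings supplied")
    hits = 0
    for ranking in rankings:
        try:
            target_fold = target_labels[ranking.target_id]
        except KeyError:
            raise KeyError(f"no fold label for target {ranking.target_id!r}") from None
        top = ranking.entries[:k]
        for template_id, _, _ in top:
            try:
                template_fold = fold_labels[template_id]
            except KeyError:
                raise KeyError(
                    f"no fold label for template {template_id!r}"
                ) from None
            if template_fold == target_fold:
                hits += 1
                break
    return 100.0 * hits / len(rankings)


def score_similarity_correlation(raw_scores, similarities) -> float:
    """Pearson correlation between raw scores and structure similarities.

    A well-behaved scoring function yields a negative coefficient: lower
    (better) raw scores go with higher similarity.
    """
    x = np.asarray(raw_scores, dtype=float)
    y = np.asarray(similarities, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("raw_scores and similarities must be equal-length 1-D")
    if len(x) < 3:
        raise ValueError("need at least 3 points for a correlation")
    if np.std(x) == 0.0 or np.std(y) == 0.0:
        raise ValueError("degenerate input: zero variance")
    return float(stats.pearsonr(x, y).statistic)
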
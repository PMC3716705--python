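# Methods

## Model

A transmembrane protein (TMP) is represented as a sequence of position
profiles. Four per-position features feed the alignment:

1. **Sequence profile.** The residue frequency vector `f` comes from the
   PSI-BLAST weighted observed percentages (divided by 100 and
   renormalised). Rows whose percentages are all zero — PSI-BLAST emits
   these at some positions — fall back to `softmax(log_odds / 2)`; the
   temperature 2 simply softens the integer log-odds into a usable
   distribution. The log-odds vector `M` is used as-is, unscaled: the
   profile-compatibility term is the plain dot product `Σ_r f_target(r) ·
   M_template(r)`, deliberately asymmetric (target frequencies against
   template log-odds), and no 20×20 substitution matrix is involved
   anywhere.
2. **Segment type** `s ∈ {H, B, I, O, U}` from the predicted topology
   string. Both target and template are expected to carry *predicted*
   topology, so their errors are correlated rather than compounded;
   nothing stops a caller from supplying known template topology instead.
   `U` (unknown) participates in scoring as a genuine fifth code — it is
   never imputed, since the predictor made no claim there.
3. **Segment orientation** `o ∈ {−1, 0, +1}`: which way a
   membrane-spanning segment crosses the bilayer (+1 outside→inside).
   Orientations are derived from the topology string, not stored.
4. **Relative accessibility** `a ∈ [0, 1]` from an external predictor
   (target and template both predicted, for the same consistency reason).

The pair cost is `shift − (w1·profile + w2·segment + w3·orientation +
w4·asa)` and the aligner *minimises*; the raw score of the optimal path
is therefore better when lower, and the shift decides when pairing weak
matches loses to opening a gap. The segment term is +1 on identical
codes and −1 otherwise; the orientation term is +1/−1 for equal/opposite
nonzero orientations and 0 whenever a non-TM position is involved; the
accessibility term is `1 − |Δa|`. The segment and accessibility forms
are this package's choices — they are the simplest forms consistent with
the orientation term's published ±1/0 convention, and both are isolated
behind single functions (`segment_term`, `asa_term`) so alternates can be
swapped without touching the aligner.

### Orientation recovery from noisy strings

Published convention defines only the encoding; recovering orientations
from arbitrary legal strings needs tie-break rules, which are this
package's own: the preceding determined loop decides (OUTSIDE→+1,
INSIDE→−1), else the following loop (INSIDE→+1, OUTSIDE→−1); TM segments
flanked only by unknowns alternate away from the nearest determined TM
segment; a chain with no determined member starts at +1. The procedure
is idempotent and guarantees nonzero orientation exactly on TM
positions.

## Alignment

Three-layer affine dynamic programming (pair / gap-in-template /
gap-in-target), minimising. A gap run skipping residues `k..l` of one
sequence costs `open(k) + Σ ext(k+1..l)`, where each residue contributes
the TM or non-TM penalty according to *its own* segment — the governing
residue is the one present in the gapped column, i.e. the residue being
skipped. Gaps may open inside TM segments; they are only penalised
harder (`gap_open_tm > gap_open_non` is enforced at parameter
construction). Within the unaligned block between two pairs the
target-skip run is placed before the template-skip run, so each run is
charged exactly one open regardless of penalty values; this makes the DP
minimum coincide with the minimum over all monotone pair sets, which the
test suite verifies by exhaustive enumeration on small instances.

Three modes are exposed because "local-global" underdetermines which
sequence is global:

- `glocal_template` (default): the target aligns in full; template end
  gaps are free. This is the fold-recognition threading geometry.
- `global`: all end gaps penalised.
- `glocal_both`: end gaps free in both sequences; the aligned core must
  contain at least one pair.

Ties are broken deterministically (pair over gap, gap-in-template over
gap-in-target, lower template index), so alignments are bit-reproducible.
The row recurrences are vectorised in numpy; the within-row gap layer is
computed as a min-plus prefix scan (`running_min(c − E) + E` with `E` the
prefix sums of extend penalties), giving O(n·m) work with O(m)-vector
operations. Traceback matches candidate transitions to cell values with
a 1e-9 tolerance to absorb the scan's floating-point reassociation.

The adjusted score is `S_raw + κ·|L_target − L_template|` with κ = 1.0
by default. The published adjustment is known only to favour templates
of similar length; the additive form is the simplest with that property
and is isolated in `adjusted_score`. Ranking uses the adjusted score by
default with raw-score ranking one flag away, since both are defensible
readings of the published protocol.

## Parameters

Nine trainable parameters: four feature weights, the shift, and four gap
penalties (TM/non-TM × open/extend). The bundled α-helical preset is the
published 9-tuple `(1.6, 8.4, 6.7, 3.2, 4, 12.1, 1.6, 8.6, 1.1)` read in
the order `(w1..w4, shift, gap_open_tm, gap_ext_tm, gap_open_non,
gap_ext_non)` — that mapping is this package's documented assumption; it
is consistent with the stated requirement that the TM open penalty be
significantly larger than the non-TM one (12.1 > 8.6). The β-barrel
vector `(1.5, 9.2, 4.3, 3.6, 5, 9.2, 11.8, 1.6, 8.3, 1.1)` has **ten**
printed values for nine parameters; which value is surplus is not
recoverable, so the preset stores the vector verbatim and refuses to map
it without an explicit `beta_mapping` choice (`"skip_sixth"` or
`"skip_last"`, both of which keep `gap_open_tm > gap_open_non`). Nothing
is ever dropped silently.

## Training

Coordinate-wise grid search: from a (seeded) random initial set, each
iteration evaluates every single-parameter move on a local grid —
multiplicative factors for weights and penalties ({0.8, 1.25} at level 1;
{0.25, 0.5, 0.8, 1.25, 2, 4} at level 2, the default), additive deltas
for the shift — accepts the best strictly-improving move, and stops when
none improves or `max_iters` is reached. The accepted-objective trace is
non-decreasing by construction, and grid points violating the parameter
constraints are skipped, not clipped. The objective is mean alignment
accuracy against reference alignments (`reference_acc`); the original
procedure optimised a structural-superposition score, which requires 3D
template structures this package does not consume, so the objective is a
pluggable substitution that preserves the procedure (grid search,
monotone stop rule). α and β parameter sets are trained separately.

## Synthetic data

The generator's defaults encode the study conditions: helical TM
segments of 17–25 residues (strands 11–14), loops of 3–30 residues,
alternating inside/outside loops starting from an inside loop, four TM
segments per protein, three homologs per family at substitution rate 0.3
and indel rate 0.05 with mean indel length 3. Sequences are drawn from a
hydrophobic-biased composition in the membrane (the {A, I, L, F, V, M}
set carries ~72% of the mass) and a hydrophilic-biased one in loops;
per-position frequency vectors are Dirichlet draws (concentration 25)
around the emitting composition, log-odds are `log(freq / 0.05)` against
the uniform background, and accessibility is Beta(1.5, 8.5) in the
membrane (mean ≈ 0.15) versus Beta(5, 5) in loops. Indels fall in TM
segments at 10% of the loop propensity, which is what makes the
segment-dependent gap penalties observable in tests. Because
orientations are always derived from topology, the first TM segment of a
generated protein (preceded by an inside loop) carries orientation −1
and successive segments alternate.

Evolution records the exact residue-level alignment of each member to
its ancestor; benchmark references compose member→ancestor with
template→ancestor alignments. Similarity labels for correlation
analyses are global sequence identities computed with edlib, an
edit-distance library entirely independent of this package's aligner.

What the generator does *not* emulate: real PSSMs carry correlations
between neighbouring positions and family-specific conservation patterns
that Dirichlet noise around two fixed compositions lacks; topology and
accessibility are exactly consistent between homologs (no predictor
noise); families are star phylogenies. Passing tests therefore
demonstrate the machinery is correct and the features carry the intended
signal under the stated model — not that the trained presets reach any
particular accuracy on real proteins, which additionally depends on
upstream predictor quality.

## Numerical and design choices

- Canonical amino-acid order is the PSI-BLAST ASCII header order
  (`ARNDCQEGHILKMFPSTWYV`); parsers map any column permutation onto it.
- On-disk indices are 1-based, in-memory indices 0-based.
- Percentages rows must sum to 100 ± 2 (rounding slack) or be all-zero.
- The ACC denominator excludes target positions the reference leaves
  unaligned; `denominator="target_length"` switches to the full-length
  convention. Region accuracies recombine position-weighted to the
  overall accuracy exactly.
- Evaluation problem sizes: enumeration checks use lengths ≤ 6 (the
  exhaustive space is ~10³ alignments); benchmarks use 10 families × 2
  members with 3-TM-segment proteins of ~80–180 residues; training runs
  use 20 instances. These sizes give stable statistics while keeping a
  full run in seconds.
- Alignments between α-helical and β-barrel proteins are rejected
  outright, mirroring the benchmarking protocol that removes them.

## Known limitations

- The β parameter mapping is genuinely ambiguous (see above); both
  offered mappings are plausible and neither is validated on real data.
- The adjusted-score form and the segment/accessibility term forms are
  stand-ins for formulas that could not be recovered exactly; all three
  are isolated behind single functions.
- No statistical significance (E-values) for rankings; no secondary
  structure within loops; no structural superposition — fold labels and
  similarity tables are consumed as inputs, never computed from 3D
  coordinates.
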
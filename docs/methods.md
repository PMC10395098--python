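# Methods

## Structures

All structures are built by binary Merge; coordination of three or more
conjuncts is right-branching binary.  For *n* NP–V pairs (surface order
NP×n, adverb, V×n; the adverb is excluded from the "4 W"/"6 W" word
counts):

* **Nesting** — center-embedded clauses `{NP_k, {S_inner, V_k}}`, the
  adverb adjoined to the innermost verb (`{Adv, V_n}`).  The exact
  attachment site of the adverb is not fully determined by the sentence
  material; adjunction inside the innermost predicate phrase is the one
  choice consistent with every factor estimate (the adverb is invisible
  to search costs, depth, memory span and encoding).
* **Crossing** — `{NP-sequence, {Adv, V-sequence}}`.  Sequence nodes
  store the flat FormSequence order; the depth metric treats their
  interior as the underlying right-branching binary coordination
  (member *i* of a length-*k* sequence sits `min(i+1, k−1)` edges below
  the sequence node), which gives Degree of Merger = *n*.
* **Grouping** — `{NP-group, {Adv, V-group}}`, with the coordinate
  groups marked atomic: a group is a single search target and a single
  depth leaf (the collective group reading).

## Search-cost counting

Σ₁ counts the nodes entered from, and including, the cycle root before
the Subject is reached (breadth-first, minimality: first element found
wins; ties cannot arise in the three constructions).  Σ₂ counts the set
nodes entered — the Subject's sister included — before the predicate
verb is reached, with one exception: a sister containing no embedded
clause is selected wholesale as the Predicate at cost 0.  This
convention uniquely reproduces the per-cycle costs (1, 0) and (1, 1) of
the two-clause nested structure and all factor totals; whether the
wholesale selection reflects adverb invisibility instead is not
decidable from the material and would not change any count.

Closed forms (verified against tree traversal for n = 2…6): Nesting
Σ₁ = n, Σ₂ = n−1, DoM = 2n−1, span = 2(n−1); Crossing ordering =
2(n−1), DoM = n, span = n−1; Grouping Σ₁ = 1, Σ₂ = 0, DoM = 1,
span = 2(n−1); S-P pairs = n except Grouping's single group pair;
encoding = n everywhere.

Memory span is the maximum number of intervening non-adverb words in
any S-P dependency, measured from the leftmost word of the subject to
the rightmost word of the predicate; for the group pair this runs from
the first NP to the last V, the only convention matching the grouped
spans.  Absent factors (dashes in the estimate table) are `None` in
profiles and 0 in arithmetic (baseline subtraction, vector
composition).  Nonlinguistic factors whose Grouping-baselined contrast
is ≤ 0 are flagged eliminated.

## Stimulus generation

Lexemes are romanized (six male names, six speech verbs with explicit
inflection tables, 3 + 3 adverbs); script and display timing are
presentation-layer details outside scope.  Particle and verb-form rules
per dependency type are enforced exactly (nominative `-ga` on all NPs
under Nesting and on the final NP otherwise, coordinator `-to`
elsewhere; past + complementizer `-to` for non-final Nesting verbs;
adverbial form + comma for non-final Crossing/Grouping verbs;
progressive final verb under Crossing to block the group reading, past
under Grouping).  Question options: the correct answer, the remaining
in-sentence words of the opposite category, and the grouped option
(correct exactly under Grouping).  Four-word sentences leave only three
such options; the fourth is drawn from out-of-sentence words of the
same category — a stated convention of this package, since no sampling
rule for distractors is fixed by the task description.

## Fitting and likelihoods

The no-intercept fit uses the closed form `a = Σ e·ȳ / Σ e²` over the
four condition means, plus two steps of iterative refinement on the
normal equation so that exactly proportional (noise-free) data recover
their generating scale bit-for-bit; condition means are reduced along
the contiguous axis so numpy's pairwise summation keeps identical rows
exact.  r² is reported uncentered (`1 − RSS/Σ ȳ²`), the appropriate
definition for a through-origin model; the centered value is also
attached for transparency since either convention is defensible.

Goodness of fit: per condition, a two-sided one-sample t-test of
participant values against the group fitted value, treated as fixed
(no propagation of the scale's uncertainty), at the
Bonferroni-corrected threshold α = 0.05/4 = 0.0125.  The standalone
`goodness_t_tests` rejects zero within-condition variance; the
p-values attached to a `FitResult` instead degenerate gracefully
(p = 1 when the condition mean equals the fitted value exactly) so
noise-free simulations run end to end.

Log-likelihoods are Gaussian with maximum-likelihood error variance
over the *n* fitted observations, `LL = −(n/2)(ln(2π·RSS/n) + 1)`, *n*
defaulting to the four condition means and exposed as `n_loglik`: the
likelihood-ratio identity `exp(ΔLL) = (RSS_good/RSS_alt)^(n/2)` holds
for every *n*, and ratios — not absolute LL values — are the meaningful
output.  RSS = 0 is represented as LL = +∞ and the ratio special-cases
to 0, 1 or ∞.  Ratios are formatted in scientific notation with two
significant digits.

## Synthetic data

The generator emulates only what the fitting stage consumes: per
participant and condition, `y = a·e_c + ε`, ε i.i.d. Gaussian between
participants.  Defaults: 32 participants; true scale a = 0.05 percent
signal change per estimate unit, placing fitted condition means in the
±0.1–0.4 range typical of event-related ROI analyses; noise σ = 0.01
(noise-to-scale ratio 0.2).  One RNG stream per (region, event) — and
per replicate in recovery experiments — is derived from the master seed
by stable hashing (CRC-32 of the cell name as a spawn key), so adding
regions never perturbs existing data and every output is reproducible
byte-for-byte from the seed.

What the generator does *not* emulate: trial-level noise, serial
correlation, participant random slopes, hemodynamics, or any
behavioral error process.  Passing recovery and dissociation tests
therefore show that the analysis pipeline is correct and well
calibrated under its own assumptions — not that those assumptions hold
of measured BOLD data.

## Problem sizes in the checked experiments

The test suite exercises structures at n = 2…6 pairs, fit correctness
on 100 random datasets against an independent 1-D minimizer (agreement
to 1e-6), t-test calibration on 2,000 null replicates, and parameter
recovery / model selection on 1,000 replicates at the default study
conditions (32 participants, σ/a = 0.2), where the scale bias stays
below 1% of the true scale and the generating model wins the
likelihood-ratio comparison in at least 95% of replicates.

## Limitations

* The calculus covers the three generated constructions; it does not
  parse free text, and the general interpretive rule relating arbitrary
  pairs is implemented only in its Subject–Predicate special case.
* Depth inside sequence nodes is a counting convention (right-branching
  interior), not a claim about the constituency of coordinations.
* Whole-brain voxelwise analysis, cluster inference and anatomical
  labeling are out of scope; the fitting stage starts from ROI
  condition means.
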
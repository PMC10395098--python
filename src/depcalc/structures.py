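"""Builders for the three sentence constructions.

Three dependency types over ``n`` NP–V pairs, all with the same surface
order NP×n, adverb, V×n (the adverb is excluded from the word count, so
``n = 2`` is a "4 W" sentence and ``n = 3`` a "6 W" sentence):

Nesting (NT)
    Center-embedded clauses, the canonical SOV embedding: each clause is
    ``{NP_k, {S_inner, V_k}}``, with the adverb adjoined inside the
    innermost predicate phrase.  All NPs carry the nominative marker.
Crossing (CR)
    "Respectively"-style coordination: ``{NP-sequence, {ADV, V-sequence}}``.
    The coordinations are turned into ordered n-tuples by FormSequence,
    and NP_i pairs with V_i by position.
Grouping (GR)
    The control, a collective group reading: ``{NP-group, {ADV, V-group}}``
    where the coordinate groups act as single atomic elements.

Coordination of three or more conjuncts is right-branching binary
(Merge is binary); sequence nodes record the flat linear order while the
depth metric treats their interior as the underlying right-branching
coordination.
"""

from __future__ import annotations

from dataclasses import dataclass

from .tree import SyntaxObject, form_sequence, lexical, merge

NESTING = "NT"
CROSSING = "CR"
GROUPING = "GR"
DEPENDENCIES = (NESTING, CROSSING, GROUPING)

SUBJECTS_PLUS = "SUBJECTS_PLUS"
PREDICATES = "PREDICATES"
SENTENCE = "SENTENCE"
EVENTS = (SUBJECTS_PLUS, PREDICATES, SENTENCE)

#: Word-count label per number of NP–V pairs (the adverb is not counted).
def word_count_label(n_pairs: int) -> str:
    return f"{2 * n_pairs} W"


@dataclass(frozen=True)
class SentenceConfig:
    """A sentence condition: dependency type, size, and stimulus event.

    ``n_pairs`` is the number of NP–V pairs; the linearized sentence has
    ``2 * n_pairs + 1`` words including the adverb.
    """

    dependency: str
    n_pairs: int
    event: str = SENTENCE

    def __post_init__(self) -> None:
        if self.dependency not in DEPENDENCIES:
            raise ValueError(f"unknown dependency type: {self.dependency!r}")
        if self.n_pairs < 2:
            raise ValueError("n_pairs must be at least 2")
        if self.event not in EVENTS:
            raise ValueError(f"unknown stimulus event: {self.event!r}")

    @property
    def word_count(self) -> str:
        return word_count_label(self.n_pairs)


def _np_leaves(n: int, lexemes: list[str] | None) -> list[SyntaxObject]:
    return [
        lexical("NP", lexemes[k] if lexemes else f"NP{k + 1}", surface_index=k)
        for k in range(n)
    ]


def _v_leaves(n: int, lexemes: list[str] | None, order: list[int]) -> list[SyntaxObject]:
    """V leaves indexed by pair (V_k corresponds to NP_k); ``order`` maps
    pair index -> surface position."""
    return [
        lexical("V", lexemes[k] if lexemes else f"V{k + 1}", surface_index=order[k])
        for k in range(n)
    ]


def _right_branching(members: list[SyntaxObject], category: str) -> SyntaxObject:
    """Right-branching binary coordination of >= 2 conjuncts."""
    node = members[-1]
    for m in reversed(members[:-1]):
        node = merge(m, node, category=category)
    return node


def build_structure(
    config: SentenceConfig,
    *,
    np_lexemes: list[str] | None = None,
    v_lexemes: list[str] | None = None,
    adverb: str | None = None,
    include_adverb: bool = True,
) -> tuple[SyntaxObject, list[SyntaxObject]]:
    """Build the tree for one condition and return ``(root, surface)``.

    ``surface`` is the list of lexical leaves in linear order (NP×n,
    adverb, V×n), each with its ``surface_index`` set.  Lexemes default
    to schematic placeholders; the stimulus generator passes real words.
    ``include_adverb=False`` builds the bare dependency skeleton, which
    is useful for counting Merge applications.
    """
    n = config.n_pairs
    dep = config.dependency

    nps = _np_leaves(n, np_lexemes)
    adv = lexical("ADV", adverb or "Adv", surface_index=n) if include_adverb else None

    if dep == NESTING:
        # V_k of pair k sits at surface position 2n - k + ... innermost verb
        # first: pair n-1 (innermost) at position n+1, pair 0 at position 2n.
        v_order = [2 * n - k for k in range(n)]
        vs = _v_leaves(n, v_lexemes, v_order)
        # Innermost clause: {NP_n, {Adv, V_n}} (adverb adjoined to the
        # innermost verb); outer clauses {NP_k, {S_inner, V_k}}.
        if adv is not None:
            pred = merge(adv, vs[n - 1], category="VP")
        else:
            pred = vs[n - 1]
        clause = merge(nps[n - 1], pred, category="CLAUSE")
        for k in range(n - 2, -1, -1):
            pred = merge(clause, vs[k], category="VP")
            clause = merge(nps[k], pred, category="CLAUSE")
        root = clause

    elif dep == CROSSING:
        v_order = [n + 1 + k for k in range(n)]
        vs = _v_leaves(n, v_lexemes, v_order)
        np_seq = form_sequence(nps, [x.node_id for x in nps], category="NP_SEQ")
        v_seq = form_sequence(vs, [x.node_id for x in vs], category="V_SEQ")
        if adv is not None:
            vp = merge(adv, v_seq, category="VP")
        else:
            vp = v_seq
        root = merge(np_seq, vp, category="CLAUSE")

    else:  # GROUPING
        v_order = [n + 1 + k for k in range(n)]
        vs = _v_leaves(n, v_lexemes, v_order)
        np_group = _right_branching(nps, "NP_GROUP")
        np_group.atomic = True
        v_group = _right_branching(vs, "V_GROUP")
        v_group.atomic = True
        if adv is not None:
            vp = merge(adv, v_group, category="VP")
        else:
            vp = v_group
        root = merge(np_group, vp, category="CLAUSE")

    surface = sorted(
        (leaf for leaf in root.leaves()),
        key=lambda leaf: leaf.surface_index,
    )
    if not include_adverb:
        # Re-pack surface indices so the skeleton linearization is gap-free.
        for i, leaf in enumerate(surface):
            leaf.surface_index = i
    return root, surface
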
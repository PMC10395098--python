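"""Minimal Search (Σ) and Subject–Predicate pair formation.

Σ is a two-step search over a Merge-built tree, obeying minimality
("search as far as the first element reached and no further"):

Σ1
    Starting from a clause (cycle) root, find the closest NP and fix it
    as the Subject.  The Σ1 cost of a cycle is the number of nodes
    entered from — and including — the cycle root before the Subject is
    reached.
Σ2
    With the Subject fixed, find the Predicate in the Subject's sister
    domain.  When the sister contains no embedded clause it is selected
    wholesale as the Predicate and the Σ2 cost is 0; otherwise Σ2
    descends into the sister, and its cost is the number of set nodes
    entered (the sister included) before the predicate verb is reached.

When a sentence contains more than one clause, Σ applies cyclically,
innermost cycle first.  Crossing structures contain FSQ sequences, whose
conjuncts Σ cannot discriminate, so Σ is inapplicable there and the
Subject–Predicate relation is instead assigned positionally (FS-P′):
member i of the NP sequence pairs with member i of the V sequence.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from typing import Optional

from .tree import LEXICAL, SEQUENCE, SET, SyntaxObject

FS_P = "FS_P"
FS_P_PRIME = "FS_P_PRIME"

_SUBJECT_CATEGORIES = ("NP", "NP_GROUP")
_PREDICATE_CATEGORIES = ("V", "V_GROUP")


class SearchInapplicableError(Exception):
    """Σ cannot form Subject–Predicate pairs on this structure."""


@dataclass
class SearchResult:
    """Outcome of one Σ cycle: the pair found and the node-pass costs."""

    cycle_root: SyntaxObject
    subject: SyntaxObject
    predicate: SyntaxObject
    sigma1_count: int
    sigma2_count: int


@dataclass
class SPPair:
    """A Subject–Predicate pair with the rule that formed it."""

    subject: SyntaxObject
    predicate: SyntaxObject
    rule: str
    index_match: Optional[int] = None


def _has_sequence(tree: SyntaxObject) -> bool:
    return any(n.kind == SEQUENCE for n in tree.walk())


def _contains_clause(node: SyntaxObject) -> bool:
    return any(n.kind == SET and n.category == "CLAUSE" for n in node.walk())


def clause_cycles(tree: SyntaxObject) -> list[SyntaxObject]:
    """Clause nodes in cyclic application order (innermost first).

    Depth in the tree orders the cycles: the most deeply embedded clause
    is processed first, the root clause last.
    """
    cycles: list[tuple[int, SyntaxObject]] = []

    def visit(node: SyntaxObject, depth: int) -> None:
        if node.atomic:
            return
        if node.kind == SET and node.category == "CLAUSE":
            cycles.append((depth, node))
        for child in node.children:
            visit(child, depth + 1)

    visit(tree, 0)
    cycles.sort(key=lambda item: -item[0])
    return [node for _, node in cycles]


def _search_subject(cycle_root: SyntaxObject) -> tuple[SyntaxObject, int]:
    """Σ1: breadth-first minimal search for the closest NP.

    Returns the subject and the number of nodes entered from (and
    including) the cycle root before it was found.  Atomic coordinate
    groups are single search targets; their interiors are not entered.
    """
    queue: deque[SyntaxObject] = deque([cycle_root])
    entered = 0
    while queue:
        node = queue.popleft()
        entered += 1
        for child in node.children:
            if child.category in _SUBJECT_CATEGORIES and (
                child.kind == LEXICAL or child.atomic
            ):
                return child, entered
            if child.kind in (SET, SEQUENCE) and not child.atomic:
                queue.append(child)
    raise SearchInapplicableError("no NP found in the cycle's search domain")


def _search_predicate(sister: SyntaxObject) -> tuple[SyntaxObject, int]:
    """Σ2: find the Predicate in the Subject's sister domain.

    A sister without an embedded clause is selected wholesale (cost 0).
    Otherwise the search enters set nodes breadth-first until a verb is
    reached, counting each set node entered (the sister included).
    """
    if not _contains_clause(sister):
        return sister, 0
    queue: deque[SyntaxObject] = deque([sister])
    entered = 0
    while queue:
        node = queue.popleft()
        entered += 1
        for child in node.children:
            if child.category in _PREDICATE_CATEGORIES and (
                child.kind == LEXICAL or child.atomic
            ):
                return child, entered
            if child.kind == SET and not child.atomic:
                queue.append(child)
    raise SearchInapplicableError("no predicate found in the sister domain")


def sigma_search_all(tree: SyntaxObject) -> list[SearchResult]:
    """Run Σ cyclically over every clause of a Nesting or Grouping tree.

    Returns one :class:`SearchResult` per clause cycle, innermost first.
    Raises :class:`SearchInapplicableError` on Crossing trees: FSQ
    sequences force linear ordering and Σ cannot pick among conjuncts.
    """
    if _has_sequence(tree):
        raise SearchInapplicableError(
            "tree contains FSQ sequences; Σ cannot form the S-P pair"
        )
    results = []
    for cycle in clause_cycles(tree):
        subject, s1 = _search_subject(cycle)
        sister = next(c for c in cycle.children if c is not subject)
        predicate, s2 = _search_predicate(sister)
        results.append(
            SearchResult(
                cycle_root=cycle,
                subject=subject,
                predicate=predicate,
                sigma1_count=s1,
                sigma2_count=s2,
            )
        )
    return results


def _sequences(tree: SyntaxObject) -> dict[str, SyntaxObject]:
    return {n.category: n for n in tree.walk() if n.kind == SEQUENCE}


def form_sp_pairs(tree: SyntaxObject) -> list[SPPair]:
    """Assign Subject–Predicate relations over a built structure.

    Nesting and Grouping use FS-P (one pair per Σ cycle); Crossing uses
    FS-P′, pairing equal positions of the NP and V sequences.
    """
    if _has_sequence(tree):
        return form_sp_pairs_prime(tree)
    return [
        SPPair(subject=r.subject, predicate=r.predicate, rule=FS_P)
        for r in sigma_search_all(tree)
    ]


def form_sp_pairs_prime(tree: SyntaxObject) -> list[SPPair]:
    """FS-P′: positional pairing of FSQ sequence members (i = j only)."""
    seqs = _sequences(tree)
    if "NP_SEQ" not in seqs or "V_SEQ" not in seqs:
        raise SearchInapplicableError(
            "FS-P' requires both an NP sequence and a V sequence"
        )
    np_seq, v_seq = seqs["NP_SEQ"], seqs["V_SEQ"]
    if len(np_seq.children) != len(v_seq.children):
        raise SearchInapplicableError("NP and V sequences differ in length")
    return [
        SPPair(subject=np_i, predicate=v_i, rule=FS_P_PRIME, index_match=i)
        for i, (np_i, v_i) in enumerate(zip(np_seq.children, v_seq.children))
    ]
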
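"""Merge-built syntactic objects.

This module implements the two structure-building primitives of the
complexity calculus:

* :func:`merge` — binary set formation.  Merge takes two syntactic objects
  and forms the *unordered* set containing them.  All hierarchical
  structure in the calculus is built this way; the operation itself is
  treated as cost-free.
* :func:`form_sequence` — FormSequence (FSQ), the peripheral operation
  that converts a collection of Merge-formed objects into an *ordered*
  n-tuple.  FSQ is what makes crossed serial dependencies expressible;
  its ordering links are the "ordering cost" predictor downstream.

Nodes are :class:`SyntaxObject` instances.  Set nodes compare equal under
child permutation (Merge is symmetric); sequence nodes compare equal only
with identical child order.  Trees serialize to JSON and to a bracketed
text form (braces for sets, angle brackets for sequences).
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence

LEXICAL = "lexical"
SET = "set"
SEQUENCE = "sequence"

#: Categories used by the three sentence constructions.  ``VP`` labels the
#: intermediate predicate phrases formed when a verb merges with its
#: complement (an embedded clause or an adverb-adjoined verb).
CATEGORIES = (
    "NP",
    "V",
    "ADV",
    "CLAUSE",
    "VP",
    "NP_GROUP",
    "V_GROUP",
    "NP_SEQ",
    "V_SEQ",
)

_node_counter = itertools.count()


@dataclass(eq=False)
class SyntaxObject:
    """A node of a Merge-built tree.

    Parameters
    ----------
    kind
        ``"lexical"`` (leaf), ``"set"`` (binary Merge output, unordered)
        or ``"sequence"`` (FSQ output, ordered).
    category
        Syntactic category label, one of :data:`CATEGORIES`.
    children
        Child nodes; exactly two for sets, at least one for sequences,
        none for lexical nodes.
    lexeme
        Optional surface string, including any particle suffix
        (e.g. ``"Taro-ga"``).
    surface_index
        0-based position of the word in the linearized sentence; set by
        the structure builders on lexical leaves.
    atomic
        Marks coordinate groups that behave as a single element for
        search and for depth counting (the group reading of the
        Grouping control condition).
    """

    kind: str
    category: str
    children: tuple["SyntaxObject", ...] = ()
    lexeme: Optional[str] = None
    surface_index: Optional[int] = None
    atomic: bool = False
    node_id: int = field(default_factory=lambda: next(_node_counter))

    def __post_init__(self) -> None:
        if self.kind not in (LEXICAL, SET, SEQUENCE):
            raise ValueError(f"unknown node kind: {self.kind!r}")
        if self.kind == LEXICAL and self.children:
            raise ValueError("lexical nodes take no children")
        if self.kind == SET and len(self.children) != 2:
            raise ValueError("set nodes are binary (Merge takes two objects)")
        if self.kind == SEQUENCE and len(self.children) < 1:
            raise ValueError("sequence nodes need at least one member")
        self.children = tuple(self.children)

    # -- structural identity -------------------------------------------------

    def canonical_key(self):
        """Order-insensitive key for set nodes; order-sensitive for sequences."""
        if self.kind == LEXICAL:
            return (LEXICAL, self.category, self.lexeme)
        keys = [c.canonical_key() for c in self.children]
        if self.kind == SET:
            keys = sorted(keys)
        return (self.kind, self.category, tuple(keys))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SyntaxObject):
            return NotImplemented
        return self.canonical_key() == other.canonical_key()

    def __hash__(self) -> int:
        return hash(self.canonical_key())

    # -- traversal -----------------------------------------------------------

    def walk(self) -> Iterator["SyntaxObject"]:
        """Yield this node and all descendants, parents before children."""
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def leaves(self) -> list["SyntaxObject"]:
        return [n for n in self.walk() if n.kind == LEXICAL]

    @property
    def is_leaf(self) -> bool:
        return self.kind == LEXICAL

    # -- serialization -------------------------------------------------------

    def to_dict(self) -> dict:
        d: dict = {"kind": self.kind, "category": self.category}
        if self.lexeme is not None:
            d["lexeme"] = self.lexeme
        if self.surface_index is not None:
            d["surface_index"] = self.surface_index
        if self.atomic:
            d["atomic"] = True
        if self.kind == SEQUENCE:
            d["ordered"] = True
        if self.children:
            d["children"] = [c.to_dict() for c in self._serial_children()]
        return d

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    @classmethod
    def from_dict(cls, d: dict) -> "SyntaxObject":
        children = tuple(cls.from_dict(c) for c in d.get("children", ()))
        return cls(
            kind=d["kind"],
            category=d["category"],
            children=children,
            lexeme=d.get("lexeme"),
            surface_index=d.get("surface_index"),
            atomic=d.get("atomic", False),
        )

    def _serial_children(self) -> list["SyntaxObject"]:
        # Sets are semantically unordered; serialize children in a canonical
        # order (category, lexeme, key) purely so output is reproducible.
        if self.kind == SET:
            return sorted(
                self.children,
                key=lambda c: (c.category, c.lexeme or "", c.canonical_key()),
            )
        return list(self.children)

    def to_bracketed(self) -> str:
        """Penn-style text rendering: braces = sets, angle brackets = sequences."""
        if self.kind == LEXICAL:
            return self.lexeme if self.lexeme is not None else self.category
        inner = " ".join(c.to_bracketed() for c in self._serial_children())
        if self.kind == SET:
            return "{" + inner + "}"
        return "<" + inner + ">"

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"SyntaxObject({self.category}:{self.to_bracketed()})"


def lexical(category: str, lexeme: str | None = None,
            surface_index: int | None = None) -> SyntaxObject:
    """Build a lexical leaf node."""
    return SyntaxObject(kind=LEXICAL, category=category, lexeme=lexeme,
                        surface_index=surface_index)


def merge(left: SyntaxObject, right: SyntaxObject, *,
          category: str = "CLAUSE", atomic: bool = False) -> SyntaxObject:
    """Merge two syntactic objects into an unordered binary set.

    The inputs are not modified and may be shared between trees.  Passing
    the same object twice is rejected: Merge requires two distinct
    objects and self-merge is degenerate.
    """
    if left is right:
        raise ValueError("self-merge is degenerate: Merge needs two distinct objects")
    return SyntaxObject(kind=SET, category=category, children=(left, right),
                        atomic=atomic)


def form_sequence(members: Iterable[SyntaxObject],
                  surface_order: Sequence[int], *,
                  category: str = "NP_SEQ") -> SyntaxObject:
    """FormSequence: turn a set of objects into an ordered n-tuple.

    ``surface_order`` is the list of member ``node_id`` values in the
    desired linear order and must be a permutation of the members' ids.
    The resulting sequence node carries ``len(members) - 1`` ordering
    links (adjacent ordered pairs), the quantity counted by
    :func:`depcalc.metrics.count_ordering`.
    """
    members = list(members)
    by_id = {m.node_id: m for m in members}
    if len(by_id) != len(members):
        raise ValueError("members must have distinct node ids")
    if sorted(surface_order) != sorted(by_id):
        raise ValueError("surface_order is not a permutation of the member ids")
    ordered = tuple(by_id[i] for i in surface_order)
    return SyntaxObject(kind=SEQUENCE, category=category, children=ordered)


def ordering_links(node: SyntaxObject) -> int:
    """Number of adjacent ordered links carried by a sequence node."""
    if node.kind != SEQUENCE:
        return 0
    return len(node.children) - 1
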
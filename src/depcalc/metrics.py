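"""Per-condition complexity factors and Grouping-baselined contrasts.

For each sentence condition (dependency type × word count) and stimulus
event, the calculus yields a set of integer predictor estimates:

Linguistic factors
    ``sigma1`` / ``sigma2`` / ``sigma_total`` — Σ node-pass counts,
    summed over clause cycles (Subjects+ event, search-applicable
    conditions only); ``n_sp`` — number of Subject–Predicate pairs;
    ``n_ordering`` — FSQ ordering links (Predicates event, Crossing
    only); ``dom`` — Degree of Merger, the maximum embedding depth of
    the dependency skeleton (Subjects+ only).
Nonlinguistic factors
    ``memory_span`` — maximum number of intervening non-adverb words in
    any S-P dependency (fixed during the Predicates event);
    ``n_encoding`` — number of words encoded per event (the adverb
    excluded), equal to the number of NP–V pairs.

A factor that does not apply to a condition/event is *absent* (``None``)
in the profile; in arithmetic contexts (baseline subtraction, model
composition) absent counts as 0.  The control condition is Grouping:
``contrast_profile`` subtracts the Grouping profile at the same word
count, and nonlinguistic factors whose contrast is zero or negative are
flagged as eliminated from further analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from .search import SearchInapplicableError, form_sp_pairs, sigma_search_all
from .structures import (
    CROSSING,
    GROUPING,
    NESTING,
    PREDICATES,
    SENTENCE,
    SUBJECTS_PLUS,
    SentenceConfig,
    build_structure,
)
from .tree import LEXICAL, SEQUENCE, SET, SyntaxObject

#: Factor names in Table layout order.
LINGUISTIC_FACTORS = ("sigma1", "sigma2", "sigma_total", "n_sp", "n_ordering", "dom")
NONLINGUISTIC_FACTORS = ("memory_span", "n_encoding")
ALL_FACTORS = LINGUISTIC_FACTORS + NONLINGUISTIC_FACTORS


def count_ordering(tree: SyntaxObject) -> int:
    """Total FSQ ordering links: sum over sequence nodes of length − 1."""
    return sum(
        len(n.children) - 1 for n in tree.walk() if n.kind == SEQUENCE
    )


def degree_of_merger(tree: SyntaxObject) -> int:
    """Maximum leaf depth (in edges) of the dependency skeleton.

    Adverbs are excluded; a set node left with a single non-adverb child
    collapses onto that child.  Atomic coordinate groups count as single
    leaves.  A sequence of length k counts its underlying right-branching
    binary coordination: member i sits ``min(i + 1, k - 1)`` edges below
    the sequence node (both of the last two members share the deepest
    set).
    """

    def depth(node: SyntaxObject) -> Optional[int]:
        if node.category == "ADV":
            return None
        if node.kind == LEXICAL or node.atomic:
            return 0
        if node.kind == SEQUENCE:
            k = len(node.children)
            best = 0
            for i, child in enumerate(node.children):
                d = depth(child)
                if d is None:
                    continue
                embed = min(i + 1, k - 1) if k >= 2 else 1
                best = max(best, embed + d)
            return best
        child_depths = [d for d in (depth(c) for c in node.children) if d is not None]
        if not child_depths:
            return None
        if len(child_depths) == 1:
            return child_depths[0]
        return 1 + max(child_depths)

    d = depth(tree)
    return d if d is not None else 0


def memory_span(surface: list[SyntaxObject], pairs) -> int:
    """Maximum count of intervening non-adverb words over S-P dependencies.

    For each pair the dependency stretches from the leftmost word of the
    subject to the rightmost word of the predicate (for the group pair
    of the Grouping condition: first NP to last V); words strictly in
    between are counted, adverbs excluded.
    """
    adverb_positions = {
        leaf.surface_index for leaf in surface if leaf.category == "ADV"
    }
    best = 0
    for pair in pairs:
        subj_leaves = (
            pair.subject.leaves() if not pair.subject.is_leaf else [pair.subject]
        )
        pred_leaves = (
            pair.predicate.leaves() if not pair.predicate.is_leaf else [pair.predicate]
        )
        positions = [leaf.surface_index for leaf in subj_leaves + pred_leaves]
        if any(p is None for p in positions):
            raise ValueError("memory span requires surface indices on all leaves")
        lo = min(leaf.surface_index for leaf in subj_leaves)
        hi = max(
            leaf.surface_index
            for leaf in pred_leaves
            if leaf.category != "ADV"
        )
        between = [
            p for p in range(lo + 1, hi) if p not in adverb_positions
        ]
        best = max(best, len(between))
    return best


@dataclass
class ComplexityProfile:
    """All factor estimates for one condition and stimulus event.

    ``None`` marks a factor that does not apply (a dash in the estimate
    table); present values are nonnegative integers.
    """

    condition: SentenceConfig
    sigma1: Optional[int] = None
    sigma2: Optional[int] = None
    sigma_total: Optional[int] = None
    n_sp: int = 0
    n_ordering: Optional[int] = None
    dom: Optional[int] = None
    memory_span: Optional[int] = None
    n_encoding: int = 0

    def get(self, factor: str) -> Optional[int]:
        if factor not in ALL_FACTORS:
            raise KeyError(f"unknown factor: {factor!r}")
        return getattr(self, factor)

    def numeric(self, factor: str) -> int:
        """Factor value with absent mapped to 0."""
        value = self.get(factor)
        return 0 if value is None else value


def complexity_profile(config: SentenceConfig) -> ComplexityProfile:
    """Compute every factor for one condition × event by tree traversal.

    Event applicability follows the estimate-table layout: Σ factors and
    the Degree of Merger belong to the Subjects+ event (structure
    building happens once the NPs and adverb are seen); Ordering and
    memory span become fixed during the Predicates event; S-P
    correspondence and encoding apply during both events.
    """
    if config.event == SENTENCE:
        raise ValueError(
            "complexity factors are event-specific; use SUBJECTS_PLUS or PREDICATES"
        )
    tree, surface = build_structure(config)
    pairs = form_sp_pairs(tree)
    profile = ComplexityProfile(
        condition=config,
        n_sp=len(pairs),
        n_encoding=config.n_pairs,
    )

    if config.event == SUBJECTS_PLUS:
        profile.dom = degree_of_merger(tree)
        try:
            results = sigma_search_all(tree)
        except SearchInapplicableError:
            pass  # Crossing: Σ does not apply; the Σ cells stay absent
        else:
            profile.sigma1 = sum(r.sigma1_count for r in results)
            profile.sigma2 = sum(r.sigma2_count for r in results)
            profile.sigma_total = profile.sigma1 + profile.sigma2
    else:  # PREDICATES
        profile.memory_span = memory_span(surface, pairs)
        if config.dependency == CROSSING:
            profile.n_ordering = count_ordering(tree)

    return profile


NT_MINUS_GR = "NT_minus_GR"
CR_MINUS_GR = "CR_minus_GR"


@dataclass
class ContrastProfile:
    """Factor-wise difference of a condition against the Grouping control.

    Presence follows the target condition: a factor absent in the target
    stays absent in the contrast; an absent baseline value counts as 0.
    Nonlinguistic factors whose contrast is zero or negative carry no
    explanatory load and are listed in ``eliminated``.
    """

    contrast_label: str
    word_count: str
    event: str
    sigma1: Optional[int] = None
    sigma2: Optional[int] = None
    sigma_total: Optional[int] = None
    n_sp: Optional[int] = None
    n_ordering: Optional[int] = None
    dom: Optional[int] = None
    memory_span: Optional[int] = None
    n_encoding: Optional[int] = None
    eliminated: tuple[str, ...] = field(default_factory=tuple)

    def get(self, factor: str) -> Optional[int]:
        if factor not in ALL_FACTORS:
            raise KeyError(f"unknown factor: {factor!r}")
        return getattr(self, factor)

    def numeric(self, factor: str) -> int:
        value = self.get(factor)
        return 0 if value is None else value


def contrast_profile(
    target: ComplexityProfile, baseline_gr: ComplexityProfile
) -> ContrastProfile:
    """Subtract the Grouping baseline from a Nesting or Crossing profile."""
    t_cfg, b_cfg = target.condition, baseline_gr.condition
    if b_cfg.dependency != GROUPING:
        raise ValueError("baseline must be a Grouping profile")
    if t_cfg.n_pairs != b_cfg.n_pairs or t_cfg.event != b_cfg.event:
        raise ValueError("target and baseline must share word count and event")
    label = NT_MINUS_GR if t_cfg.dependency == NESTING else CR_MINUS_GR

    contrast = ContrastProfile(
        contrast_label=label,
        word_count=t_cfg.word_count,
        event=t_cfg.event,
    )
    eliminated = []
    for factor in ALL_FACTORS:
        t_val = target.get(factor)
        if t_val is None:
            continue
        value = t_val - baseline_gr.numeric(factor)
        setattr(contrast, factor, value)
        if factor in NONLINGUISTIC_FACTORS and value <= 0:
            eliminated.append(factor)
    contrast.eliminated = tuple(eliminated)
    return contrast


def all_contrasts(n_pairs_values=(3, 2)) -> dict:
    """Contrast profiles for every (dependency, n_pairs, event) against GR.

    Returns a mapping ``(dependency, n_pairs, event) -> ContrastProfile``
    for dependency in {NT, CR}.
    """
    out = {}
    for event in (SUBJECTS_PLUS, PREDICATES):
        for n in n_pairs_values:
            baseline = complexity_profile(SentenceConfig(GROUPING, n, event))
            for dep in (NESTING, CROSSING):
                target = complexity_profile(SentenceConfig(dep, n, event))
                out[(dep, n, event)] = contrast_profile(target, baseline)
    return out


def estimates_table(n_pairs_values=(3, 2)) -> pd.DataFrame:
    """Long-format table of every factor estimate and its GR contrast.

    Columns: ``factor, event, dependency, word_count, value,
    contrast_value`` — one row per factor × event × condition, with
    absent factors as missing values.
    """
    contrasts = all_contrasts(n_pairs_values)
    rows = []
    for event in (SUBJECTS_PLUS, PREDICATES):
        for dep in (NESTING, CROSSING, GROUPING):
            for n in n_pairs_values:
                profile = complexity_profile(SentenceConfig(dep, n, event))
                contrast = contrasts.get((dep, n, event))
                for factor in ALL_FACTORS:
                    rows.append(
                        {
                            "factor": factor,
                            "event": event,
                            "dependency": dep,
                            "word_count": profile.condition.word_count,
                            "value": profile.get(factor),
                            "contrast_value": (
                                contrast.get(factor) if contrast is not None else None
                            ),
                        }
                    )
    return pd.DataFrame(rows).astype({"value": "Int64", "contrast_value": "Int64"})
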
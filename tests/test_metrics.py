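"""Complexity factors per condition and Grouping-baselined contrasts.

The expected values for n = 2 ("4 W") and n = 3 ("6 W") are the
published estimate table of the study design; the closed forms for
general n serve as an independent oracle against the tree computation.
"""

import pytest

from depcalc.metrics import (
    ALL_FACTORS,
    ComplexityProfile,
    all_contrasts,
    complexity_profile,
    contrast_profile,
    count_ordering,
    degree_of_merger,
    estimates_table,
    memory_span,
)
from depcalc.search import form_sp_pairs
from depcalc.structures import (
    CROSSING,
    GROUPING,
    NESTING,
    PREDICATES,
    SENTENCE,
    SUBJECTS_PLUS,
    SentenceConfig,
    build_structure,
)


def closed_form(dep: str, n: int, factor: str):
    """Independent per-factor closed forms (event applicability ignored)."""
    forms = {
        NESTING: {
            "sigma1": n, "sigma2": n - 1, "sigma_total": 2 * n - 1,
            "n_sp": n, "n_ordering": 0, "dom": 2 * n - 1,
            "memory_span": 2 * (n - 1), "n_encoding": n,
        },
        CROSSING: {
            "sigma1": None, "sigma2": None, "sigma_total": None,
            "n_sp": n, "n_ordering": 2 * (n - 1), "dom": n,
            "memory_span": n - 1, "n_encoding": n,
        },
        GROUPING: {
            "sigma1": 1, "sigma2": 0, "sigma_total": 1,
            "n_sp": 1, "n_ordering": 0, "dom": 1,
            "memory_span": 2 * (n - 1), "n_encoding": n,
        },
    }
    return forms[dep][factor]


# --- published estimate-table cells (6 W, 4 W per dependency) -------------

SUBJECTS_PLUS_TABLE = {
    # factor: {dep: (6W, 4W)}; None = dash
    "sigma1": {NESTING: (3, 2), CROSSING: (None, None), GROUPING: (1, 1)},
    "sigma2": {NESTING: (2, 1), CROSSING: (None, None), GROUPING: (0, 0)},
    "sigma_total": {NESTING: (5, 3), CROSSING: (None, None), GROUPING: (1, 1)},
    "n_sp": {NESTING: (3, 2), CROSSING: (3, 2), GROUPING: (1, 1)},
    "n_ordering": {NESTING: (None, None), CROSSING: (None, None),
                   GROUPING: (None, None)},
    "dom": {NESTING: (5, 3), CROSSING: (3, 2), GROUPING: (1, 1)},
    "memory_span": {NESTING: (None, None), CROSSING: (None, None),
                    GROUPING: (None, None)},
    "n_encoding": {NESTING: (3, 2), CROSSING: (3, 2), GROUPING: (3, 2)},
}

PREDICATES_TABLE = {
    "sigma1": {NESTING: (None, None), CROSSING: (None, None),
               GROUPING: (None, None)},
    "sigma2": {NESTING: (None, None), CROSSING: (None, None),
               GROUPING: (None, None)},
    "sigma_total": {NESTING: (None, None), CROSSING: (None, None),
                    GROUPING: (None, None)},
    "n_sp": {NESTING: (3, 2), CROSSING: (3, 2), GROUPING: (1, 1)},
    "n_ordering": {NESTING: (None, None), CROSSING: (4, 2),
                   GROUPING: (None, None)},
    "dom": {NESTING: (None, None), CROSSING: (None, None),
            GROUPING: (None, None)},
    "memory_span": {NESTING: (4, 2), CROSSING: (2, 1), GROUPING: (4, 2)},
    "n_encoding": {NESTING: (3, 2), CROSSING: (3, 2), GROUPING: (3, 2)},
}


class TestComplexityProfiles:
    @pytest.mark.parametrize("event,table", [
        (SUBJECTS_PLUS, SUBJECTS_PLUS_TABLE),
        (PREDICATES, PREDICATES_TABLE),
    ])
    @pytest.mark.parametrize("dep", [NESTING, CROSSING, GROUPING])
    @pytest.mark.parametrize("n,col", [(3, 0), (2, 1)])
    def test_every_published_cell(self, event, table, dep, n, col):
        profile = complexity_profile(SentenceConfig(dep, n, event))
        for factor in ALL_FACTORS:
            assert profile.get(factor) == table[factor][dep][col], (
                f"{factor} for {dep} {2 * n} W during {event}"
            )

    @pytest.mark.parametrize("dep", [NESTING, CROSSING, GROUPING])
    @pytest.mark.parametrize("n", [2, 3, 4, 5, 6])
    @pytest.mark.parametrize("event", [SUBJECTS_PLUS, PREDICATES])
    def test_tree_computation_matches_closed_forms(self, dep, n, event):
        """Oracle equivalence: traversal vs closed form wherever applicable."""
        profile = complexity_profile(SentenceConfig(dep, n, event))
        for factor in ALL_FACTORS:
            value = profile.get(factor)
            if value is None:
                continue
            assert value == closed_form(dep, n, factor), (dep, n, factor)

    def test_sigma_total_is_sum_of_parts(self):
        profile = complexity_profile(SentenceConfig(NESTING, 4, SUBJECTS_PLUS))
        assert profile.sigma_total == profile.sigma1 + profile.sigma2

    def test_whole_sentence_event_rejected(self):
        with pytest.raises(ValueError, match="event"):
            complexity_profile(SentenceConfig(NESTING, 2, SENTENCE))


class TestIndividualMetrics:
    @pytest.mark.parametrize("n,expected", [(2, 2), (3, 4), (5, 8)])
    def test_ordering_links_crossing(self, n, expected):
        tree, _ = build_structure(SentenceConfig(CROSSING, n))
        assert count_ordering(tree) == expected

    @pytest.mark.parametrize("dep", [NESTING, GROUPING])
    def test_ordering_zero_without_sequences(self, dep):
        tree, _ = build_structure(SentenceConfig(dep, 3))
        assert count_ordering(tree) == 0

    def test_single_clause_depth_is_one(self):
        from depcalc.tree import lexical, merge

        clause = merge(lexical("NP", "Taro-ga"), lexical("V", "itta"))
        assert degree_of_merger(clause) == 1

    def test_adjacent_pair_spans_nothing(self):
        """An NP immediately followed by its V has memory span 0."""
        from depcalc.search import SPPair

        from depcalc.tree import lexical

        np_ = lexical("NP", "Taro-ga", surface_index=0)
        v = lexical("V", "itta", surface_index=1)
        pair = SPPair(subject=np_, predicate=v, rule="FS_P")
        assert memory_span([np_, v], [pair]) == 0

    def test_memory_span_requires_surface_indices(self):
        from depcalc.search import SPPair

        from depcalc.tree import lexical

        np_ = lexical("NP", "Taro-ga")
        v = lexical("V", "itta")
        pair = SPPair(subject=np_, predicate=v, rule="FS_P")
        with pytest.raises(ValueError, match="surface"):
            memory_span([np_, v], [pair])

    @pytest.mark.parametrize("dep,n,expected", [
        (NESTING, 3, 4), (NESTING, 2, 2),
        (CROSSING, 3, 2), (CROSSING, 2, 1),
        (GROUPING, 3, 4), (GROUPING, 2, 2),
    ])
    def test_memory_span_per_condition(self, dep, n, expected):
        tree, surface = build_structure(SentenceConfig(dep, n))
        assert memory_span(surface, form_sp_pairs(tree)) == expected


EXPECTED_CONTRASTS = {
    # (contrast dep, n, event) -> {factor: value or None}
    (NESTING, 3, SUBJECTS_PLUS): {
        "sigma1": 2, "sigma2": 2, "sigma_total": 4, "n_sp": 2, "dom": 4,
        "n_ordering": None, "memory_span": None, "n_encoding": 0,
    },
    (NESTING, 2, SUBJECTS_PLUS): {
        "sigma1": 1, "sigma2": 1, "sigma_total": 2, "n_sp": 1, "dom": 2,
        "n_ordering": None, "memory_span": None, "n_encoding": 0,
    },
    (CROSSING, 3, SUBJECTS_PLUS): {
        "sigma1": None, "sigma2": None, "sigma_total": None, "n_sp": 2,
        "dom": 2, "n_ordering": None, "memory_span": None, "n_encoding": 0,
    },
    (CROSSING, 2, SUBJECTS_PLUS): {
        "sigma1": None, "sigma2": None, "sigma_total": None, "n_sp": 1,
        "dom": 1, "n_ordering": None, "memory_span": None, "n_encoding": 0,
    },
    (NESTING, 3, PREDICATES): {
        "sigma1": None, "sigma2": None, "sigma_total": None, "n_sp": 2,
        "dom": None, "n_ordering": None, "memory_span": 0, "n_encoding": 0,
    },
    (NESTING, 2, PREDICATES): {
        "sigma1": None, "sigma2": None, "sigma_total": None, "n_sp": 1,
        "dom": None, "n_ordering": None, "memory_span": 0, "n_encoding": 0,
    },
    (CROSSING, 3, PREDICATES): {
        "sigma1": None, "sigma2": None, "sigma_total": None, "n_sp": 2,
        "dom": None, "n_ordering": 4, "memory_span": -2, "n_encoding": 0,
    },
    (CROSSING, 2, PREDICATES): {
        "sigma1": None, "sigma2": None, "sigma_total": None, "n_sp": 1,
        "dom": None, "n_ordering": 2, "memory_span": -1, "n_encoding": 0,
    },
}


class TestContrasts:
    @pytest.mark.parametrize("key", sorted(EXPECTED_CONTRASTS, key=str))
    def test_published_contrast_blocks(self, key):
        dep, n, event = key
        contrasts = all_contrasts()
        contrast = contrasts[key]
        for factor, expected in EXPECTED_CONTRASTS[key].items():
            assert contrast.get(factor) == expected, (key, factor)

    def test_nonpositive_nonlinguistic_factors_flagged_eliminated(self):
        contrast = all_contrasts()[(CROSSING, 3, PREDICATES)]
        assert "memory_span" in contrast.eliminated  # contrast is -2
        assert "n_encoding" in contrast.eliminated  # contrast is 0
        positive = all_contrasts()[(CROSSING, 3, SUBJECTS_PLUS)]
        assert "memory_span" not in positive.eliminated

    def test_self_subtraction_is_zero(self):
        profile = complexity_profile(SentenceConfig(GROUPING, 3, SUBJECTS_PLUS))
        contrast = contrast_profile(profile, profile)
        for factor in ALL_FACTORS:
            value = contrast.get(factor)
            assert value in (None, 0)

    def test_mismatched_baseline_rejected(self):
        target = complexity_profile(SentenceConfig(NESTING, 3, SUBJECTS_PLUS))
        wrong_wc = complexity_profile(SentenceConfig(GROUPING, 2, SUBJECTS_PLUS))
        wrong_dep = complexity_profile(SentenceConfig(CROSSING, 3, SUBJECTS_PLUS))
        with pytest.raises(ValueError, match="word count"):
            contrast_profile(target, wrong_wc)
        with pytest.raises(ValueError, match="Grouping"):
            contrast_profile(target, wrong_dep)

    def test_contrast_subtraction_is_linear(self):
        """contrast(a + b, g) = contrast(a, g) + raw profile b, factor-wise."""
        event = SUBJECTS_PLUS
        a = complexity_profile(SentenceConfig(NESTING, 3, event))
        g = complexity_profile(SentenceConfig(GROUPING, 3, event))
        b = complexity_profile(SentenceConfig(NESTING, 3, event))
        summed = ComplexityProfile(
            condition=a.condition,
            n_sp=a.n_sp + b.n_sp,
            n_encoding=a.n_encoding + b.n_encoding,
            sigma1=a.numeric("sigma1") + b.numeric("sigma1"),
            sigma2=a.numeric("sigma2") + b.numeric("sigma2"),
            sigma_total=a.numeric("sigma_total") + b.numeric("sigma_total"),
            dom=a.numeric("dom") + b.numeric("dom"),
        )
        lhs = contrast_profile(summed, g)
        rhs = contrast_profile(a, g)
        for factor in ALL_FACTORS:
            if lhs.get(factor) is None:
                continue
            assert lhs.numeric(factor) == rhs.numeric(factor) + b.numeric(factor)


def test_estimates_table_layout_and_key_cells():
    table = estimates_table()
    assert set(table.columns) == {
        "factor", "event", "dependency", "word_count", "value", "contrast_value"
    }
    cell = table[
        (table.factor == "sigma_total")
        & (table.event == SUBJECTS_PLUS)
        & (table.dependency == NESTING)
        & (table.word_count == "6 W")
    ]
    assert cell["value"].item() == 5
    assert cell["contrast_value"].item() == 4
    # 8 factors x 2 events x 6 conditions
    assert len(table) == 96
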
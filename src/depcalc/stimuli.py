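"""Trial material generation for the Subject–Predicate matching task.

Each trial presents a sentence in two stimulus events — the noun
phrases plus an adverb (Subjects+), then the verbs (Predicates) — and a
four-option question probing one Subject–Predicate correspondence.
Sentences are built from a small closed lexicon of six male names and
six speech verbs, romanized here; script and display details are
presentation-layer concerns outside the generator's scope.

Particle and verb-form rules per dependency type:

Nesting
    every NP carries the nominative marker ``-ga``; every non-final verb
    is past tense plus the complementizer ``-to``; the final verb is
    plain past tense.
Crossing
    the final NP carries ``-ga`` and earlier NPs the coordinator
    ``-to``; non-final verbs take their adverbial (conjunctive) form
    followed by a comma; the final verb is progressive, which blocks the
    collective group reading.  The adverb is a "respectively"-type one.
Grouping
    as Crossing, except the final verb is plain past tense (ensuring
    the group reading) and the adverb is a frequency adverb.

One of the four question options is always a group of all
opposite-category words joined by middle dots; it is the correct answer
exactly under the Grouping condition and a distractor otherwise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .structures import (
    CROSSING,
    DEPENDENCIES,
    GROUPING,
    NESTING,
    SENTENCE,
    SentenceConfig,
)

PAST = "past"
ADVERBIAL = "adverbial"
PROGRESSIVE = "progressive"
PRESENT = "present"

#: Inflection table per verb stem; explicit strings, no morphology engine.
VERB_FORMS: dict[str, dict[str, str]] = {
    "hana-su": {
        PAST: "hanashita", ADVERBIAL: "hanashi",
        PROGRESSIVE: "hanashiteiru", PRESENT: "hanasu",
    },
    "shabe-ru": {
        PAST: "shabetta", ADVERBIAL: "shaberi",
        PROGRESSIVE: "shabetteiru", PRESENT: "shaberu",
    },
    "sake-bu": {
        PAST: "sakenda", ADVERBIAL: "sakebi",
        PROGRESSIVE: "sakendeiru", PRESENT: "sakebu",
    },
    "wame-ku": {
        PAST: "wameita", ADVERBIAL: "wameki",
        PROGRESSIVE: "wameiteiru", PRESENT: "wameku",
    },
    "tsubuya-ku": {
        PAST: "tsubuyaita", ADVERBIAL: "tsubuyaki",
        PROGRESSIVE: "tsubuyaiteiru", PRESENT: "tsubuyaku",
    },
    "sasaya-ku": {
        PAST: "sasayaita", ADVERBIAL: "sasayaki",
        PROGRESSIVE: "sasayaiteiru", PRESENT: "sasayaku",
    },
}


@dataclass(frozen=True)
class Lexicon:
    """The closed word stock of the experiment."""

    names: tuple[str, ...] = (
        "Taro", "Jiro", "Kenta", "Shouta", "Tatsuya", "Masaya",
    )
    verbs: tuple[str, ...] = tuple(VERB_FORMS)
    adverbs_crossing: tuple[str, ...] = ("sorezore", "ono-ono", "meimei")
    adverbs_frequency: tuple[str, ...] = ("tokidoki", "tabitabi", "shibashiba")

    def __post_init__(self) -> None:
        if len(set(self.names)) != 6 or len(set(self.verbs)) != 6:
            raise ValueError("lexicon requires 6 distinct names and 6 distinct verbs")
        if len(set(self.adverbs_crossing)) != 3 or len(set(self.adverbs_frequency)) != 3:
            raise ValueError("lexicon requires 3 + 3 distinct adverbs")

    def verb_form(self, stem: str, form: str) -> str:
        return VERB_FORMS[stem][form]


DEFAULT_LEXICON = Lexicon()

GROUP_SEPARATOR = "・"  # middle dot joining grouped options


@dataclass
class QuestionSpec:
    """A four-option S-P matching question with its answer key."""

    probe: str
    probe_category: str  # "NP" or "V"
    options: tuple[str, ...]
    correct_index: int
    time_limit_s: float

    def score(self, selected_index: int) -> bool:
        return selected_index == self.correct_index


@dataclass
class Trial:
    """One generated trial: token events, answer key, and question."""

    config: SentenceConfig
    subjects_event: tuple[str, ...]
    predicates_event: tuple[str, ...]
    names: tuple[str, ...]
    verb_stems: tuple[str, ...]
    adverb: str
    sp_key: tuple[tuple[tuple[int, ...], tuple[int, ...]], ...]
    question: QuestionSpec

    @property
    def surface_tokens(self) -> tuple[str, ...]:
        return self.subjects_event + self.predicates_event

    def to_json(self) -> str:
        d = {
            "dependency": self.config.dependency,
            "n_pairs": self.config.n_pairs,
            "subjects_event": list(self.subjects_event),
            "predicates_event": list(self.predicates_event),
            "names": list(self.names),
            "verb_stems": list(self.verb_stems),
            "adverb": self.adverb,
            "sp_key": [[list(s), list(p)] for s, p in self.sp_key],
            "question": {
                "probe": self.question.probe,
                "probe_category": self.question.probe_category,
                "options": list(self.question.options),
                "correct_index": self.question.correct_index,
                "time_limit_s": self.question.time_limit_s,
            },
        }
        return json.dumps(d, ensure_ascii=False, sort_keys=True)


def _np_tokens(dep: str, names: tuple[str, ...]) -> list[str]:
    if dep == NESTING:
        return [f"{name}-ga" for name in names]
    # Crossing / Grouping: coordinator on all but the last NP.
    return [f"{name}-to" for name in names[:-1]] + [f"{names[-1]}-ga"]


def _v_tokens(dep: str, stems_surface: tuple[str, ...], lexicon: Lexicon) -> list[str]:
    n = len(stems_surface)
    tokens = []
    for i, stem in enumerate(stems_surface):
        final = i == n - 1
        if dep == NESTING:
            form = lexicon.verb_form(stem, PAST)
            tokens.append(form if final else f"{form}-to")
        else:
            if final:
                form = PROGRESSIVE if dep == CROSSING else PAST
                tokens.append(lexicon.verb_form(stem, form))
            else:
                tokens.append(lexicon.verb_form(stem, ADVERBIAL) + ",")
    return tokens


def _sp_key(dep: str, n: int) -> tuple[tuple[tuple[int, ...], tuple[int, ...]], ...]:
    """Answer key over surface token indices (NPs 0..n-1, adverb n, Vs n+1..2n).

    Each entry pairs a tuple of subject positions with a tuple of
    predicate positions; singleton tuples for Nesting/Crossing, the full
    groups for Grouping.
    """
    if dep == NESTING:
        # NP_k (outermost first) pairs with the k-th verb from the end.
        return tuple(((k,), (2 * n - k,)) for k in range(n))
    if dep == CROSSING:
        return tuple(((i,), (n + 1 + i,)) for i in range(n))
    return ((tuple(range(n)), tuple(range(n + 1, 2 * n + 1))),)


def _question(
    trial_dep: str,
    n: int,
    names: tuple[str, ...],
    verb_stems_surface: tuple[str, ...],
    sp_key,
    lexicon: Lexicon,
    rng: np.random.Generator,
) -> QuestionSpec:
    """Build the four-option question.

    Question forms follow the task: probe NPs appear bare, probe and
    option verbs in present tense.  Distractors are the other
    in-sentence words of the opposite category plus the grouped option;
    when the sentence is too short to fill four options, out-of-sentence
    words of the opposite category complete the set.
    """
    probe_category = "NP" if rng.integers(2) == 0 else "V"
    verbs_present = tuple(
        lexicon.verb_form(stem, PRESENT) for stem in verb_stems_surface
    )

    if probe_category == "NP":
        probe_pos = int(rng.integers(n))  # surface NP position
        probe = names[probe_pos]
        pool = list(verbs_present)
        grouped = GROUP_SEPARATOR.join(verbs_present)
        extra = [
            lexicon.verb_form(stem, PRESENT)
            for stem in lexicon.verbs
            if stem not in verb_stems_surface
        ]
        if trial_dep == GROUPING:
            correct = grouped
        else:
            (pair,) = [p for p in sp_key if p[0] == (probe_pos,)]
            correct = verbs_present[pair[1][0] - n - 1]
    else:
        probe_pos = int(rng.integers(n))  # surface V position
        probe = verbs_present[probe_pos]
        pool = list(names)
        grouped = GROUP_SEPARATOR.join(names)
        extra = [name for name in lexicon.names if name not in names]
        if trial_dep == GROUPING:
            correct = grouped
        else:
            (pair,) = [p for p in sp_key if p[1] == (probe_pos + n + 1,)]
            correct = names[pair[0][0]]

    distractors = [w for w in pool if w != correct]
    if grouped != correct:
        distractors.append(grouped)
    rng.shuffle(distractors)
    while len(distractors) < 3:
        distractors.append(extra.pop(int(rng.integers(len(extra)))))
    options = [correct] + distractors[:3]
    order = rng.permutation(4)
    options = tuple(options[i] for i in order)
    correct_index = int(np.argwhere(order == 0)[0, 0])
    time_limit = {2: 4.0, 3: 6.0}.get(n, 2.0 * n)
    return QuestionSpec(
        probe=probe,
        probe_category=probe_category,
        options=options,
        correct_index=correct_index,
        time_limit_s=time_limit,
    )


def generate_trial(
    config: SentenceConfig,
    rng_seed: int,
    lexicon: Lexicon = DEFAULT_LEXICON,
) -> Trial:
    """Generate one condition-conforming trial, fully determined by the seed."""
    n = config.n_pairs
    if n > len(lexicon.names):
        raise ValueError("n_pairs exceeds the lexicon (at most 6 NP-V pairs)")
    rng = np.random.default_rng(rng_seed)
    dep = config.dependency

    names = tuple(rng.choice(lexicon.names, size=n, replace=False))
    stems = tuple(rng.choice(lexicon.verbs, size=n, replace=False))
    adverb_set = (
        lexicon.adverbs_crossing if dep == CROSSING else lexicon.adverbs_frequency
    )
    adverb = str(rng.choice(adverb_set))

    # ``stems`` is pair-indexed (stem k belongs to NP k); surface verb order
    # reverses the pairing under Nesting (innermost verb first).
    stems_surface = tuple(reversed(stems)) if dep == NESTING else stems
    np_tokens = _np_tokens(dep, names)
    v_tokens = _v_tokens(dep, stems_surface, lexicon)
    sp_key = _sp_key(dep, n)
    question = _question(dep, n, names, stems_surface, sp_key, lexicon, rng)

    return Trial(
        config=config,
        subjects_event=tuple(np_tokens) + (adverb,),
        predicates_event=tuple(v_tokens),
        names=names,
        verb_stems=stems,
        adverb=adverb,
        sp_key=sp_key,
        question=question,
    )


#: The six conditions of a scanning run.
RUN_CONDITIONS = tuple(
    (dep, n) for dep in DEPENDENCIES for n in (3, 2)
)
TRIALS_PER_CONDITION = 3


def generate_run(
    rng_seed: int, lexicon: Lexicon = DEFAULT_LEXICON
) -> list[Trial]:
    """Generate one run: 18 trials, 3 per condition, order randomized."""
    rng = np.random.default_rng(rng_seed)
    configs = [
        SentenceConfig(dep, n, SENTENCE)
        for dep, n in RUN_CONDITIONS
        for _ in range(TRIALS_PER_CONDITION)
    ]
    order = rng.permutation(len(configs))
    trial_seeds = rng.integers(0, 2**31, size=len(configs))
    return [
        generate_trial(configs[i], int(trial_seeds[j]), lexicon)
        for j, i in enumerate(order)
    ]


def run_to_frame(trials: list[Trial]) -> pd.DataFrame:
    """CSV export: one row per event token."""
    rows = []
    for t_idx, trial in enumerate(trials):
        for event, tokens in (
            ("SUBJECTS_PLUS", trial.subjects_event),
            ("PREDICATES", trial.predicates_event),
        ):
            for pos, token in enumerate(tokens):
                rows.append(
                    {
                        "trial_id": t_idx,
                        "condition": f"{trial.config.dependency} "
                        f"{trial.config.word_count}",
                        "event": event,
                        "position": pos,
                        "token": token,
                    }
                )
    return pd.DataFrame(rows)


def run_to_jsonl(trials: list[Trial], seed: Optional[int] = None) -> str:
    header = json.dumps({"format": "depcalc-trials", "seed": seed})
    return "\n".join([header] + [t.to_json() for t in trials]) + "\n"
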
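"""Bi-gram dictionary-driven two-layer 8-target spelling interface.

The speller exposes eight selectable boxes on a 2x4 grid.  Layer I shows
the 28 speller characters (A-Z, the word separator ``_`` and the full stop)
partitioned into four groups of seven, plus three dictionary suggestions
and UNDO.  Selecting a group opens Layer II with that group's seven
characters and BACK.  Word suggestions are ranked with a word-level bi-gram
model backed off to unigram frequencies; accepting a suggestion completes
the current word and appends the separator.

The module also provides an error-free/greedy user model
(:func:`optimal_step_count`), a seeded copy-spelling simulator with a
uniform command-error model and UNDO-based correction, and the output
characters per minute (OCM) metric.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "ALPHABET",
    "GROUPS",
    "Lexicon",
    "SpellerState",
    "load_fixture_lexicon",
    "suggest",
    "apply_selection",
    "optimal_step_count",
    "simulate_copy_spelling",
    "ocm",
]

#: The 28 speller characters.
ALPHABET = "ABCDEFGHIJKLMNOPQRSTUVWXYZ_."

#: Layer-I groups: four disjoint groups of seven characters.
GROUPS = (ALPHABET[0:7], ALPHABET[7:14], ALPHABET[14:21], ALPHABET[21:28])

_WORD_RE = re.compile(r"^[A-Z]+$")

# Layer-I target roles (0-based): 0-3 groups, 4-6 suggestions, 7 UNDO.
N_GROUPS = 4
SUGGESTION_SLOTS = (4, 5, 6)
UNDO_TARGET = 7
# Layer-II: 0-6 characters of the active group, 7 BACK.
BACK_TARGET = 7


@dataclass
class Lexicon:
    """Word-frequency tables: unigram counts and bi-gram co-occurrence
    counts (next-neighbor pairs), words uppercase A-Z only."""

    unigrams: dict = field(default_factory=dict)
    bigrams: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for w, c in self.unigrams.items():
            if not _WORD_RE.match(w) or c <= 0:
                raise ValueError(f"bad unigram entry {w!r}: {c}")
        for (w1, w2), c in self.bigrams.items():
            if not (_WORD_RE.match(w1) and _WORD_RE.match(w2)) or c <= 0:
                raise ValueError(f"bad bigram entry {(w1, w2)!r}: {c}")

    @classmethod
    def empty(cls) -> "Lexicon":
        return cls({}, {})

    @classmethod
    def from_tsv(cls, unigram_path, bigram_path) -> "Lexicon":
        """Load Leipzig-Corpora-style TSV tables (``WORD<TAB>count`` and
        ``WORD1<TAB>WORD2<TAB>count``).  Words are uppercased; entries with
        out-of-alphabet characters are dropped (count reported in
        ``.dropped``)."""
        uni = pd.read_csv(unigram_path, sep="\t", header=None, names=["word", "count"])
        bi = pd.read_csv(bigram_path, sep="\t", header=None, names=["w1", "w2", "count"])
        dropped = 0
        unigrams: dict = {}
        for w, c in zip(uni["word"].astype(str).str.upper(), uni["count"]):
            if _WORD_RE.match(w) and c > 0:
                unigrams[w] = unigrams.get(w, 0) + int(c)
            else:
                dropped += 1
        bigrams: dict = {}
        for w1, w2, c in zip(
            bi["w1"].astype(str).str.upper(), bi["w2"].astype(str).str.upper(), bi["count"]
        ):
            if _WORD_RE.match(w1) and _WORD_RE.match(w2) and c > 0:
                bigrams[(w1, w2)] = bigrams.get((w1, w2), 0) + int(c)
            else:
                dropped += 1
        lex = cls(unigrams, bigrams)
        lex.dropped = dropped
        return lex


def load_fixture_lexicon() -> Lexicon:
    """Packaged synthetic stand-in for a corpus-derived lexicon (~200
    common English words with Zipf-like counts plus a bi-gram table)."""
    data = resources.files("vepwin").joinpath("data")
    with resources.as_file(data.joinpath("lexicon_synthetic_unigrams.tsv")) as up, \
            resources.as_file(data.joinpath("lexicon_synthetic_bigrams.tsv")) as bp:
        return Lexicon.from_tsv(up, bp)


def suggest(previous_word: str, prefix: str, lexicon: Lexicon, k: int = 3) -> list[str]:
    """Rank up to ``k`` word suggestions for the current partial word.

    Bi-gram continuations of ``previous_word`` matching ``prefix`` come
    first (descending co-occurrence count), then unigram-frequency words
    matching the prefix fill the remaining slots (duplicates removed).
    Ties break lexicographically.
    """
    if prefix and not _WORD_RE.match(prefix):
        raise ValueError("prefix must be over A-Z")
    out: list[str] = []
    if previous_word:
        cand = [
            (c, w2)
            for (w1, w2), c in lexicon.bigrams.items()
            if w1 == previous_word and w2.startswith(prefix)
        ]
        for _, w in sorted(cand, key=lambda t: (-t[0], t[1])):
            if w not in out:
                out.append(w)
    if len(out) < k:
        cand = [(c, w) for w, c in lexicon.unigrams.items() if w.startswith(prefix)]
        for _, w in sorted(cand, key=lambda t: (-t[0], t[1])):
            if w not in out:
                out.append(w)
            if len(out) >= k:
                break
    return out[:k]


@dataclass
class SpellerState:
    """Interface state: current layer, typed output, target text and the
    undo history (stack of typed strings before each text edit)."""

    target_text: str = ""
    typed: str = ""
    layer: str = "I"
    active_group: int | None = None
    history: list = field(default_factory=list)

    def current_prefix(self) -> str:
        return self.typed.rsplit("_", 1)[-1]

    def previous_word(self) -> str:
        """Last completed word: the text between the last two separators."""
        parts = self.typed.split("_")
        return parts[-2] if len(parts) >= 2 else ""

    def suggestions(self, lexicon: Lexicon) -> list[str]:
        prefix = self.current_prefix()
        if prefix and not _WORD_RE.match(prefix):
            return []
        return suggest(self.previous_word(), prefix, lexicon, k=len(SUGGESTION_SLOTS))


def apply_selection(state: SpellerState, target: int, lexicon: Lexicon) -> SpellerState:
    """Execute one selection (0-based target index) in place.

    Layer I: groups open Layer II; a suggestion replaces the current partial
    word with the suggested word plus the separator; UNDO reverts the last
    text-modifying selection.  Layer II: a character is appended and the
    interface returns to Layer I; BACK returns without typing.
    """
    if not 0 <= target < 8:
        raise ValueError("target must be in 0..7")
    if state.layer == "I":
        if target < N_GROUPS:
            state.layer = "II"
            state.active_group = target
        elif target in SUGGESTION_SLOTS:
            words = state.suggestions(lexicon)
            slot = target - SUGGESTION_SLOTS[0]
            if slot < len(words):
                state.history.append(state.typed)
                head = state.typed.rsplit("_", 1)
                base = head[0] + "_" if len(head) == 2 else ""
                state.typed = base + words[slot] + "_"
        else:  # UNDO
            if state.history:
                state.typed = state.history.pop()
    else:
        if target == BACK_TARGET:
            state.layer = "I"
            state.active_group = None
        else:
            ch = GROUPS[state.active_group][target]
            state.history.append(state.typed)
            state.typed += ch
            state.layer = "I"
            state.active_group = None
    return state


def _is_done(typed: str, sentence: str) -> bool:
    # A dictionary-completed final word carries the trailing separator.
    return typed == sentence or typed == sentence + "_"


def _on_track(typed: str, sentence: str) -> bool:
    return (sentence + "_").startswith(typed) or sentence.startswith(typed)


def _group_of(ch: str) -> int:
    for g, chars in enumerate(GROUPS):
        if ch in chars:
            return g
    raise ValueError(f"character {ch!r} not in the speller alphabet")


def _intended_selection(state: SpellerState, lexicon: Lexicon) -> int:
    """Greedy error-free user policy: fix divergent text via UNDO/BACK,
    take a displayed correct suggestion when available, otherwise type the
    next character of the target sentence."""
    sentence = state.target_text
    if not _on_track(state.typed, sentence):
        return BACK_TARGET if state.layer == "II" else UNDO_TARGET
    next_ch = sentence[len(state.typed)]
    if state.layer == "II":
        grp = _group_of(next_ch)
        if grp == state.active_group:
            return GROUPS[grp].index(next_ch)
        return BACK_TARGET  # landed in the wrong group
    # Layer I: is the target's current word on display?
    words = sentence.split("_")
    before = state.typed.count("_")
    current_word = words[before] if before < len(words) else ""
    if current_word and _WORD_RE.match(current_word):
        shown = state.suggestions(lexicon)
        if current_word in shown:
            return SUGGESTION_SLOTS[0] + shown.index(current_word)
    return _group_of(next_ch)


def optimal_step_count(sentence: str, lexicon: Lexicon, max_steps: int = 100000) -> int:
    """Number of selections a greedy error-free user needs to type
    ``sentence``: one step per accepted suggestion, two (group + character)
    per typed character."""
    if any(c not in ALPHABET for c in sentence):
        raise ValueError("sentence must be over the speller alphabet")
    state = SpellerState(target_text=sentence)
    steps = 0
    while not _is_done(state.typed, sentence):
        if steps >= max_steps:
            raise RuntimeError("user model failed to terminate")
        apply_selection(state, _intended_selection(state, lexicon), lexicon)
        steps += 1
    return steps


def ocm(output_chars: float, elapsed_s: float) -> float:
    """Output characters per minute: typed characters divided by the time
    needed to type them (errors cost extra commands, lowering OCM)."""
    if elapsed_s <= 0:
        raise ValueError("elapsed_s must be positive")
    return 60.0 * output_chars / elapsed_s


def simulate_copy_spelling(
    sentence: str,
    lexicon: Lexicon,
    command_error_rate: float = 0.0,
    selection_time_s: float = 2.05,
    seed: int = 0,
    executor=None,
    max_commands: int | None = None,
) -> dict:
    """Simulate a copy-spelling session with the greedy user model.

    Each intended selection is corrupted with probability
    ``command_error_rate`` into a uniformly random *wrong* target of the
    current layer; the user repairs wrong text with UNDO (and BACK for
    wrong-group detours).  Alternatively an ``executor`` callable
    ``(intended, step) -> (executed, elapsed_s)`` can stand in for the
    error model, e.g. a decoder driven by a synthetic EEG stream.

    Returns a session summary with the JSON-lines-ready command log.
    """
    if not sentence:
        raise ValueError("sentence must be non-empty")
    if any(c not in ALPHABET for c in sentence):
        raise ValueError("sentence must be over the speller alphabet")
    rng = np.random.default_rng(seed)
    state = SpellerState(target_text=sentence)
    if max_commands is None:
        max_commands = 60 * len(sentence) + 400
    log: list[dict] = []
    commands = 0
    correct = 0
    elapsed = 0.0
    while not _is_done(state.typed, sentence):
        if commands >= max_commands:
            raise RuntimeError("copy-spelling session exceeded the command cap")
        intended = _intended_selection(state, lexicon)
        if executor is not None:
            executed, dt = executor(intended, commands)
        else:
            executed = intended
            if command_error_rate > 0 and rng.random() < command_error_rate:
                executed = int(rng.integers(0, 7))
                if executed >= intended:
                    executed += 1
            dt = selection_time_s
        layer_before = state.layer
        if executed is not None:
            apply_selection(state, executed, lexicon)
        commands += 1
        correct += executed == intended
        elapsed += dt
        log.append(
            {
                "step": commands,
                "layer": layer_before,
                "intended": int(intended),
                "executed": None if executed is None else int(executed),
                "typed_after": state.typed,
                "t": round(elapsed, 6),
            }
        )
    out_chars = len(sentence)
    return {
        "sentence": sentence,
        "typed": state.typed,
        "commands": commands,
        "correct": int(correct),
        "accuracy": correct / commands if commands else 1.0,
        "elapsed_s": elapsed,
        "output_chars": out_chars,
        "ocm": ocm(out_chars, elapsed) if elapsed > 0 else 0.0,
        "log": log,
    }


def write_session_log(log: list, path) -> None:
    """Write a session command log as JSON lines."""
    with open(path, "w") as fh:
        for rec in log:
            fh.write(json.dumps(rec, sort_keys=True) + "\n")
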
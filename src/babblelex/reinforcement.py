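"""Approval detection and the reinforcement selection heuristic.

When the teacher approves ("well done", "good", "clever", ...), the learner
analyses its immediately preceding utterance and moves one CVC syllable into
its lexicon (*ilex*).  Only CVC forms are candidates, matching the scenario in
which nearly all salient words are closed monosyllables.  The selection score
combines perceived frequency with recency of teacher use:

    score(s) = count(s) / (1 + dt(s)),    dt = turns since s was last heard

with never-heard syllables scoring zero.  The functional form is a named,
swappable strategy (``SCORE_STRATEGIES``); an exponential-decay alternative is
provided for comparison.  Ties break toward the more recently heard syllable,
then lexicographically, so selection is deterministic.

Approval matching is exact phonemic-substring matching against canonical
renderings of the approval terms; recognizer noise that can garble an approval
is applied on the teacher side, not here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Callable, Iterable

from .perception import PhonemeStream, SyllableTable
from .phonology import SyllableForm
from .production import Utterance

SCORE_STRATEGIES: dict[str, Callable[[int, int], float]] = {
    "frequency_recency": lambda count, dt: count / (1 + dt),
    "exp_decay": lambda count, dt: count * math.exp(-0.1 * dt),
}


@dataclass
class LexiconEntry:
    form: SyllableForm
    first_learned_turn: int
    reinforcement_count: int = 1


class Lexicon:
    """The learner's store of reinforced CVC word forms (*ilex*).

    Entries are only ever added or re-counted during a session, never removed;
    iteration follows first-learned order.
    """

    def __init__(self):
        self._entries: dict[tuple[str, ...], LexiconEntry] = {}

    def __len__(self) -> int:
        return len(self._entries)

    def __contains__(self, phonemes) -> bool:
        return tuple(phonemes) in self._entries

    def entry(self, phonemes) -> LexiconEntry | None:
        return self._entries.get(tuple(phonemes))

    def forms(self) -> list[SyllableForm]:
        """Lexicon word forms in first-learned order."""
        return [e.form for e in self._entries.values()]

    def items(self):
        return self._entries.items()

    def write_tsv(self, path: str | Path, gloss: dict[tuple[str, ...], str] | None = None):
        """Dump (form, orthographic gloss if resolvable, first turn, count)."""
        gloss = gloss or {}
        with open(path, "w") as fh:
            fh.write("form\tgloss\tfirst_learned_turn\treinforcement_count\n")
            for phonemes, e in self._entries.items():
                fh.write(
                    f"{' '.join(phonemes)}\t{gloss.get(phonemes, '')}\t"
                    f"{e.first_learned_turn}\t{e.reinforcement_count}\n"
                )


def reinforce(lexicon: Lexicon, syllable: SyllableForm, turn_index: int = 0) -> Lexicon:
    """Store ``syllable`` in the lexicon (or bump its reinforcement count)."""
    if syllable.stype != "CVC":
        raise ValueError(f"only CVC forms are reinforced, got {syllable.stype}")
    entry = lexicon._entries.get(syllable.phonemes)
    if entry is None:
        lexicon._entries[syllable.phonemes] = LexiconEntry(syllable, turn_index)
    else:
        entry.reinforcement_count += 1
    return lexicon


@dataclass(frozen=True)
class ApprovalSet:
    """Approval terms with canonical phonemic renderings."""

    terms: tuple[tuple[str, tuple[str, ...]], ...]

    def __post_init__(self):
        if not self.terms:
            raise ValueError("approval set must be non-empty")

    @classmethod
    def from_file(cls, path: str | Path) -> "ApprovalSet":
        terms = []
        for line in Path(path).read_text().splitlines():
            line = line.split("#", 1)[0].rstrip()
            if not line.strip():
                continue
            orth, phon = line.split("\t")
            terms.append((orth.strip(), tuple(phon.lower().split())))
        return cls(tuple(terms))

    @classmethod
    def default(cls) -> "ApprovalSet":
        with resources.as_file(resources.files("babblelex") / "data" / "approvals.txt") as p:
            return cls.from_file(p)


def _contains(haystack: tuple[str, ...], needle: tuple[str, ...]) -> bool:
    n = len(needle)
    return any(haystack[i : i + n] == needle for i in range(len(haystack) - n + 1))


def detect_approval(stream: PhonemeStream, approvals: ApprovalSet | None = None) -> bool:
    """True iff any approval term occurs contiguously in the stream."""
    approvals = approvals or ApprovalSet.default()
    toks = tuple(t.lower() for t in stream.tokens)
    return any(_contains(toks, phon) for _, phon in approvals.terms)


def heuristic_select(
    prev: Utterance,
    table: SyllableTable,
    now: int,
    strategy: str = "frequency_recency",
) -> SyllableForm | None:
    """The CVC syllable of ``prev`` with the highest frequency/recency score.

    Returns None when ``prev`` holds no CVC syllable with positive score (an
    approval then reinforces nothing — logged upstream as a heuristic miss).
    """
    score_fn = SCORE_STRATEGIES[strategy]
    best = None
    best_key = None
    for syl in prev.syllables:
        if syl.stype != "CVC":
            continue
        stats = table.stats("CVC", syl.phonemes)
        if stats is None or stats.count <= 0:
            continue
        dt = now - stats.last_heard
        score = score_fn(stats.count, dt)
        if score <= 0:
            continue
        key = (-score, dt, syl.phonemes)  # ties: smaller dt, then lexicographic
        if best_key is None or key < best_key:
            best, best_key = syl, key
    return best
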
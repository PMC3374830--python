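"""Quasi-random syllabic babble, biased toward perceived frequencies.

Each syllable of an utterance is produced in two seeded draws: first a
candidate is chosen uniformly among the four syllable types *plus* every word
already in the lexicon (so two learnt words give six equiprobable candidates);
then, if a type was chosen, a syllable of that type is sampled with
probability proportional to its perceived count (counts 1, 3, 6 give chances
1/10, 3/10, 6/10).  While a type's table is still empty the learner falls back
to a uniformly random legal syllable — the initial random babble.  A chosen
lexicon word is emitted directly.

All randomness flows through a single ``numpy.random.Generator``; the draw
order (candidate, then syllable) is fixed, so transcripts are reproducible
bit-for-bit under a seed.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass
from itertools import accumulate

import numpy as np

from .phonology import (
    SYLLABLE_TYPES,
    ClusterInventory,
    PhonemeInventory,
    SyllableForm,
)
from .perception import SyllableTable


@dataclass(frozen=True)
class Utterance:
    """An ordered run of produced syllables within one learner turn."""

    syllables: tuple[SyllableForm, ...]
    turn_index: int = 0

    def render(self) -> str:
        """Paper-style transcript notation: ``(s k w eh r) (b aa k s)``."""
        return " ".join(f"({s})" for s in self.syllables)

    def __len__(self) -> int:
        return len(self.syllables)


def choose_candidate(lexicon, rng: np.random.Generator):
    """Uniform draw over the 4 syllable types plus each lexicon word.

    Returns either a type tag (``"V"``/``"CV"``/``"VC"``/``"CVC"``) or the
    :class:`~babblelex.phonology.SyllableForm` of a lexicon word.
    """
    words = lexicon.forms() if lexicon is not None else []
    k = int(rng.integers(0, 4 + len(words)))
    if k < 4:
        return SYLLABLE_TYPES[k]
    return words[k - 4]


def syllable_distribution(
    table: SyllableTable, stype: str
) -> tuple[list[tuple[str, ...]], list[float]]:
    """The exact production distribution over perceived syllables of ``stype``:
    counts normalised by their sum.  Syllables in lexicographic order."""
    entries = table.entries(stype)
    forms = sorted(entries)
    counts = [entries[f].count for f in forms]
    total = sum(counts)
    return forms, [c / total for c in counts]


def sample_syllable(
    table: SyllableTable,
    stype: str,
    rng: np.random.Generator,
    inventory: PhonemeInventory | None = None,
    clusters: ClusterInventory | None = None,
) -> SyllableForm:
    """Draw a syllable of ``stype`` proportional to its perceived count.

    Falls back to :func:`random_syllable` while the type's table is empty.
    """
    entries = table.entries(stype)
    if not entries:
        return random_syllable(stype, rng, inventory, clusters)
    # cumulative-weight cache lives on the table, invalidated by its version
    cache = getattr(table, "_production_cache", None)
    if cache is None:
        cache = table._production_cache = {}
    cached = cache.get(stype)
    if cached is None or cached[0] != table.version:
        forms = sorted(entries)
        cum = list(accumulate(entries[f].count for f in forms))
        cache[stype] = (table.version, forms, cum)
    else:
        _, forms, cum = cache[stype]
    x = rng.random() * cum[-1]
    phonemes = forms[bisect.bisect_right(cum, x)]
    return _as_form(phonemes, stype, inventory)


def _as_form(phonemes: tuple[str, ...], stype: str, inventory) -> SyllableForm:
    inventory = inventory or PhonemeInventory.default()
    i = next(j for j, t in enumerate(phonemes) if t in inventory.vowels)
    return SyllableForm(tuple(phonemes), stype, phonemes[:i], phonemes[i], phonemes[i + 1 :])


def random_syllable(
    stype: str,
    rng: np.random.Generator,
    inventory: PhonemeInventory | None = None,
    clusters: ClusterInventory | None = None,
) -> SyllableForm:
    """A uniformly random legal syllable of ``stype``.

    Uniform over (onset choice) x (vowel) x (coda choice).  In permissive
    cluster mode choices are drawn compositionally: cluster length uniform on
    1..max, then each consonant uniform.
    """
    inventory = inventory or PhonemeInventory.default()
    clusters = clusters or ClusterInventory.english()
    vowels = sorted(inventory.vowels)
    consonants = sorted(inventory.consonants)

    def draw_cluster(legal_set: frozenset) -> tuple[str, ...]:
        if clusters.permissive:
            length = int(rng.integers(1, clusters.max_cluster_len + 1))
            return tuple(consonants[int(rng.integers(0, len(consonants)))] for _ in range(length))
        options = [(c,) for c in consonants] + sorted(legal_set)
        return options[int(rng.integers(0, len(options)))]

    onset = draw_cluster(clusters.onsets) if stype.startswith("C") else ()
    nucleus = vowels[int(rng.integers(0, len(vowels)))]
    coda = draw_cluster(clusters.codas) if stype.endswith("C") else ()
    return SyllableForm(onset + (nucleus,) + coda, stype, onset, nucleus, coda)


def babble(
    table: SyllableTable,
    lexicon,
    rng: np.random.Generator,
    n_syllables: int = 5,
    turn_index: int = 0,
    inventory: PhonemeInventory | None = None,
    clusters: ClusterInventory | None = None,
) -> Utterance:
    """Produce one learner utterance of ``n_syllables`` syllables.

    The default of five syllables per turn reflects the roughly five-syllable
    runs the learner fits into one four-second dialogue turn.
    """
    syllables = []
    for _ in range(n_syllables):
        cand = choose_candidate(lexicon, rng)
        if isinstance(cand, SyllableForm):
            syllables.append(cand)
        else:
            syllables.append(sample_syllable(table, cand, rng, inventory, clusters))
    return Utterance(tuple(syllables), turn_index)
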
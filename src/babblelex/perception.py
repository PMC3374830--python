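"""Exhaustive syllable perception from unsegmented phoneme streams.

The learner hears each teacher utterance as a flat phoneme sequence with no
word or syllable boundaries, so it entertains *every* contiguous substring
that parses as a legal syllable: the pseudo-phoneme stream ``a r e d b o x``
yields the ten overlapping candidates *a, ar, re, red, e, ed, bo, box, o, ox*.
Each perceived occurrence increments a per-type frequency table and stamps the
syllable's last-heard turn; these statistics later drive both production bias
and the reinforcement heuristic.

Streams are perceived one utterance (one dialogue turn) at a time; syllables
never span turn boundaries.  Recency is measured in discrete turn indices.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from .phonology import (
    SYLLABLE_TYPES,
    ClusterInventory,
    PhonemeInventory,
    SyllableForm,
    parse_syllable,
)


@dataclass(frozen=True)
class PhonemeStream:
    """One unsegmented utterance: ordered phoneme tokens plus its turn index."""

    tokens: tuple[str, ...]
    turn_index: int = 0

    @classmethod
    def from_text(cls, text: str, turn_index: int = 0) -> "PhonemeStream":
        return cls(tuple(text.lower().split()), turn_index)

    def __len__(self) -> int:
        return len(self.tokens)


def extract_syllables(
    stream: PhonemeStream,
    inventory: PhonemeInventory | None = None,
    clusters: ClusterInventory | None = None,
) -> list[SyllableForm]:
    """All legal syllables occurring as contiguous substrings of ``stream``.

    Returns a multiset (list): overlapping candidates are all kept, because no
    segmentation knowledge is assumed.  Enumeration is vowel-anchored: every
    substring with exactly one vowel, at most ``max_cluster_len`` flanking
    consonants a side, and legal clusters.  Ordered by start position, then
    length, for determinism.
    """
    inventory = inventory or PhonemeInventory.default()
    clusters = clusters or ClusterInventory.english()
    toks = inventory.normalize(stream.tokens)
    n = len(toks)
    is_v = [t in inventory.vowels for t in toks]
    m = clusters.max_cluster_len
    out: list[tuple[int, SyllableForm]] = []
    for i, v in enumerate(is_v):
        if not v:
            continue
        # consonant runs available left and right of this nucleus
        left = 0
        while left < m and i - left - 1 >= 0 and not is_v[i - left - 1]:
            left += 1
        right = 0
        while right < m and i + right + 1 < n and not is_v[i + right + 1]:
            right += 1
        for a in range(left + 1):
            onset = toks[i - a : i]
            if not clusters.legal_onset(onset):
                continue
            for b in range(right + 1):
                coda = toks[i + 1 : i + 1 + b]
                if not clusters.legal_coda(coda):
                    continue
                stype = ("C" if a else "") + "V" + ("C" if b else "")
                form = SyllableForm(onset + (toks[i],) + coda, stype, onset, toks[i], coda)
                out.append((i - a, form))
    out.sort(key=lambda t: (t[0], len(t[1].phonemes)))
    return [f for _, f in out]


@dataclass
class SyllableStats:
    """Perception statistics for one syllable."""

    count: int = 0
    last_heard: int = -1


class SyllableTable:
    """Per-type frequency/recency tables of perceived syllables.

    One map per syllable type (V, CV, VC, CVC) from phoneme sequence to
    :class:`SyllableStats`.  Production samples within a type, so the maps are
    kept separate.
    """

    def __init__(self):
        self._tables: dict[str, dict[tuple[str, ...], SyllableStats]] = {
            t: {} for t in SYLLABLE_TYPES
        }
        self._version = 0  # bumped on every update; lets samplers cache

    # -- updates -----------------------------------------------------------

    def perceive(
        self,
        stream: PhonemeStream,
        inventory: PhonemeInventory | None = None,
        clusters: ClusterInventory | None = None,
    ) -> "SyllableTable":
        """Increment counts for every syllable occurrence extracted from ``stream``."""
        for form in extract_syllables(stream, inventory, clusters):
            stats = self._tables[form.stype].setdefault(form.phonemes, SyllableStats())
            stats.count += 1
            stats.last_heard = max(stats.last_heard, stream.turn_index)
        self._version += 1
        return self

    # -- queries -----------------------------------------------------------

    @property
    def version(self) -> int:
        return self._version

    def entries(self, stype: str) -> dict[tuple[str, ...], SyllableStats]:
        return self._tables[stype]

    def stats(self, stype: str, phonemes: tuple[str, ...]) -> SyllableStats | None:
        return self._tables[stype].get(tuple(phonemes))

    def count(self, stype: str, phonemes: Iterable[str]) -> int:
        stats = self._tables[stype].get(tuple(phonemes))
        return stats.count if stats else 0

    def last_heard(self, stype: str, phonemes: Iterable[str]) -> int | None:
        stats = self._tables[stype].get(tuple(phonemes))
        return stats.last_heard if stats else None

    def total(self, stype: str) -> int:
        return sum(s.count for s in self._tables[stype].values())

    def rank_syllables(self, stype: str) -> list[tuple[tuple[str, ...], int]]:
        """Syllables of ``stype`` ordered by descending count, ties lexicographic."""
        return sorted(
            ((p, s.count) for p, s in self._tables[stype].items()),
            key=lambda item: (-item[1], item[0]),
        )

    def __iter__(self) -> Iterator[tuple[str, tuple[str, ...], SyllableStats]]:
        for stype in SYLLABLE_TYPES:
            for phonemes, stats in self._tables[stype].items():
                yield stype, phonemes, stats

    # -- I/O ---------------------------------------------------------------

    def write_tsv(self, path: str | Path) -> None:
        """Dump (type, syllable, count, last_heard) rows as TSV."""
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t")
            w.writerow(["type", "syllable", "count", "last_heard"])
            for stype in SYLLABLE_TYPES:
                for phonemes, count in self.rank_syllables(stype):
                    stats = self._tables[stype][phonemes]
                    w.writerow([stype, " ".join(phonemes), count, stats.last_heard])

    def write_rank_csv(self, path: str | Path, stype: str) -> None:
        """Rank-frequency export (rank, syllable, count) for Zipf-style plots."""
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["rank", "syllable", "count"])
            for rank, (phonemes, count) in enumerate(self.rank_syllables(stype), 1):
                w.writerow([rank, " ".join(phonemes), count])


def read_corpus(path: str | Path, start_turn: int = 0) -> list[PhonemeStream]:
    """Read a corpus file: one utterance per line, whitespace-separated symbols,
    ``#`` comments.  Line order assigns consecutive turn indices."""
    streams = []
    turn = start_turn
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        streams.append(PhonemeStream.from_text(line, turn))
        turn += 1
    return streams
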
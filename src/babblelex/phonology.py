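"""Phoneme inventory and syllable phonotactics.

The learner operates on symbolic phoneme streams (ARPAbet-style tokens; the
default inventory is the 39-symbol CMU set, 15 vowels/diphthongs and 24
consonants).  A syllable is onset + nucleus + coda, where the nucleus is a
single vowel and the onset and coda are consonant clusters of up to three
consonants.  Cluster legality is position-dependent (e.g. ``g r`` can open a
syllable but not close one, ``k s`` the reverse) and is checked against an
editable inventory; single consonants are legal in either position.

Syllable types follow the (C)V(C) scheme: ``V``, ``CV``, ``VC`` and ``CVC``,
where ``C`` denotes a whole cluster, so *square* (``s k w eh r``) and *box*
(``b aa k s``) are both CVC.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

VOWEL = "vowel"
CONSONANT = "consonant"
SYLLABLE_TYPES = ("V", "CV", "VC", "CVC")

_DATA = resources.files("babblelex") / "data"


class UnknownPhonemeError(ValueError):
    """A token is not part of the configured phoneme inventory."""

    def __init__(self, symbol: str, position: int | None = None):
        self.symbol = symbol
        self.position = position
        loc = f" at position {position}" if position is not None else ""
        super().__init__(f"unknown phoneme symbol {symbol!r}{loc}")


@dataclass(frozen=True)
class PhonemeInventory:
    """Set of phoneme symbols partitioned into vowels and consonants."""

    vowels: frozenset[str]
    consonants: frozenset[str]

    def __post_init__(self):
        overlap = self.vowels & self.consonants
        if overlap:
            raise ValueError(f"symbols in both categories: {sorted(overlap)}")

    @property
    def symbols(self) -> frozenset[str]:
        return self.vowels | self.consonants

    def category(self, symbol: str, position: int | None = None) -> str:
        symbol = symbol.lower()
        if symbol in self.vowels:
            return VOWEL
        if symbol in self.consonants:
            return CONSONANT
        raise UnknownPhonemeError(symbol, position)

    def is_vowel(self, symbol: str) -> bool:
        return self.category(symbol) == VOWEL

    def normalize(self, tokens: Iterable[str]) -> tuple[str, ...]:
        """Lower-case ``tokens`` and validate membership."""
        out = []
        for i, tok in enumerate(tokens):
            tok = tok.lower()
            if tok not in self.vowels and tok not in self.consonants:
                raise UnknownPhonemeError(tok, i)
            out.append(tok)
        return tuple(out)

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "PhonemeInventory":
        vowels, consonants = set(), set()
        for symbol, category in pairs:
            symbol = symbol.lower()
            if category == VOWEL:
                vowels.add(symbol)
            elif category == CONSONANT:
                consonants.add(symbol)
            else:
                raise ValueError(f"bad category {category!r} for {symbol!r}")
        return cls(frozenset(vowels), frozenset(consonants))

    @classmethod
    def from_file(cls, path: str | Path) -> "PhonemeInventory":
        """Read a two-column (symbol, category) plain-text inventory."""
        pairs = []
        for line in Path(path).read_text().splitlines():
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            symbol, category = line.split()
            pairs.append((symbol, category))
        return cls.from_pairs(pairs)

    @classmethod
    def default(cls) -> "PhonemeInventory":
        """The 39-symbol CMU/ARPAbet inventory."""
        return _default_inventory()


def classify_phoneme(symbol: str, inventory: PhonemeInventory | None = None) -> str:
    """Return ``'vowel'`` or ``'consonant'`` for ``symbol`` per the inventory."""
    inventory = inventory or PhonemeInventory.default()
    return inventory.category(symbol)


@dataclass(frozen=True)
class ClusterInventory:
    """Position-dependent legality of consonant clusters.

    A cluster of length one is always legal in either position.  When
    ``permissive`` is set, any consonant sequence up to ``max_cluster_len`` is
    legal (useful for exploratory corpora); otherwise multi-consonant clusters
    must appear in ``onsets``/``codas``.
    """

    onsets: frozenset[tuple[str, ...]] = frozenset()
    codas: frozenset[tuple[str, ...]] = frozenset()
    max_cluster_len: int = 3
    permissive: bool = False

    def __post_init__(self):
        for name, clusters in (("onset", self.onsets), ("coda", self.codas)):
            for c in clusters:
                if len(c) > self.max_cluster_len:
                    raise ValueError(
                        f"{name} cluster {c} exceeds max length {self.max_cluster_len}"
                    )

    def legal_onset(self, cluster: Sequence[str]) -> bool:
        n = len(cluster)
        if n == 0 or n == 1:
            return True
        if n > self.max_cluster_len:
            return False
        return self.permissive or tuple(cluster) in self.onsets

    def legal_coda(self, cluster: Sequence[str]) -> bool:
        n = len(cluster)
        if n == 0 or n == 1:
            return True
        if n > self.max_cluster_len:
            return False
        return self.permissive or tuple(cluster) in self.codas

    # -- stock inventories -------------------------------------------------

    @classmethod
    def from_file(cls, path: str | Path, **kw) -> "ClusterInventory":
        """Read a cluster file with ``[onset]``/``[coda]`` sections."""
        onsets, codas = set(), set()
        section = None
        for line in Path(path).read_text().splitlines():
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if line.lower() in ("[onset]", "[coda]"):
                section = line.lower()
                continue
            cluster = tuple(line.lower().split())
            if section == "[onset]":
                onsets.add(cluster)
            elif section == "[coda]":
                codas.add(cluster)
            else:
                raise ValueError(f"cluster line {line!r} outside a section")
        return cls(frozenset(onsets), frozenset(codas), **kw)

    @classmethod
    def english(cls) -> "ClusterInventory":
        """Default English onset/coda cluster lists (editable data file)."""
        return _english_clusters()

    @classmethod
    def permissive_mode(cls, max_cluster_len: int = 3) -> "ClusterInventory":
        """Any consonant sequence up to ``max_cluster_len`` is legal."""
        return cls(max_cluster_len=max_cluster_len, permissive=True)

    @classmethod
    def single_consonant(cls) -> "ClusterInventory":
        """Strict mode: only single-consonant onsets and codas."""
        return cls(max_cluster_len=1)


@lru_cache(maxsize=1)
def _default_inventory() -> PhonemeInventory:
    with resources.as_file(_DATA / "cmu_inventory.txt") as p:
        return PhonemeInventory.from_file(p)


@lru_cache(maxsize=1)
def _english_clusters() -> ClusterInventory:
    with resources.as_file(_DATA / "english_clusters.txt") as p:
        return ClusterInventory.from_file(p)


@dataclass(frozen=True)
class SyllableForm:
    """A parsed (C)V(C) syllable: onset cluster, vowel nucleus, coda cluster."""

    phonemes: tuple[str, ...]
    stype: str
    onset: tuple[str, ...]
    nucleus: str
    coda: tuple[str, ...]

    def __post_init__(self):
        assert self.phonemes == self.onset + (self.nucleus,) + self.coda

    def __str__(self) -> str:
        return " ".join(self.phonemes)


def parse_syllable(
    tokens: Sequence[str],
    inventory: PhonemeInventory | None = None,
    clusters: ClusterInventory | None = None,
) -> SyllableForm | None:
    """Parse ``tokens`` as a single syllable, or return None (rejection).

    A sequence is a syllable iff it consists of exactly one vowel preceded by a
    legal (possibly empty) onset cluster and followed by a legal (possibly
    empty) coda cluster.  Unknown symbols raise :class:`UnknownPhonemeError`;
    phonotactic rejection is not an error.
    """
    inventory = inventory or PhonemeInventory.default()
    clusters = clusters or ClusterInventory.english()
    toks = inventory.normalize(tokens)
    if not toks:
        return None
    vowel_at = [i for i, t in enumerate(toks) if t in inventory.vowels]
    if len(vowel_at) != 1:
        return None
    i = vowel_at[0]
    onset, coda = toks[:i], toks[i + 1 :]
    if not clusters.legal_onset(onset) or not clusters.legal_coda(coda):
        return None
    stype = ("C" if onset else "") + "V" + ("C" if coda else "")
    return SyllableForm(toks, stype, onset, toks[i], coda)
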
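"""Synthetic teacher: child-directed speech with pronunciation variability.

Stands in for the human participants of the teaching scenario so the whole
perception-production-reinforcement loop can be run and tested end to end.
The teacher model captures the statistical structure that makes word-form
learning work:

* a small, Zipf-weighted scenario vocabulary in which salient content words
  (colours and shapes) are heavily repeated;
* near-canonical pronunciation of content words versus variable realisation
  of function words (each function entry carries a pool of reduced variants,
  so its phonemic mass is diluted across renderings);
* a noisy phoneme-recognizer channel (independent per-phoneme substitution
  within category, and deletion);
* imperfect approval behaviour — salient words in the learner's babble are
  noticed only with some probability, and praise is occasionally given
  regardless of content ("over-praise"), which is how non-words get
  reinforced;
* talk-over: a fraction of teacher words is spoken outside the turn and never
  reaches the learner.

Approval events record which word the teacher actually heard.  That
annotation is simulator-only ground truth (a real teacher's intent is
unobservable) and is consumed solely by the evaluator.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import numpy as np

from .perception import PhonemeStream
from .phonology import PhonemeInventory
from .production import Utterance
from .reinforcement import ApprovalSet

SALIENT = "salient"
OTHER_WORD = "other_word"
FUNCTION = "function"
ROLES = (SALIENT, OTHER_WORD, FUNCTION)


class ConfigError(ValueError):
    """Inconsistent teacher-profile or vocabulary configuration."""


@dataclass(frozen=True)
class VocabularyEntry:
    orth: str
    canonical: tuple[str, ...]
    role: str
    weight: float
    variants: tuple[tuple[str, ...], ...] = ()

    def __post_init__(self):
        if self.role not in ROLES:
            raise ConfigError(f"bad role {self.role!r} for {self.orth!r}")
        if self.weight <= 0:
            raise ConfigError(f"weight must be positive for {self.orth!r}")


@dataclass(frozen=True)
class TeacherProfile:
    """All tunable behaviour of the synthetic teacher (probabilities in [0,1])."""

    vocabulary: tuple[VocabularyEntry, ...]
    words_per_utterance: float = 7.8  # Poisson mean, clipped to >= 1
    canonical_prob_content: float = 1.0
    canonical_prob_function: float = 0.6
    substitution_rate: float = 0.12
    deletion_rate: float = 0.06
    hearing_prob: float = 0.35
    overpraise_prob: float = 0.03
    talkover_drop: float = 0.05

    def __post_init__(self):
        probs = (
            self.canonical_prob_content,
            self.canonical_prob_function,
            self.substitution_rate,
            self.deletion_rate,
            self.hearing_prob,
            self.overpraise_prob,
            self.talkover_drop,
        )
        if not all(0.0 <= p <= 1.0 for p in probs):
            raise ConfigError("all profile probabilities must lie in [0, 1]")
        if not self.vocabulary:
            raise ConfigError("vocabulary must be non-empty")

    def canonical_prob(self, role: str) -> float:
        return self.canonical_prob_function if role == FUNCTION else self.canonical_prob_content

    def salient_forms(self) -> dict[tuple[str, ...], str]:
        """Canonical phoneme sequence -> orthographic word, salient entries only."""
        return {e.canonical: e.orth for e in self.vocabulary if e.role == SALIENT}

    def word_forms(self) -> dict[tuple[str, ...], str]:
        """Every known proper-word rendering (canonical and variants) -> word."""
        forms: dict[tuple[str, ...], str] = {}
        for e in self.vocabulary:
            forms.setdefault(e.canonical, e.orth)
            for v in e.variants:
                forms.setdefault(v, e.orth)
        return forms


def load_vocabulary(path: str | Path) -> tuple[VocabularyEntry, ...]:
    """Read a vocabulary TSV: orth, canonical phonemes, role, weight, variants
    (pipe-separated phoneme strings, optional column)."""
    entries = []
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].rstrip()
        if not line.strip():
            continue
        parts = line.split("\t")
        if parts[0] == "orthographic":  # header
            continue
        orth, canonical, role, weight = parts[0], parts[1], parts[2], float(parts[3])
        variants = ()
        if len(parts) > 4 and parts[4].strip():
            variants = tuple(tuple(v.split()) for v in parts[4].split("|"))
        entries.append(VocabularyEntry(orth, tuple(canonical.split()), role, weight, variants))
    return tuple(entries)


def default_vocabulary() -> tuple[VocabularyEntry, ...]:
    with resources.as_file(
        resources.files("babblelex") / "data" / "default_vocabulary.tsv"
    ) as p:
        return load_vocabulary(p)


def default_profile(**overrides) -> TeacherProfile:
    """The default child-directed-speech teacher (shapes-and-colours scenario)."""
    return TeacherProfile(vocabulary=default_vocabulary(), **overrides)


def ideal_profile(**overrides) -> TeacherProfile:
    """A noiseless, perfectly attentive teacher drilling two salient words:
    no recognizer noise, no talk-over, every salient word in the learner's
    babble is noticed and approved, and praise is never gratuitous.

    The vocabulary is deliberately minimal and phonotactically inert: both
    words are canonical CVC forms with an ``hh`` onset, the one consonant
    that joins no English onset or coda cluster, so no legal CVC syllable can
    bridge a word boundary (or hide inside a word) and outscore a genuine
    word at an approval.  Under these conditions every salient word the
    learner produces ends up reinforced, making the real and simulated
    reinforcement tallies coincide.
    """
    vocabulary = (
        VocabularyEntry("hen", ("hh", "eh", "n"), SALIENT, 1.0),
        VocabularyEntry("ham", ("hh", "ae", "m"), SALIENT, 1.0),
    )
    params = dict(
        vocabulary=vocabulary,
        words_per_utterance=5.0,
        canonical_prob_content=1.0,
        canonical_prob_function=1.0,
        substitution_rate=0.0,
        deletion_rate=0.0,
        hearing_prob=1.0,
        overpraise_prob=0.0,
        talkover_drop=0.0,
    )
    params.update(overrides)
    return TeacherProfile(**params)


# ---------------------------------------------------------------------------


def pronounce(
    entry: VocabularyEntry, profile: TeacherProfile, rng: np.random.Generator
) -> tuple[str, ...]:
    """Realise one word: canonical with its role's probability, else a uniform
    draw from the entry's variant pool."""
    p = profile.canonical_prob(entry.role)
    if p < 1.0 and not entry.variants:
        raise ConfigError(
            f"{entry.orth!r}: canonical probability {p} < 1 but no variants configured"
        )
    if p >= 1.0 or rng.random() < p:
        return entry.canonical
    return entry.variants[int(rng.integers(0, len(entry.variants)))]


def apply_noise(
    tokens: tuple[str, ...],
    profile: TeacherProfile,
    rng: np.random.Generator,
    inventory: PhonemeInventory | None = None,
) -> tuple[str, ...]:
    """Recognizer channel: per phoneme, delete with ``deletion_rate``, else
    substitute (uniformly within the same category) with ``substitution_rate``."""
    if profile.deletion_rate == 0.0 and profile.substitution_rate == 0.0:
        return tokens
    inventory = inventory or PhonemeInventory.default()
    vowels, consonants = sorted(inventory.vowels), sorted(inventory.consonants)
    out = []
    for tok in tokens:
        if rng.random() < profile.deletion_rate:
            continue
        if rng.random() < profile.substitution_rate:
            pool = vowels if tok in inventory.vowels else consonants
            alternatives = [p for p in pool if p != tok]
            tok = alternatives[int(rng.integers(0, len(alternatives)))]
        out.append(tok)
    return tuple(out)


def generate_teacher_utterance(
    profile: TeacherProfile,
    rng: np.random.Generator,
    turn_index: int = 0,
    inventory: PhonemeInventory | None = None,
) -> tuple[list[str], PhonemeStream]:
    """Sample one teacher turn.

    Words are drawn by weight (Zipf-like repetition of salient words), each is
    realised via :func:`pronounce`, passed through the noise channel, and may
    be dropped entirely by talk-over.  Returns the ground-truth orthographic
    word list and the unsegmented phoneme stream the learner receives.
    """
    vocab = profile.vocabulary
    weights = np.array([e.weight for e in vocab], dtype=float)
    weights /= weights.sum()
    n_words = max(1, int(rng.poisson(profile.words_per_utterance)))
    indices = rng.choice(len(vocab), size=n_words, p=weights)
    words: list[str] = []
    tokens: list[str] = []
    for i in indices:
        entry = vocab[int(i)]
        words.append(entry.orth)
        if profile.talkover_drop > 0.0 and rng.random() < profile.talkover_drop:
            continue  # spoken out of turn; never perceived
        realised = pronounce(entry, profile, rng)
        tokens.extend(apply_noise(realised, profile, rng, inventory))
    return words, PhonemeStream(tuple(tokens), turn_index)


@dataclass(frozen=True)
class ApprovalEvent:
    """Teacher approval: the spoken term and (ground truth) the word heard."""

    term: str
    tokens: tuple[str, ...]
    heard_orth: str | None = None
    heard_form: tuple[str, ...] | None = None


def respond(
    learner_utterance: Utterance,
    profile: TeacherProfile,
    rng: np.random.Generator,
    approvals: ApprovalSet | None = None,
    salient_forms: dict[tuple[str, ...], str] | None = None,
) -> ApprovalEvent | None:
    """Decide whether the teacher approves of the learner's utterance.

    Each salient canonical form occurring as a syllable is noticed with
    ``hearing_prob`` (scanned in utterance order); failing that, approval may
    still be issued with ``overpraise_prob`` — praise with no word behind it.
    """
    approvals = approvals or ApprovalSet.default()
    salient_forms = salient_forms if salient_forms is not None else profile.salient_forms()
    heard_orth = heard_form = None
    for syl in learner_utterance.syllables:
        if syl.phonemes in salient_forms and rng.random() < profile.hearing_prob:
            heard_orth, heard_form = salient_forms[syl.phonemes], syl.phonemes
            break
    if heard_orth is None and not (
        profile.overpraise_prob > 0.0 and rng.random() < profile.overpraise_prob
    ):
        return None
    term, tokens = approvals.terms[int(rng.integers(0, len(approvals.terms)))]
    return ApprovalEvent(term, tokens, heard_orth, heard_form)
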
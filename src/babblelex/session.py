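"""Turn-taking dialogue loop between teacher and learner.

One cycle is a learner turn followed by a teacher turn.  Time is discretised:
each turn advances a global turn counter (one turn per four-second utterance
slot), and a four-minute dialogue block maps to 30 cycles by default; a
standard run is two consecutive blocks with learning carried forward.

Within a cycle the learner babbles, the teacher replies — either an approval
of the utterance it just heard or a fresh stretch of child-directed speech —
the learner perceives the teacher's stream into its syllable tables, and, if
it detects an approval, applies the selection heuristic to its own
immediately-preceding utterance and reinforces the winning CVC syllable.
Approval utterances are themselves perceived into the tables like any other
speech.

The teacher side can be the stochastic simulator or a scripted transcript
(``replay_transcript``), which also allows scripting the learner's side for
replaying recorded or constructed dialogues.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from .evaluation import EvalCounts, FMeasureReport, evaluate_session
from .perception import PhonemeStream, SyllableTable
from .phonology import ClusterInventory, PhonemeInventory, SyllableForm, parse_syllable
from .production import Utterance, babble
from .reinforcement import (
    ApprovalSet,
    Lexicon,
    detect_approval,
    heuristic_select,
    reinforce,
)
from .teacher import (
    ApprovalEvent,
    TeacherProfile,
    apply_noise,
    default_profile,
    generate_teacher_utterance,
    respond,
)


@dataclass(frozen=True)
class SessionConfig:
    seed: int = 0
    cycles_per_block: int = 30
    n_blocks: int = 2
    syllables_per_utterance: int = 5
    heuristic: str = "frequency_recency"
    carry_forward: bool = True  # keep learning across blocks
    profile: TeacherProfile | None = None

    @property
    def n_cycles(self) -> int:
        return self.cycles_per_block * self.n_blocks


def config_from_yaml(path: str | Path) -> SessionConfig:
    """Build a session config from a YAML mapping; the optional ``profile``
    block overrides the default teacher profile's fields."""
    data = yaml.safe_load(Path(path).read_text()) or {}
    profile_overrides = data.pop("profile", None)
    cfg = SessionConfig(**data)
    if profile_overrides:
        cfg = replace(cfg, profile=default_profile(**profile_overrides))
    return cfg


# -- transcript events -------------------------------------------------------


@dataclass(frozen=True)
class LearnerTurn:
    turn: int
    utterance: Utterance


@dataclass(frozen=True)
class TeacherTurn:
    turn: int
    tokens: tuple[str, ...]
    words: tuple[str, ...] | None = None  # ground-truth orthography, if known
    approval: ApprovalEvent | None = None


@dataclass(frozen=True)
class Reinforcement:
    """Outcome of an approval the learner detected."""

    turn: int
    selected: SyllableForm | None  # None: no scorable CVC in the utterance
    heard_orth: str | None = None
    heard_form: tuple[str, ...] | None = None

    @property
    def heuristic_failed(self) -> bool:
        """The teacher heard a word but a different syllable was stored."""
        return self.heard_form is not None and (
            self.selected is None or self.selected.phonemes != self.heard_form
        )


class Transcript:
    """Ordered event log of one session."""

    def __init__(self):
        self.events: list = []

    def append(self, event) -> None:
        self.events.append(event)

    def learner_utterances(self) -> list[Utterance]:
        return [e.utterance for e in self.events if isinstance(e, LearnerTurn)]

    def teacher_turns(self) -> list[TeacherTurn]:
        return [e for e in self.events if isinstance(e, TeacherTurn)]

    def reinforcements(self) -> list[Reinforcement]:
        return [e for e in self.events if isinstance(e, Reinforcement)]

    def render(self) -> str:
        """Human-readable dialogue in transcript notation."""
        lines = []
        for e in self.events:
            if isinstance(e, LearnerTurn):
                lines.append(f"D: {e.utterance.render()}")
            elif isinstance(e, TeacherTurn):
                note = ""
                if e.approval is not None:
                    heard = e.approval.heard_orth or "-"
                    note = f"    [approval: {e.approval.term!r}, heard={heard}]"
                lines.append(f"T: {' '.join(e.tokens)}{note}")
            elif isinstance(e, Reinforcement):
                if e.selected is not None:
                    lines.append(f"   -> ({e.selected}) moves into ilex")
                else:
                    lines.append("   -> reinforcement detected, no scorable CVC syllable")
        return "\n".join(lines)

    def to_replay_text(self) -> str:
        """Serialise both dialogue sides in the replay file format."""
        lines = []
        for e in self.events:
            if isinstance(e, LearnerTurn):
                lines.append(f"L: {e.utterance.render()}")
            elif isinstance(e, TeacherTurn):
                ann = ""
                if e.approval is not None and e.approval.heard_orth:
                    ann = f" | heard={e.approval.heard_orth}"
                lines.append(f"T: {' '.join(e.tokens)}{ann}")
        return "\n".join(lines) + "\n"

    def to_dicts(self) -> list[dict]:
        """Machine-readable event stream."""
        out = []
        for e in self.events:
            if isinstance(e, LearnerTurn):
                out.append(
                    {"event": "learner", "turn": e.turn,
                     "syllables": [list(s.phonemes) for s in e.utterance.syllables]}
                )
            elif isinstance(e, TeacherTurn):
                out.append(
                    {"event": "teacher", "turn": e.turn, "tokens": list(e.tokens),
                     "words": list(e.words) if e.words else None,
                     "approval": e.approval.term if e.approval else None,
                     "heard": e.approval.heard_orth if e.approval else None}
                )
            elif isinstance(e, Reinforcement):
                out.append(
                    {"event": "reinforcement", "turn": e.turn,
                     "selected": list(e.selected.phonemes) if e.selected else None,
                     "heard": e.heard_orth, "heuristic_failed": e.heuristic_failed}
                )
        return out


# -- teacher drivers ---------------------------------------------------------


class StochasticTeacher:
    """Synthetic-teacher driver: approves what it hears, otherwise chats."""

    def __init__(self, profile: TeacherProfile, rng: np.random.Generator,
                 inventory: PhonemeInventory, approvals: ApprovalSet):
        self.profile = profile
        self.rng = rng
        self.inventory = inventory
        self.approvals = approvals

    def turn(self, prev_utterance: Utterance | None, turn_index: int):
        event = None
        prefix_words: list[str] = []
        prefix_tokens: tuple[str, ...] = ()
        if prev_utterance is not None:
            event = respond(prev_utterance, self.profile, self.rng, self.approvals)
            if event is not None:
                # approvals are embedded in continuing speech ("very good
                # and ..."), spoken through the same noisy channel
                prefix_words = event.term.split()
                prefix_tokens = apply_noise(
                    event.tokens, self.profile, self.rng, self.inventory
                )
        words, stream = generate_teacher_utterance(
            self.profile, self.rng, turn_index, self.inventory
        )
        return (
            prefix_words + words,
            PhonemeStream(prefix_tokens + stream.tokens, turn_index),
            event,
        )

    def exhausted(self) -> bool:
        return False


@dataclass(frozen=True)
class ScriptTurn:
    tokens: tuple[str, ...]
    heard_orth: str | None = None


class ScriptedTeacher:
    """Plays back a fixed sequence of teacher turns."""

    def __init__(self, turns: list[ScriptTurn]):
        self.turns = list(turns)
        self._i = 0

    def turn(self, prev_utterance, turn_index: int):
        st = self.turns[self._i]
        self._i += 1
        event = None
        if st.heard_orth is not None:
            event = ApprovalEvent("scripted", st.tokens, st.heard_orth, None)
        return None, PhonemeStream(st.tokens, turn_index), event

    def exhausted(self) -> bool:
        return self._i >= len(self.turns)


# -- the loop ----------------------------------------------------------------


@dataclass
class SessionResult:
    config: SessionConfig
    transcript: Transcript
    table: SyllableTable
    lexicon: Lexicon
    counts: EvalCounts
    reports: dict[str, FMeasureReport]


def run_session(
    config: SessionConfig | None = None,
    teacher=None,
    learner_script: dict[int, tuple[SyllableForm, ...]] | None = None,
    inventory: PhonemeInventory | None = None,
    clusters: ClusterInventory | None = None,
    approvals: ApprovalSet | None = None,
) -> SessionResult:
    """Run one full dialogue session and evaluate it.

    All randomness (learner and stochastic teacher alike) is drawn from a
    single generator seeded with ``config.seed``; the draw order per cycle is
    learner first (candidate, then syllable, per syllable), then teacher.
    ``learner_script`` maps cycle numbers to fixed learner syllable sequences
    and overrides babbling for those cycles (used by transcript replay).
    """
    config = config or SessionConfig()
    profile = config.profile or default_profile()
    inventory = inventory or PhonemeInventory.default()
    clusters = clusters or ClusterInventory.english()
    approvals = approvals or ApprovalSet.default()
    rng = np.random.default_rng(config.seed)
    if teacher is None:
        teacher = StochasticTeacher(profile, rng, inventory, approvals)

    table = SyllableTable()
    lexicon = Lexicon()
    transcript = Transcript()
    turn = 0
    for cycle in range(config.n_cycles):
        if teacher.exhausted():
            break
        if not config.carry_forward and cycle > 0 and cycle % config.cycles_per_block == 0:
            table = SyllableTable()
            lexicon = Lexicon()
        # learner turn
        if learner_script is not None and cycle in learner_script:
            utterance = Utterance(tuple(learner_script[cycle]), turn)
        else:
            utterance = babble(
                table, lexicon, rng, config.syllables_per_utterance,
                turn, inventory, clusters,
            )
        transcript.append(LearnerTurn(turn, utterance))
        turn += 1
        # teacher turn
        words, stream, event = teacher.turn(utterance, turn)
        transcript.append(
            TeacherTurn(turn, stream.tokens, tuple(words) if words else None, event)
        )
        # the previous utterance is analysed against the statistics heard
        # *before* the approval: the approval turn itself is perceived after
        # reinforcement, so its own syllables cannot claim perfect recency
        if detect_approval(stream, approvals):
            selected = heuristic_select(utterance, table, turn, config.heuristic)
            if selected is not None:
                reinforce(lexicon, selected, turn)
            transcript.append(
                Reinforcement(
                    turn, selected,
                    event.heard_orth if event else None,
                    event.heard_form if event else None,
                )
            )
        table.perceive(stream, inventory, clusters)
        turn += 1

    counts, reports = evaluate_session(
        transcript, lexicon, profile.salient_forms(), profile.word_forms()
    )
    return SessionResult(config, transcript, table, lexicon, counts, reports)


# -- transcript replay -------------------------------------------------------

_HEARD_RE = re.compile(r"\|\s*heard\s*=\s*(\S+)\s*$")
_SYLLABLE_RE = re.compile(r"\(([^()]*)\)")


def parse_replay_file(
    path: str | Path,
    inventory: PhonemeInventory | None = None,
    clusters: ClusterInventory | None = None,
) -> tuple[list[ScriptTurn], dict[int, tuple[SyllableForm, ...]]]:
    """Parse a replay transcript.

    Format: one turn per line; ``T:`` lines are teacher turns (whitespace
    phonemes, optional ``| heard=word`` annotation), ``L:`` lines script the
    learner utterance for the following teacher turn as parenthesised
    syllables, e.g. ``L: (r eh d) (ao s)``.  ``#`` starts a comment.  Cycles
    are driven by teacher turns; a teacher turn without a preceding ``L:``
    line leaves the learner babbling for that cycle.
    """
    inventory = inventory or PhonemeInventory.default()
    clusters = clusters or ClusterInventory.english()
    turns: list[ScriptTurn] = []
    learner_script: dict[int, tuple[SyllableForm, ...]] = {}
    pending_learner: tuple[SyllableForm, ...] | None = None
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.upper().startswith("L:"):
            body = line[2:].strip()
            syllables = []
            for group in _SYLLABLE_RE.findall(body):
                form = parse_syllable(group.split(), inventory, clusters)
                if form is None:
                    raise ValueError(f"unparseable scripted syllable ({group})")
                syllables.append(form)
            pending_learner = tuple(syllables)
        elif line.upper().startswith("T:"):
            body = line[2:].strip()
            heard = None
            m = _HEARD_RE.search(body)
            if m:
                heard = m.group(1)
                body = body[: m.start()].strip()
            if pending_learner is not None:
                learner_script[len(turns)] = pending_learner
                pending_learner = None
            turns.append(ScriptTurn(tuple(body.lower().split()), heard))
        else:
            raise ValueError(f"replay line must start with 'L:' or 'T:': {raw!r}")
    return turns, learner_script


def replay_transcript(
    path: str | Path,
    config: SessionConfig | None = None,
    **kwargs,
) -> SessionResult:
    """Run the session loop with the teacher (and optionally learner) side
    read from a transcript file instead of sampled."""
    config = config or SessionConfig()
    turns, learner_script = parse_replay_file(path)
    if config.n_cycles < len(turns):
        config = replace(config, cycles_per_block=len(turns), n_blocks=1)
    return run_session(
        config, teacher=ScriptedTeacher(turns), learner_script=learner_script, **kwargs
    )
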
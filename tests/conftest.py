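"""Shared fixtures: inventories, perceived-corpus fixtures, replay scripts.

All corpora are synthetic, generated here at test time; the participant-style
perceived corpus reproduces the published per-syllable counts by construction
(each word repeated the recorded number of times in isolation).
"""

import pytest

from babblelex.phonology import ClusterInventory, PhonemeInventory
from babblelex.perception import PhonemeStream, SyllableTable


@pytest.fixture(scope="session")
def inventory():
    return PhonemeInventory.default()


@pytest.fixture(scope="session")
def clusters():
    return ClusterInventory.english()


@pytest.fixture(scope="session")
def pseudo_inventory():
    """Letters-as-pseudo-phonemes inventory (a e i o u vowels)."""
    vowels = [(c, "vowel") for c in "aeiou"]
    consonants = [(c, "consonant") for c in "bcdfghjklmnpqrstvwxyz"]
    return PhonemeInventory.from_pairs(vowels + consonants)


# Synthetic per-utterance corpus emulating one effective participant's
# perceived statistics: (utterance, repetitions).  Repetitions are chosen so
# that after exhaustive extraction the salient CVC words come out at the
# recorded counts (red 27, green 25, cross 17; 'r eh d z' contributes to
# 'r eh d', bare 'r eh' fillers lift the CV count of red's prefix to 51),
# with function-word renderings and word fragments lower down.
PARTICIPANT_CORPUS = [
    ("r eh d", 17),
    ("r eh d z", 10),
    ("r eh", 24),
    ("g r iy n", 25),
    ("k r ao s", 17),
    ("dh ae t s", 8),
    ("dh ae", 26),
    ("dh ah", 16),
    ("k ah l", 13),
    ("hh ah t", 10),
    ("s er k", 9),
    ("y eh s", 8),
]


@pytest.fixture(scope="session")
def participant_table(inventory, clusters):
    """A syllable table over the synthetic participant corpus (one utterance
    per turn, so no cross-utterance syllables arise)."""
    table = SyllableTable()
    turn = 0
    for phonemes, count in PARTICIPANT_CORPUS:
        for _ in range(count):
            table.perceive(PhonemeStream.from_text(phonemes, turn), inventory, clusters)
            turn += 1
    return table


REPLAY_4A_STYLE = """\
# Scripted dialogue reconstructing a successful teaching episode: the teacher
# drills red/green/model/rain/cross, approves five times, and the heuristic
# moves the intended CVC syllable into the lexicon each time.
L: (b ah) (g iy)
T: dh ih s ih z ah r eh d b aa k s
L: (n uw) (m ah)
T: r eh d ae n d g r iy n
L: (ao k s) (ow d z) (ae) (r eh d) (ao s)
T: w eh l d ah n | heard=red
L: (g ah)
T: l uh k ae t dh ah m ao d l ae n d dh ah r ey n
L: (m ao d l) (iy)
T: g uh d | heard=model
L: (r ey n) (ow)
T: w eh l d ah n | heard=rain
L: (ah) (g r iy n)
T: v eh r iy g uh d | heard=green
L: (m uh)
T: dh ae t s ah k r ao s ae n d ah k r ao s
L: (iy n) (r ey n) (r ey n) (m ao d l) (k r ao s)
T: v eh r iy d g uh d eh n d | heard=cross
"""


@pytest.fixture()
def replay_file(tmp_path):
    p = tmp_path / "dialogue.txt"
    p.write_text(REPLAY_4A_STYLE)
    return p
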
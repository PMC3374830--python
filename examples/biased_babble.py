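"""From random babble to frequency-biased production.

Before any perception the learner babbles uniformly random legal syllables.
After hearing speech, it samples syllables proportional to perceived counts
(counts 1, 3, 6 give chances 1/10, 3/10, 6/10), and learnt words join the
candidate pool directly.
"""

import numpy as np

from babblelex import (
    Lexicon,
    PhonemeStream,
    SyllableTable,
    babble,
    parse_syllable,
    reinforce,
    syllable_distribution,
)

rng = np.random.default_rng(11)
table = SyllableTable()

print("initial random babble:")
for _ in range(3):
    print("  D:", babble(table, Lexicon(), rng).render())

# the teacher repeats three words with different frequencies
for text, reps in [("s ah n", 1), ("b ao l", 3), ("hh eh n", 6)]:
    for turn in range(reps):
        table.perceive(PhonemeStream.from_text(text, turn))

forms, probs = syllable_distribution(table, "CVC")
print("\nproduction chances after perception (counts 1, 3, 6):")
for form, p in zip(forms, probs):
    print(f"  {' '.join(form):<8} {p:.1f}")

lexicon = Lexicon()
reinforce(lexicon, parse_syllable("hh eh n".split()))
print("\nbiased babble with 'hh eh n' in the lexicon (5 candidates per slot):")
for _ in range(3):
    print("  D:", babble(table, lexicon, rng).render())
# Babble is now dominated by the frequent and the learnt forms, while still
# quasi-random — exactly the bias that lets the teacher hear real words.
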
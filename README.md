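# babblelex

A symbolic simulator of one mechanism in early word-form acquisition: how a
babbling learner, hearing unsegmented streams of phonemes, can come to
produce and retain one-syllable word forms purely from the statistics of the
speech directed at it — frequency-biased babble plus approval-triggered
reinforcement. It is written for researchers in developmental cognitive
science, computational linguistics and developmental robotics who want a
tested, reproducible model of this transition to probe, extend, or use as a
baseline.

## The model

The learner perceives each teacher utterance as a flat phoneme sequence
(ARPAbet symbols) with no word or syllable boundaries, and entertains
**every** contiguous substring that is a legal syllable of type V, CV, VC or
CVC — where C is a cluster of 1–3 consonants with position-dependent
legality — keeping a count n(s) and a last-heard turn for each. The
pseudo-phoneme stream `a r e d b o x` yields the ten overlapping candidates
*a, ar, re, red, e, ed, bo, box, o, ox*.

Production is quasi-random babble biased to the input: per syllable slot a
candidate is drawn uniformly over the four types plus each learnt word, and
a type is filled by sampling syllables with probability n(s)/Σn — counts
1, 3, 6 give chances 1/10, 3/10, 6/10.

When the teacher replies with an approval term ("well done", "good", ...),
detected as a phonemic substring, the learner scores the CVC syllables s of
its previous utterance by

    score(s) = n(s) / (1 + Δt(s)),    Δt = turns since the teacher last said s,

and stores the argmax in its lexicon (*ilex*). Learning is scored with the
equally-weighted F-measure F = 2·tp/(2·tp + fp + fn) in four variants: false
positives narrow (non-words) or broad (plus proper-but-non-salient words),
and false negatives either counted (real reinforcement) or zero by
definition (simulated reinforcement — every salient word the learner uttered
counts as learnt).

A configurable synthetic teacher closes the loop: Zipf-weighted
child-directed vocabulary, canonical pronunciation of content words vs
variable renderings of function words, per-phoneme recognizer noise,
imperfect attention and over-praise. See `docs/methods.md` for the full
account.

## Worked example

```python
from babblelex import SessionConfig, run_session

result = run_session(SessionConfig(seed=9))   # 2 x 30 dialogue cycles
print(result.transcript.render().splitlines()[-5])
for phonemes, entry in result.lexicon.items():
    print(" ".join(phonemes), entry.reinforcement_count)
```

prints a dialogue tail and the final lexicon:

```
D: (d ah n) (r eh d) (r eh d) (b l aa g) (hh aa t)
b aa jh 1
d ah n 1
r eh d 7
g r iy n 2
```

The learner has picked up *red* (`r eh d`, reinforced 7×) and *green*
(`g r iy n`) — salient words its teacher was drilling — alongside two
non-words: `d ah n` is the tail of "well done" and `b aa jh` a
recognizer-garbled fragment, both reinforced by over-generous praise. The
session's evaluation (`result.counts`, `result.reports`) tallies 5 salient
words produced, 2 learnt, 3 missed by the teacher, 2 non-words, giving
F1-1 = 0.44 under real reinforcement and F1-2 = 0.83 under simulated
reinforcement — the gap measures how much learning the teacher's inattention
cost.

The `examples/` directory holds one short script per capability: syllable
extraction, perception and Zipf ranking, biased babble, full sessions, and
re-scoring the original study's outcome counts. A thin CLI mirrors them:
`babblelex run|replay|eval|zipf`.

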
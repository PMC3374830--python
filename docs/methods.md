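# Methods

`babblelex` is a symbolic simulator of one mechanism in early word-form
acquisition: the transition from random syllabic babble to the production and
reinforcement of one-syllable word forms, driven purely by the statistics of
the speech a learner hears. This note describes the model, its parameters,
the synthetic teacher, and the design decisions taken where the mechanism
left room.

## The mechanism

**Perception.** Teacher speech arrives as a flat sequence of ARPAbet phoneme
tokens with no word or syllable boundaries. The learner entertains *every*
contiguous substring that is a phonotactically legal syllable of type V, CV,
VC or CVC, where "C" denotes a cluster of one to three consonants whose
legality is position-dependent (onset vs coda) and checked against an
editable inventory. Candidates overlap: the pseudo-phoneme stream
`a r e d b o x` yields *a, ar, re, red, e, ed, bo, box, o, ox*. Each
occurrence increments a per-type frequency table and stamps the syllable's
last-heard turn. Streams are perceived one utterance (one dialogue turn) at
a time; nothing spans turns. Implementation enumerates syllables anchored on
each vowel; a brute-force all-substrings oracle verifies equivalence in the
tests.

**Production.** Each learner turn emits `syllables_per_utterance` syllables
(default 5, roughly what fits a four-second turn). Per syllable, a candidate
is drawn uniformly over the four types plus every lexicon word (two learnt
words give six candidates at 1/6); a chosen type is then filled by sampling
perceived syllables of that type proportional to their counts (counts 1, 3, 6
give chances 0.1/0.3/0.6), or by a uniformly random legal syllable while the
type's table is empty — the initial random babble. A chosen lexicon word is
emitted directly.

**Reinforcement.** When the learner detects an approval term ("well done",
"good", "clever", "yes", "very good") as a contiguous phonemic substring of
the teacher turn that immediately follows its own utterance, it scores the
CVC syllables of that utterance by

    score(s) = count(s) / (1 + Δt(s)),   Δt = turns since s was last heard,

with never-heard syllables scoring zero, and stores the argmax in its
lexicon (*ilex*). Only CVC forms are candidates, matching a scenario in
which nearly all target words are closed monosyllables. The score's
functional form is a swappable strategy (an exponential-decay variant ships
alongside); this quotient is the simplest form combining the stated
ingredients — frequency, teacher recency, and syllable type.

**Evaluation.** Lexicon entries are classified against the scenario
dictionaries as salient words (tp), other proper words, or non-words, and
combined with the distinct salient words the learner produced into four
equally-weighted F-measures `2tp/(2tp+fp+fn)`: F1 vs F2 narrow/broaden the
false positives (non-words only vs non-words plus other words), and the
"-1"/"-2" conditions score real reinforcement (fn = produced-but-unlearnt,
including heuristic failures) vs simulated reinforcement (every produced
salient word counts; fn = 0). Reported values are rounded half-up to two
decimals; raw values are retained. `f_measure(0,0,0)` is defined as 0 with a
warning so reports stay total.

## Ordering inside a dialogue cycle

One cycle is a learner turn followed by a teacher turn. The approval scan
applies only to the teacher turn immediately following a learner utterance,
and reinforcement targets only that utterance. Two ordering decisions
matter:

* **Approvals are perceived into the tables like any other speech** — but
  only *after* the reinforcement analysis of the preceding utterance. If the
  approval turn were perceived first, its own syllables (`w eh l d`,
  `g uh d`, ...) would enter the analysis with perfect recency and routinely
  outscore the word the teacher was praising.
* **The stochastic teacher embeds approvals in continuing speech** ("very
  good and ..."), as attentive teachers do. A teacher who utters bare
  approval terms in a high-approval regime starves the salient statistics of
  recency until approval fragments dominate both perception and production.

## The synthetic teacher

The teacher emulates the statistical structure of child-directed speech in a
shapes-and-colours teaching game:

* **Vocabulary** (editable TSV): ~24 entries with Zipf-like weights — the
  top salient word appears ~50 times in ~600 words, matching observed
  teaching sessions. Roles are `salient` (content words being taught),
  `other_word` (proper but non-salient: "this", "look", ...), `function`.
* **Pronunciation**: content words are realised canonically
  (`canonical_prob_content = 1.0`); function words are realised canonically
  with `canonical_prob_function = 0.6`, else uniformly from a per-entry pool
  of reduced variants ("that" → `dh ae` / `dh ah t` / `dh eh t`). This is
  the frequency-dilution structure: variable renderings spread a function
  word's phonemic mass, so consistently-pronounced salient words climb the
  perceived rankings. A canonical probability below 1 with an empty variant
  pool is a configuration error.
* **Recognizer channel**: independent per-phoneme deletion (rate 0.06) and
  within-category substitution (rate 0.12), giving ≈ 0.82³ ≈ 55% intact
  recognition of a three-phoneme word — inside the 45–61% range observed for
  salient words with real recognizers. These rates are free knobs of a
  deliberately simple channel, not estimates of any particular recognizer.
* **Behaviour**: a salient word in the learner's babble is noticed with
  `hearing_prob = 0.35` (teachers miss most of them), praise is given
  without cause with `overpraise_prob = 0.03` per learner turn (the route by
  which non-words are reinforced), and `talkover_drop = 0.05` of teacher
  words are spoken over the learner's turn and never perceived.
* **Session scale**: `words_per_utterance` is Poisson with mean 7.8, so a
  standard 60-turn dialogue delivers ≈ 470 teacher words — the observed
  per-participant mean.

Approval events record which word the teacher heard. That annotation is
simulator-only ground truth, consumed by the evaluator to count heuristic
failures; the learner never sees it.

What the generator does **not** emulate: prosody and stress, acoustics,
dynamic turn-taking, semantics or grounding, per-participant personality
beyond the profile knobs, and the long-tailed vocabulary of real speech
(the scenario vocabulary is closed). Passing tests therefore show that the
mechanism behaves as specified under CDS-like *statistics*, not that it
would survive raw audio.

## The ideal-teacher profile and what it can(not) guarantee

For property testing, `ideal_profile()` removes every failure channel: no
noise, no talk-over, `hearing_prob = 1`, `overpraise_prob = 0`, canonical
pronunciation only. Under it, every salient word the learner utters is
approved, and the intended invariant is that real reinforcement equals the
simulated upper bound (nothing is "missed").

That equality is *not* automatic, because an approval reinforces the
highest-scoring CVC of the utterance, not the word the teacher heard. Two
structural hazards remain even in ideal conditions:

1. **Embedded and word-bridging syllables.** A word like *box*
   (`b aa k s`) contains the CVC `b aa k`, which accrues exactly the same
   count and recency and precedes it lexicographically — under the adopted
   tie-break *box* can never win its own approval. Similarly `d r eh d`
   bridges adjacent *red red*, and "clever" followed by any consonant-initial
   word yields a legal `v er C`.
2. **Crowding.** With three or more equal-weight words, once some words are
   learnt they join the candidate pool, flood utterances, and the argmax
   keeps re-reinforcing them; the rarest produced word can stay unlearnt at
   session end (measured: 8/100 seeds fail the equality with three words,
   26/100 with four).

The shipped ideal profile therefore drills **two** salient words, *hen*
(`hh eh n`) and *ham* (`hh ae m`): `hh` joins no English onset or coda
cluster, so no legal CVC hides inside a word or bridges a boundary, and with
two words crowding cannot strand either of them. Under this profile the
equality held in 500/500 seeded standard sessions. The hazards above are
real properties of the mechanism, documented rather than patched.

## Numerical and procedural choices

* Single `numpy.random.Generator` per session; fixed draw order (learner
  candidate, then syllable, per slot; then teacher response, then teacher
  speech), so transcripts are bit-reproducible under a seed.
* Heuristic ties break toward smaller Δt, then lexicographic phoneme order.
  Rank listings break count ties lexicographically.
* Recency is discrete dialogue turns (one turn ≈ one four-second utterance
  slot); a four-minute block is 30 cycles, a standard run two blocks with
  learning carried forward (`carry_forward=False` resets tables and lexicon
  at block boundaries).
* Phoneme symbols are case-insensitive, normalised to lower case; unknown
  symbols raise an error naming the token and its position, while
  phonotactic rejection of a candidate syllable is not an error.
* Clusters longer than three consonants are always rejected (*glimpsed*).
* The default English onset/coda lists are an implementer-compiled
  approximation of standard phonotactics, shipped as an editable data file;
  a permissive mode (any cluster ≤ 3) and a strict single-consonant mode are
  provided. The coda list includes syllabic-l codas (`d l`, `t l`) so
  perceived forms like `m ao d l` ("model") count as closed syllables.
* Descriptive statistics report both sample and population SD (the reporting
  convention of the source tables is unstated; the sample SD reproduces
  them). Columns affected by the filtered set exclude it from summaries.
* The bundled per-set outcome table reproduces the published F-measures at
  two decimals in 19 of 20 cells; the remaining cell (set 4, F2-1)
  recomputes to 0.31 against a printed 0.32 and is documented as a known
  rounding discrepancy rather than asserted.

## Problem sizes used in tests

Property tests run at desk scale: sampling laws use 10⁵ seeded draws (≈3
standard errors of tolerance), extraction equivalence uses 1 000 random
streams of length ≤ 12, Monte-Carlo production checks use 10⁴ utterances,
and session-level properties use 50–100 seeded replicates of the standard
60-cycle dialogue. The full suite completes in well under a minute.

## Known limitations

* The reinforcement score is one plausible member of the family the
  mechanism sketches; alternatives (e.g. exponential recency decay) are
  pluggable but not calibrated against human-interaction data.
* Sub-syllable competition (the *box*/`b aa k` case) means some cluster-coda
  words are unlearnable under deterministic tie-breaking.
* Approval detection is exact substring matching of canonical renderings;
  a garbled approval is simply missed (the noise channel supplies this
  failure mode).
* Group-level human results depend on participant behaviour that is outside
  the simulator; only the deterministic computations and the mechanism's
  statistical properties are reproducible here.
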
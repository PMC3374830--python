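"""A full teaching dialogue with the synthetic teacher, evaluated.

Runs the standard two-block session (2 x 30 cycles of learner/teacher turns)
under the default child-directed-speech profile — recognizer noise, variable
function-word pronunciation, imperfect hearing, occasional over-praise — and
prints the transcript tail, the final lexicon and all four F-measures.
"""

from babblelex import SessionConfig, run_session

result = run_session(SessionConfig(seed=9))

print("transcript (last 8 events):")
print("\n".join(result.transcript.render().splitlines()[-8:]))

print("\nfinal lexicon (ilex):")
for phonemes, entry in result.lexicon.items():
    print(f"  ({' '.join(phonemes)})  first learnt turn {entry.first_learned_turn},"
          f" reinforced {entry.reinforcement_count}x")

c = result.counts
print(f"\nsalient words produced: {c.produced_salient}  learnt: {c.tp}  "
      f"missed: {c.fn_missed}  non-words: {c.fp_nonwords}  other words: {c.fp_other}")
for variant, report in result.reports.items():
    print(f"  {variant} = {report.rounded:.2f}")
# The '-1' scores reflect what the (imperfect) teacher actually reinforced;
# the '-2' scores are the simulated-reinforcement upper bound in which every
# salient word the learner uttered counts as learnt.
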
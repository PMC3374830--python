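# Aggregated per-set reinforcement outcomes from the five-set human-robot
# teaching study. Columns:
#   set            experiment set number
#   participants   participants in the set
#   produced       salient words produced by the robot (simulated-reinforcement tp)
#   missed         words produced but not reinforced (includes heuristic failures)
#   heuristic_failed  approvals where the selection heuristic stored the wrong
#                     syllable (subset of missed)
#   learnt         salient words learnt (real-reinforcement tp)
#   nonwords       non-words learnt (false positives, narrow definition)
#   other_words    proper but non-salient words learnt (extra fp, broad definition)
set	participants	produced	missed	heuristic_failed	learnt	nonwords	other_words
1	7	22	17	1	5	11	2
2	7	8	4	0	4	9	5
3	6	14	11	2	3	11	6
4	7	18	12	1	6	11	4
5	7	17	10	0	7	13	5
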
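# Per-participant speech and perception statistics from the five-set
# human-robot teaching study (34 participants; participant 2G's orthographic
# transcription was unavailable, so its word counts are blank). Columns:
#   set  participant  total_words  different_words  different_syllables
#   different_cvc_syllables  salient_in_top10_spoken  salient_in_top10_perceived
#   salient_uttered_by_robot
# Set 2 used a syllabifier filter, so syllable-derived columns
# (different_syllables, different_cvc_syllables, salient_in_top10_perceived,
# salient_uttered_by_robot) are excluded from cross-set summaries.
set	participant	total_words	different_words	different_syllables	different_cvc_syllables	salient_in_top10_spoken	salient_in_top10_perceived	salient_uttered_by_robot
1	1A	282	38	267	96	6	5	5
1	1B	387	76	358	126	4	0	2
1	1C	447	53	284	99	5	3	6
1	1D	481	78	317	116	7	5	4
1	1E	825	84	458	199	5	4	4
1	1F	559	121	453	189	5	3	1
1	1G	398	79	306	117	4	0	0
2	2A	627	53	149	38	5	2	1
2	2B	475	61	98	21	5	2	2
2	2C	876	113	170	45	3	1	1
2	2D	832	113	176	44	4	2	0
2	2E	229	20	86	21	8	2	1
2	2F	729	109	151	28	1	0	1
2	2G			139	35		1	2
3	3A	454	57	316	114	4	3	4
3	3B	165	20	181	61	7	3	2
3	3C	330	56	297	112	8	4	2
3	3D	110	27	171	57	2	2	2
3	3E	297	48	304	118	7	3	3
3	3F	656	135	549	240	3	2	1
4	4A	611	92	426	180	4	4	3
4	4B	368	44	359	154	4	2	1
4	4C	654	84	515	225	6	1	2
4	4D	692	128	488	212	3	2	3
4	4E	704	100	476	203	4	2	2
4	4F	234	65	298	110	8	4	4
4	4G	180	24	227	80	5	3	3
5	5A	558	118	492	213	2	3	2
5	5B	681	145	539	235	5	3	1
5	5C	491	46	301	117	6	3	3
5	5D	221	53	243	85	4	3	2
5	5E	715	120	474	211	4	2	2
5	5F	189	20	139	46	6	5	5
5	5G	83	7	52	13	2	2	2
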
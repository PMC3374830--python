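"""Exhaustive overlapping-syllable extraction from an unsegmented stream.

The learner has no segmentation knowledge, so it entertains every contiguous
substring that is a legal syllable.  First with letters as pseudo-phonemes
(single-consonant clusters), then with a real ARPAbet utterance.
"""

from babblelex import ClusterInventory, PhonemeInventory, PhonemeStream, extract_syllables

# pseudo-phoneme demonstration: "a red box" with no word boundaries
pseudo = PhonemeInventory.from_pairs(
    [(c, "vowel") for c in "aeiou"] + [(c, "consonant") for c in "bcdfghjklmnpqrstvwxyz"]
)
stream = PhonemeStream.from_text("a r e d b o x")
sylls = extract_syllables(stream, pseudo, ClusterInventory.single_consonant())
print("stream:", " ".join(stream.tokens))
print("candidate syllables:", ", ".join("".join(s.phonemes) for s in sylls))
# -> a, ar, re, red, e, ed, bo, box, o, ox : ten overlapping candidates, four
#    of which (red, box, ...) happen to be real words.

# the same mechanism on ARPAbet phonemes with English cluster phonotactics
utterance = PhonemeStream.from_text("dh ae t s ah r eh d b aa k s")
print("\nutterance:", " ".join(utterance.tokens), "(\"that's a red box\")")
for form in extract_syllables(utterance):
    print(f"  {form.stype:<3} {' '.join(form.phonemes)}")
# Every line is one legal (C)V(C) parse; note the overlapping CVC candidates
# 'r eh d' and 'b aa k s' alongside word-bridging fragments.
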
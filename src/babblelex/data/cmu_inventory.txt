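# 39-symbol ARPAbet phoneme inventory (CMU pronouncing-dictionary symbols,
# lower case, no stress marks). Two columns: symbol, category.
aa	vowel
ae	vowel
ah	vowel
ao	vowel
aw	vowel
ay	vowel
eh	vowel
er	vowel
ey	vowel
ih	vowel
iy	vowel
ow	vowel
oy	vowel
uh	vowel
uw	vowel
b	consonant
ch	consonant
d	consonant
dh	consonant
f	consonant
g	consonant
hh	consonant
jh	consonant
k	consonant
l	consonant
m	consonant
n	consonant
ng	consonant
p	consonant
r	consonant
s	consonant
sh	consonant
t	consonant
th	consonant
v	consonant
w	consonant
y	consonant
z	consonant
zh	consonant
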
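# English onset and coda consonant clusters (ARPAbet symbols), one cluster per
# line, space-separated. Compiled from standard English phonotactics; edit to
# taste — single consonants are always legal in both positions and need not be
# listed. Clusters longer than 3 consonants are never legal.
#
# The coda list includes syllabic-l codas (d l, t l) so that perceived forms
# like "m ao d l" (model) count as closed syllables.

[onset]
p l
p r
p y
b l
b r
b y
t r
t w
t y
d r
d w
d y
k l
k r
k w
k y
g l
g r
g w
f l
f r
f y
v y
th r
th w
s p
s t
s k
s m
s n
s l
s w
s f
s y
sh r
m y
n y
hh y
s p l
s p r
s p y
s t r
s t y
s k l
s k r
s k w
s k y

[coda]
p t
p s
p th
t s
k t
k s
k th
b z
b d
d z
d th
d l
t l
g z
g d
ch t
jh d
f t
f s
f th
v d
v z
th s
s p
s t
s k
z d
sh t
m p
m z
m d
m f
n t
n d
n s
n z
n ch
n jh
n th
ng k
ng z
ng d
l p
l t
l k
l b
l d
l ch
l jh
l f
l v
l th
l s
l z
l m
r p
r t
r k
r b
r d
r g
r ch
r jh
r f
r v
r th
r s
r z
r sh
r m
r n
r l
k s t
k s th
m p s
m p t
n t s
n d z
n th s
ng k s
ng k t
l t s
l d z
l k s
r t s
r d z
r k s
r m z
r n z
s t s
s k s
p t s
f t s
f th s
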
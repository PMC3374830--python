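# Default child-directed-speech scenario vocabulary for the shapes-and-colours
# teaching game. Columns (tab-separated):
#   orthographic  canonical_phonemes  role  weight  variants (pipe-separated)
# Roles: salient (content word being taught), other_word (proper but
# non-salient), function. Weights follow the Zipf-like profile of the
# orthographic rank-frequency tables of the original study (top salient word
# ~50 tokens in ~600 words). Function words carry >=2 pronunciation variants
# (vowel reduction / coda loss); content words are canonical, with their
# observed variability supplied by the recognizer-noise channel.
a	ah	function	53	ey|ah
red	r eh d	salient	51
thats	dh ae t s	function	33	dh ae s|dh ah t s|dh ae
green	g r iy n	salient	32
you	y uw	function	26	y ah|y uw
and	ae n d	function	24	ah n|ae n|ah n d|eh n
cross	k r ao s	salient	21
blue	b l uw	salient	21
heart	hh aa t	salient	20
circle	s er k ah l	salient	17
we	w iy	function	15	w iy|w ih
that	dh ae t	function	14	dh ae|dh ah t|dh eh t
the	dh ah	function	12	dh iy|dh eh
is	ih z	function	10	ih z|s
this	dh ih s	other_word	10
look	l uh k	other_word	9
can	k ae n	function	8	k ah n|k n
see	s iy	function	8	s iy|s ih
yes	y eh s	other_word	8
good	g uh d	other_word	6
box	b aa k s	salient	6
star	s t aa r	salient	5
sun	s ah n	salient	5
ring	r ih ng	salient	4
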
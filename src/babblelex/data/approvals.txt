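# Approval terms and their canonical phonemic renderings. Format:
#   orthographic term <TAB> space-separated phonemes
well done	w eh l d ah n
good	g uh d
clever	k l eh v er
yes	y eh s
very good	v eh r iy g uh d
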
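name	group	genome_size	absent_chromosomes
rat	rodent	2647915728	2B,7B,21,22
mouse	rodent	2728222451	2B,7B,20,21,22
gelada	Old World monkey	2889630685	2B,21,22
baboon	Old World monkey	2869821163	2B,7B,21,22
macaque	Old World monkey	2946843737	2B,7B,21,22
gorilla	great ape	3063362754	7B
chimpanzee	great ape	3050398082	7B
bonobo	great ape	3203531224	7B
human	great ape	3099706404	2B,7B
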
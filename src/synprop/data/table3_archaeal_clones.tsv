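# Archaeal 16S rRNA clone counts at t2 (39 days); libraries of up to 12
# clones, loaders use a nominal per-sample total of 12.  Zero cells omitted.
taxon	consortium	timepoint	count
Methanosarcina mazei	N12	t2	10
Methanosarcina thermophila	Wp2a	t2	1
Methanosarcina vacuolata	Wp2a	t2	9
Methanosarcina sp.	Wp2a	t2	1
Methanosaeta concilii	Ap1a	t2	1
Methanosaeta harundinacea	Ap1a	t2	1
Methanobacterium petrolearium	N12	t2	1
Methanoculleus marisnigri	G12	t2	2
Methanoculleus receptaculi	Ap1a	t2	4
Methanoculleus receptaculi	G12	t2	5
Methanoculleus sp.	Ap1a	t2	1
Methanomethylovorans hollandica	Ap1a	t2	1
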
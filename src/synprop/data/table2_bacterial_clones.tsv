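# Dominant bacterial 16S rRNA clone counts per consortium sample (t1/t2/t3 =
# 14/39/56 days).  Only dominant sequence clusters are tabulated; libraries
# held up to 60 clones each, so loaders use a nominal per-sample total of 60
# and column sums are lower bounds on the clones screened.  Zero cells are
# omitted.
taxon	consortium	timepoint	count
Syntrophobacter sulfatireducens	Ap1a	t2	15
Syntrophobacter sulfatireducens	Ap1a	t3	16
Cryptanaerobacter/Pelotomaculum	N12	t2	14
Cryptanaerobacter/Pelotomaculum	N12	t3	26
Cryptanaerobacter/Pelotomaculum	Wp2a	t1	16
Cryptanaerobacter/Pelotomaculum	Wp2a	t2	33
Cryptanaerobacter/Pelotomaculum	Wp2a	t3	27
Candidatus Cloacamonas	Ap1a	t1	2
Candidatus Cloacamonas	Ap1a	t2	3
Candidatus Cloacamonas	Ap1a	t3	2
Candidatus Cloacamonas	Wp2a	t2	1
Candidatus Cloacamonas	Wp2a	t3	9
Tepidanaerobacter acetatoxydans	Ap1a	t1	15
Tepidanaerobacter acetatoxydans	Ap1a	t2	7
Tepidanaerobacter acetatoxydans	Ap1a	t3	2
Tepidanaerobacter acetatoxydans	G12	t1	32
Tepidanaerobacter acetatoxydans	G12	t2	19
Tepidanaerobacter acetatoxydans	G12	t3	5
Tepidanaerobacter acetatoxydans	N12	t1	12
Tepidanaerobacter acetatoxydans	N12	t2	4
Tepidanaerobacter acetatoxydans	N12	t3	2
Tepidanaerobacter acetatoxydans	Wp2a	t1	18
Tepidanaerobacter acetatoxydans	Wp2a	t2	4
Tepidanaerobacter acetatoxydans	Wp2a	t3	3
Desulfovibrio aminophilus	G12	t1	4
Desulfovibrio aminophilus	G12	t2	8
Desulfovibrio aminophilus	G12	t3	24
Desulfovibrio aminophilus	N12	t1	7
Desulfovibrio aminophilus	N12	t2	3
Desulfovibrio aminophilus	N12	t3	1
Caloramator/Moorella	N12	t1	1
Caloramator/Moorella	N12	t2	1
Caloramator/Moorella	N12	t3	2
Syntrophaceticus/Thermacetogenium	N12	t2	13
Syntrophaceticus/Thermacetogenium	N12	t3	2
Aminobacterium colombiense	Ap1a	t1	24
Aminobacterium colombiense	Ap1a	t2	6
Aminobacterium colombiense	Ap1a	t3	20
Aminobacterium colombiense	N12	t1	1
Aminobacterium colombiense	N12	t2	2
Aminobacterium colombiense	N12	t3	1
Aminobacterium colombiense	Wp2a	t1	4
Aminobacterium colombiense	Wp2a	t2	7
Aminobacterium colombiense	Wp2a	t3	2
Sedimentibacter	N12	t1	6
Sedimentibacter	N12	t3	1
Defluviitoga tunisiensis	N12	t1	2
Defluviitoga tunisiensis	N12	t2	1
Defluviitoga tunisiensis	N12	t3	1
Defluviitoga tunisiensis	Wp2a	t1	2
Defluviitoga tunisiensis	Wp2a	t2	2
Defluviitoga tunisiensis	Wp2a	t3	1
Mesotoga infera	Ap1a	t1	1
Mesotoga infera	Ap1a	t2	1
Mesotoga infera	Ap1a	t3	3
Mesotoga infera	G12	t1	1
Mesotoga infera	G12	t2	2
Mesotoga infera	G12	t3	2
Mesotoga infera	Wp2a	t1	1
Mesotoga infera	Wp2a	t2	2
Mesotoga infera	Wp2a	t3	1
Ornatilinea	Wp2a	t1	1
Ornatilinea	Wp2a	t2	1
Ornatilinea	Wp2a	t3	1
Treponema	Ap1a	t1	11
Treponema	Ap1a	t2	14
Treponema	Ap1a	t3	2
Treponema	G12	t1	14
Treponema	G12	t2	15
Treponema	G12	t3	6
Treponema	N12	t1	13
Treponema	N12	t2	6
Treponema	N12	t3	3
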
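# Functional guild of each dominant bacterial cluster ("putative" members
# are folded into their guild).
taxon	guild
Syntrophobacter sulfatireducens	propionate-oxidizing
Cryptanaerobacter/Pelotomaculum	propionate-oxidizing
Candidatus Cloacamonas	propionate-oxidizing
Tepidanaerobacter acetatoxydans	acetate-oxidizing
Desulfovibrio aminophilus	H2-oxidizing
Caloramator/Moorella	H2-oxidizing
Syntrophaceticus/Thermacetogenium	H2-oxidizing
Aminobacterium colombiense	propionate-forming
Sedimentibacter	propionate-forming
Defluviitoga tunisiensis	sugar-metabolizing
Mesotoga infera	sugar-metabolizing
Ornatilinea	sugar-metabolizing
Treponema	sugar-metabolizing
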
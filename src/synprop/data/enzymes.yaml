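# ARDRA restriction enzymes with standard catalogue recognition sites and
# top-strand cut offsets (GCG^C means cut_offset 3).  All five sites are
# reverse-complement palindromes, asserted at load.
enzymes:
  - name: HhaI
    recognition: GCGC
    cut_offset: 3
  - name: HinfI
    recognition: GANTC
    cut_offset: 1
  - name: HaeIII
    recognition: GGCC
    cut_offset: 2
  - name: SmaI
    recognition: CCCGGG
    cut_offset: 3
  - name: XhoI
    recognition: CTCGAG
    cut_offset: 1
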
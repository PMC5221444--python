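# Domain-specific 16S rRNA gene primers, 5'->3', IUPAC degeneracies allowed.
# E5F/E1541r amplify near-full-length bacterial genes; Met86f/Ar1530 the
# archaeal counterparts.
primers:
  - name: E5F
    sequence: AGAGTTTGATCMTGGCT
  - name: E1541r
    sequence: AAGGAGGTGATCCANCCRCA
  - name: Met86f
    sequence: GCTCAGTAACACGTGG
  - name: Ar1530
    sequence: GGAGGTGATCCAGCCG
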
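# Propionate concentrations (mmol/L) of the four consortia over an 8-week
# batch incubation; sampling days 0 (t0), 14 (t1), 39 (t2), 56 (t3).
consortium	day	propionate_mM
Ap1a	0	25
Ap1a	14	21
Ap1a	39	8
Ap1a	56	0
G12	0	26
G12	14	28
G12	39	27
G12	56	24
N12	0	27
N12	14	25
N12	39	19
N12	56	0
Wp2a	0	25
Wp2a	14	16
Wp2a	39	17
Wp2a	56	1
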
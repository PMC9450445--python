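gene	validation_carriers	control_carriers
MIB2	13	0
S100A1	11	1
TTN	12	3
CCK	10	2
NUP205	11	3
LGR4	14	2
NCOR2	13	0
ESRRB	25	4
WWOX	14	1
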
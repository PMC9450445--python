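variable	group	n	mean	sd
lvef	all	137	60.4	6.7
lvef	no_mutation	50	63.8	7.5
lvef	with_mutation	87	58.4	5.2
calc_volume	all	137	1213.4	149.1
calc_volume	no_mutation	50	1129.3	154.0
calc_volume	with_mutation	87	1261.8	123.0
age	all	137	64.6	10.8
age	no_mutation	50	64.4	12.2
age	with_mutation	87	64.7	10.1
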
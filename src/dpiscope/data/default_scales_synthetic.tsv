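# Synthetic stand-in amino-acid scales: five constructed 20-value property
# tables spanning distinct physicochemical axes (hydropathy, net charge,
# side-chain size, backbone flexibility, aromaticity). They are NOT copies of
# any published scale database; supply your own TSV for real AAIndex tables.
id	A	C	D	E	F	G	H	I	K	L	M	N	P	Q	R	S	T	V	W	Y
hydropathy_syn	1.8	2.5	-3.5	-3.5	2.8	-0.4	-3.2	4.5	-3.9	3.8	1.9	-3.5	-1.6	-3.5	-4.5	-0.8	-0.7	4.2	-0.9	-1.3
charge_syn	0	0	-1	-1	0	0	0.5	0	1	0	0	0	0	0	1	0	0	0	0	0
size_syn	71.1	103.1	115.1	129.1	147.2	57.1	137.1	113.2	128.2	113.2	131.2	114.1	97.1	128.1	156.2	87.1	101.1	99.1	186.2	163.2
flexibility_syn	0.55	0.45	0.75	0.65	0.3	1.0	0.5	0.35	0.7	0.4	0.5	0.75	0.3	0.7	0.6	0.8	0.6	0.35	0.25	0.35
aromaticity_syn	0	0	0	0	1	0	0.5	0	0	0	0	0	0	0	0	0	0	0	1	1
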
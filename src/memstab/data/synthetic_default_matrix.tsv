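factor	level	stab_score	destab_score	combined
amino_acid	G	20	19	39
amino_acid	Q	17	20	37
amino_acid	A	19	17	36
amino_acid	T	18	15	33
amino_acid	P	14	18	32
amino_acid	M	15	12	27
amino_acid	E	16	11	27
amino_acid	S	7	16	23
amino_acid	R	11	10	21
amino_acid	F	5	13	18
amino_acid	W	13	3	16
amino_acid	C	10	5	15
amino_acid	K	9	6	15
amino_acid	H	1	14	15
amino_acid	Y	12	1	13
amino_acid	I	6	7	13
amino_acid	N	4	9	13
amino_acid	L	2	8	10
amino_acid	V	8	2	10
amino_acid	D	3	4	7
topology	extracellular_helix	6	6	12
topology	TM_helix	5	4	9
topology	cytosolic_loop	4	5	9
topology	reentrant	3	3	6
topology	extracellular_loop	2	2	4
topology	cytosolic_helix	1	1	2
conservation_bin	90-100	8	8	16
conservation_bin	50-60	10	6	16
conservation_bin	10-20	6	9	15
conservation_bin	20-30	2	10	12
conservation_bin	70-80	9	2	11
conservation_bin	40-50	7	4	11
conservation_bin	30-40	5	5	10
conservation_bin	00-10	1	7	8
conservation_bin	80-90	4	3	7
conservation_bin	60-70	3	1	4
lipid_contact_bin	0.8-1.0	5	5	10
lipid_contact_bin	0.2-0.4	4	3	7
lipid_contact_bin	0.4-0.6	2	4	6
lipid_contact_bin	0.6-0.8	3	1	4
lipid_contact_bin	0.0-0.2	1	2	3
helix_contact_bin	0.8-1.0	5	5	10
helix_contact_bin	0.2-0.4	3	4	7
helix_contact_bin	0.0-0.2	4	1	5
helix_contact_bin	0.4-0.6	1	3	4
helix_contact_bin	0.6-0.8	2	2	4
disorder_bin	0.6-0.8	5	3	8
disorder_bin	0.8-1.0	2	5	7
disorder_bin	0.2-0.4	4	2	6
disorder_bin	0.4-0.6	1	4	5
disorder_bin	0.0-0.2	3	1	4
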
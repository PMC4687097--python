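metabolite	compound	description	enzymes
BPA_I_1	BPA	aromatic hydroxylation (5-hydroxy BPA)	1A1;1A2;1B1;3A4
BPA_I_2	BPA	hydroxyl to carbonyl (quinone-like)	1A2;2D6;2E1
BPA_I_3	BPA	arene epoxidation	2E1
PCB_I_1	PCB3	arene oxide (unsubstituted ring)	1A1;1B1;1A2;2A6;2B6;2C9;2C19;2E1;3A4
PCB_I_2	PCB3	4-hydroxylation	1B1;2B6;2C8;2C9;2C18;2C19;2D6;2E1;3A4;3A5
PCB_I_3	PCB3	arene epoxidation	1A1;1B1;2C8;2C9;2E1;3A4
PCB_I_4	PCB3	3-hydroxylation	2B6;3A4
PCB_I_5	PCB3	3,4-dihydroxylation	3A4
PCB_I_6	PCB3	epoxidation	2E1
PCB_I_7	PCB3	hydroxylation (chlorinated ring)	2E1
PCB_I_8	PCB3	cis-dihydrodiol formation	2C9;2C19
PCB_I_9	PCB3	chlorination shift (3,4-dichlorobiphenyl)	1A2
PCB_I_10	PCB3	2-hydroxylation	2D6
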
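tf	gene	chrom	cher_start	cher_end	max_peak	score	tfbs_position	assay_id	assay_position
RUNX1	MTMR11	1	149914894	149915698	1.82	5.51	149914981	GPH1014896	149915029
RUNX1	MTMR11	1	149914894	149915698	1.82	5.51	149914982	GPH1014896	149915029
RUNX1	MTMR11	1	149914894	149915698	1.82	5.51	149915422	GPH1014896	149915029
RUNX1	MTMR11	1	149914894	149915698	1.82	5.51	149915646	GPH1014896	149915029
ELF1	DUSP10	1	221910850	221912636	1.11	3.48	221911869	GPH1015368	221911302
ELF1	DUSP10	1	221910850	221912636	1.11	3.48	221911869	GPH1015369	221911004
ELF1	ITGAM	16	31265046	31265641	1.77	3.85	31265104	GPH1005092	31265074
ETS2	MARCH1	4	164540016	164540804	1.82	7.09	164540319	GPH1023955	164540062
ETS2	HDAC8	X	71795290	71796102	1.45	3.99	71795629	GPH1027352	71795212
ETS2	MMP14	14	23304660	23305370	1.52	4	23305194	GPH1003823	23304254
STAT5	MAGI1	3	66027042	66027848	2.14	6.17	66027092	GPH1023100	66026742
STAT5	MAGI1	3	66027042	66027848	2.14	6.17	66027435	GPH1023100	66026742
STAT5	MAGI1	3	66027042	66027848	2.14	6.17	66027447	GPH1023100	66026742
STAT5	MAGI1	3	66027042	66027848	2.14	6.17	66027779	GPH1023100	66026742
STAT5	MAGI1	3	66027042	66027848	2.14	6.17	66027791	GPH1023100	66026742
ETS2	THBD	20	23032992	23033730	1.48	4.9	23033025	GPH1022015	23032818
ETS2	THBD	20	23032992	23033730	1.48	4.9	23033065	GPH1022015	23032818
ETS2	THBD	20	23032992	23033730	1.48	4.9	23033114	GPH1022015	23032818
ETS2	THBD	20	23032992	23033730	1.48	4.9	23033328	GPH1022015	23032818
ETS2	SPOCK1	5	136837910	136838620	1.2	3.02	136838118	GPH1024386	136837303
ETS2	SPOCK1	5	136837910	136838620	1.2	3.02	136838136	GPH1024386	136837303
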
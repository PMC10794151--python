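protein_id	gene	mw_kda	secreted	fraction	psm_vehicle	psm_pf	psm_protx
P0DMV8	HSPA1A	70.0	True	30-100	0	8	6
P21741	MDK	15.6	True	10-30	0	7	7
SYN0001	SECA	23.2	True	10-30	3	8	7
SYN0002	SECB	52.4	True	30-100	4	9	13
SYN0003	SECC	34.6	True	30-100	0	3	8
SYN0004	SECD	15.8	True	10-30	2	5	9
P02751	FN1	262.0	True	30-100	0	7	4
SYN0101	PEPS	5.0	True	10-30	0	5	3
P05121	SERPINE1	45.0	True	30-100	2	7	3
P61769	B2M	13.7	True	10-30	4	8	9
P60709	ACTB	41.7	False	30-100	1	8	5
P04406	GAPDH	36.0	False	30-100	0	8	7
P02768	ALB	69.4	True	30-100	30	31	29
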
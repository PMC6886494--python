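# Candidate hub proteins interacting with >10 neurodegeneration-associated
# proteins: total partner counts, seed-partner counts, and the originally
# reported enrichment factor and Bonferroni-adjusted p-value.
symbol	accession	n_partners	k_seed	ef_reported	p_adj_reported
TRAF6	Q9Y4K3	315	17	28.40	1.03E-17
PRKN	O60260	454	18	20.86	2.77E-16
SQSTM1	Q13501	309	13	22.14	8.25E-13
HSPA4	P34932	363	13	17.90	1.58E-10
HSPA8	P11142	708	16	11.29	8.20E-10
YWHAZ	P63104	412	12	14.56	9.38E-9
HSP90AA1	P07900	839	15	8.93	6.65E-08
YWHAQ	P27348	476	11	11.55	4.74E-07
CYLD	Q9NQC7	620	12	9.67	8.15E-07
CTNNB1	P35222	616	11	8.92	6.00E-06
UBC	P0CG48	1050	14	6.66	6.54E-06
TP53	P04637	1062	14	6.59	7.46E-06
CUL7	Q14999	658	11	8.35	1.13E-05
EGFR	P00533	1224	14	5.71	3.73E-05
RNF4	P78317	1251	14	5.59	4.75E-05
MCM2	P49736	940	11	5.85	3.09E-04
BRCA1	P38398	962	11	5.71	3.80E-04
NTRK1	P04629	1948	16	4.10	4.54E-04
CUL3	Q13618	1227	13	5.29	1.75E-04
ESR2	Q92731	2249	13	2.89	4.67E-02
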
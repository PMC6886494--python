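# Detection patterns of common neurodegeneration-associated proteins in
# B-lymphocyte vs dendritic-cell mass-spectrometry datasets.
# Datasets: HPM_B (tissue-atlas B cells), blood_B (blood-derived B cells),
# blood_DC (blood-derived dendritic cells), MoDC (monocyte-derived DCs).
symbol	accession	HPM_B	blood_B	blood_DC	MoDC
APOE	P02649	Detected	detected	0	0
APP	P05067	Detected	0	0	0
ATXN2	Q99700	Detected	Detected	0	0
CHMP2B	Q9UQN3	Detected	Detected	0	Detected
DCTN1	Q14203	Detected	Detected	0	Detected
FIG4	Q92562	Detected	Detected	0	0
FUS	P35637	Detected	Detected	detected	Detected
GBA	P04062	0	Detected	0	Detected
GRN	P28799	Detected	Detected	0	0
HNRNPA1	P09651	Detected	0	0	Detected
HTT	P42858	Detected	Detected	Detected	Detected
LRRK2	Q5S007	Detected	Detected	Detected	0
MATR3	P43243	Detected	Detected	Detected	Detected
OPTN	Q96CV9	Detected	Detected	0	0
PARK7	Q99497	Detected	Detected	Detected	Detected
PFN1	P07737	Detected	Detected	Detected	Detected
PRPH	P41219	Detected	0	0	Detected
PSEN1	P49768	Detected	0	0	0
SETX	Q7Z333	Detected	Detected	0	Detected
SIGMAR1	Q99720	Detected	Detected	0	0
SNCA	P37840	Detected	0	0	0
SOD1	P00441	Detected	Detected	Detected	Detected
SPG11	Q96JI7	Detected	Detected	0	0
SQSTM1	Q13501	Detected	Detected	0	Detected
TARDBP	Q13148	Detected	0	Detected	Detected
TBK1	Q9UHD2	Detected	Detected	0	Detected
TBP	P20226	Detected	Detected	0	0
TRPM7	Q96QT4	0	Detected	0	0
TUBA4A	P68366	Detected	0	0	Detected
UBQLN2	Q9UHD9	Detected	Detected	0	0
UCHL1	P09936	Detected	Detected	0	0
VAPB	O95292	Detected	Detected	Detected	Detected
VCP	P55072	Detected	Detected	Detected	Detected
VPS35	Q96QK1	Detected	Detected	Detected	Detected
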
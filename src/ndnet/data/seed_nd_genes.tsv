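# Curated seed set of common neurodegeneration-associated genes (AD, PD, ALS,
# HD, FTD).  38 members are enumerable from the packaged detection and
# immunopeptidome tables; the curated population size is 48 and is supplied as
# declared_size by the loader.
symbol	accession
APOE	P02649
APP	P05067
ATXN2	Q99700
CHMP2B	Q9UQN3
DCTN1	Q14203
FIG4	Q92562
FUS	P35637
GBA	P04062
GRN	P28799
HNRNPA1	P09651
HTT	P42858
LRRK2	Q5S007
MATR3	P43243
OPTN	Q96CV9
PARK7	Q99497
PFN1	P07737
PRPH	P41219
PSEN1	P49768
SETX	Q7Z333
SIGMAR1	Q99720
SNCA	P37840
SOD1	P00441
SPG11	Q96JI7
SQSTM1	Q13501
TARDBP	Q13148
TBK1	Q9UHD2
TBP	P20226
TRPM7	Q96QT4
TUBA4A	P68366
UBQLN2	Q9UHD9
UCHL1	P09936
VAPB	O95292
VCP	P55072
VPS35	Q96QK1
PRNP	P04156
ATP13A2	Q9NQ11
PSEN2	P49810
MAPT	P10636
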
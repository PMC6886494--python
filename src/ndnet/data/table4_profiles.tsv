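# Neurodegeneration-associated parent proteins providing endogenous MHC class
# II-binding peptides in the human B-cell lineage, with the reported MHC class
# II restriction labels (verbatim, |-separated).
parent_symbol	parent_accession	restrictions
APP	P05067	HLA class II|HLA-DQ|HLA-DR|HLA-DR3|HLA-DQ7.5|HLA-DQ2.5|HLA-DQ2.2|HLA-DRB1*15:01 (HLA-DR15)|HLA-DRB5*01:01 (HLA-DR51)|HLA-DRB1*04:05 (HLA-DR4)|HLA-DQA1*05:01/DQB1*02:01 (HLA-DQ2.5)
SQSTM1	Q13501	HLA class II|HLA-DR|HLA-DQ|HLA-DR1|HLA-DQ7.5|HLA-DQ2.5|HLA-DQ2.2|HLA-DR15/DR51|HLA-DQA1*05:01/DQB1*02:01 (HLA-DQ2.5)
PFN1	P07737	HLA class II|HLA-DR|HLA-DQ|HLA-DR1|HLA-DR3|HLA-DRB1*04:05 (HLA-DR4)|HLA-DR15/DR51
SOD1	P00441	HLA class II|HLA-DR|HLA-DR1|HLA-DQ7.5|HLA-DQ2.5|HLA-DQ2.2
VCP	P55072	HLA class II|HLA-DR|HLA-DR1|HLA-DQ7.5|HLA-DQ2.5|HLA-DQ2.2
GBA	P04062	HLA class II|HLA-DR|HLA-DQ|HLA-DR1|HLA-DR15|HLA-DRB1*04:05 (HLA-DR4)
PSEN1	P49768	HLA class II|HLA-DQ|HLA-DQ2.2|HLA-DR15/DR51|HLA-DRB1*04:05 (HLA-DR4)
UBQLN2	Q9UHD9	HLA class II|HLA-DR1|HLA-DQ7.5|HLA-DQ2.2|HLA-DRB1*04:05 (HLA-DR4)
PRNP	P04156	HLA-DQ|HLA-DR|HLA-DR1|HLA-DQ7.5|HLA-DQ2.2
VPS35	Q96QK1	HLA class II|HLA-DR|HLA-DR15/DR51|HLA-DQA1*05:01/DQB1*02:01 (HLA-DQ2.5)
OPTN	Q96CV9	HLA-DR1|HLA-DQ7.5|HLA-DQ2.5|HLA-DQ2.2
PARK7	Q99497	HLA class II|HLA-DR1|HLA-DRB1*04:01 (HLA-DR4)|HLA-DRB1*04:05 (HLA-DR4)
GRN	P28799	HLA class II|HLA-DQ|HLA-DQ7.5
SPG11	Q96JI7	HLA-DQ7.5|HLA-DQ2.2
UCHL1	P09936	HLA class II|HLA-DR
FUS	P35637	HLA class II
ATP13A2	Q9NQ11	HLA-DR
HNRNPA1	P09651	HLA class II
CHMP2B	Q9UQN3	HLA-DQ7.5
HTT	P42858	HLA-DR
TBK1	Q9UHD2	HLA-DR15/DR51
PSEN2	P49810	HLA-DR15/DR51
MAPT	P10636	HLA-DR15/DR51
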
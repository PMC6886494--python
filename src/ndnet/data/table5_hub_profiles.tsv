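# Hub proteins linking neurodegeneration-associated proteins that provide
# endogenous MHC class II-binding peptides in the human B-cell lineage, with
# the reported MHC class II restriction labels (verbatim, |-separated).
parent_symbol	parent_accession	restrictions
HSPA8	P11142	HLA class II|HLA-DR|HLA-DQ|HLA-DR1|HLA-DQ7.5|HLA-DQ2.5|HLA-DQ2.2|HLA-DR3|HLA-DRB1*15:01 (HLA-DR15)|HLA-DR15/DR51|HLA-DQA1*05:01/DQB1*02:01 (HLA-DQ2.5)|HLA-DRB1*04:01 (HLA-DR4)|HLA-DRB1*04:05 (HLA-DR4)
SQSTM1	Q13501	HLA class II|HLA-DR|HLA-DQ|HLA-DR1|HLA-DQ7.5|HLA-DQ2.5|HLA-DQ2.2|HLA-DR15/DR51|HLA-DQA1*05:01/DQB1*02:01 (HLA-DQ2.5)
HSP90AA1	P07900	HLA class II|HLA-DR|HLA-DQ|HLA-DQ7.5|HLA-DQ2.5|HLA-DQ2.2|HLA-DRB1*04:05 (HLA-DR4)|HLA-DRB1*15:01 (HLA-DR15)|HLA-DQA1*05:01/DQB1*02:01 (HLA-DQ2.5)
YWHAZ	P63104	HLA class II|HLA-DR|HLA-DQ|HLA-DR1|HLA-DRB1*04:05 (HLA-DR4)
YWHAQ	P27348	HLA class II|HLA-DQ|HLA-DRB1*04:05 (HLA-DR4)
HSPA4	P34932	HLA-DR|HLA-DR3
CYLD	Q9NQC7	HLA-DRB1*04:05 (HLA-DR4)
TRAF6	Q9Y4K3	HLA-DR1
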
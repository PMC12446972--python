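gene	division	category
COL1A1	core matrisome	collagens
COL1A2	core matrisome	collagens
COL3A1	core matrisome	collagens
COL6A1	core matrisome	collagens
COL6A2	core matrisome	collagens
COL6A3	core matrisome	collagens
COL14A1	core matrisome	collagens
FN1	core matrisome	ECM glycoproteins
ELN	core matrisome	ECM glycoproteins
FBN1	core matrisome	ECM glycoproteins
POSTN	core matrisome	ECM glycoproteins
LTBP1	core matrisome	ECM glycoproteins
BGN	core matrisome	proteoglycans
DCN	core matrisome	proteoglycans
MMP7	matrisome-associated	ECM regulators
MMP14	matrisome-associated	ECM regulators
TIMP1	matrisome-associated	ECM regulators
HTRA1	matrisome-associated	ECM regulators
ADAMTSL1	matrisome-associated	ECM regulators
TGFB2	matrisome-associated	secreted factors
CCN2	matrisome-associated	secreted factors
S100A4	matrisome-associated	secreted factors
CXCL12	matrisome-associated	secreted factors
C1QA	matrisome-associated	ECM-affiliated
ANXA2	matrisome-associated	ECM-affiliated
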
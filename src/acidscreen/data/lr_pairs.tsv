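ligand	receptor	annotation
MIF	CD74	paracrine
MIF	CXCR4	paracrine
MIF	CD44	paracrine
MDK	SDC2	paracrine
MDK	SDC4	paracrine
MDK	CD44	paracrine
APP	CD74	contact
COL1A1	CD44	ECM
COL1A2	CD44	ECM
COL4A1	CD44	ECM
COL6A1	CD44	ECM
COL6A2	CD44	ECM
COL6A3	CD44	ECM
FN1	CD44	ECM
FN1	SDC4	ECM
LAMC1	CD44	ECM
LAMB3	CD44	ECM
PTN	SDC2	paracrine
SPP1	CD44	ECM
THBS1	CD44	ECM
THBS2	CD44	ECM
TNC	SDC4	ECM
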
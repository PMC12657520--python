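target	inhibitor	working_concentration_uM
NR4A1	SYN-NR4A1-i	10
STAT3	Stattic	10
GATA3	SYN-GATA3-i	10
NFATC1	SYN-NFATC1-i	10
FOXO1	SYN-FOXO1-i	10
TP53	SYN-TP53-i	10
STAT1	SYN-STAT1-i	10
JUN	SYN-JUN-i	10
SMAD3	SYN-SMAD3-i	10
HIF1A	SYN-HIF1A-i	10
SIN3A	SYN-SIN3A-i	10
NCOR1	SYN-NCOR1-i	10
SRC	SYN-SRC-i	10
PDK1	SYN-PDK1-i	10
HDAC2	SYN-HDAC2-i	10
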
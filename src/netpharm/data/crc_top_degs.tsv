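gene	log2fc	p_adj	direction
MMP3	4.1101	1.41e-03	up
REG1A	3.8436	5.89e-03	up
FOXQ1	3.5684	1.79e-03	up
CXCL11	3.4122	2.12e-03	up
MMP7	3.3618	1.56e-03	up
REG1B	3.3276	2.67e-02	up
MMP1	3.2300	2.86e-03	up
TCN1	3.2266	3.83e-03	up
SLC6A14	2.7141	6.57e-03	up
CXCL3	2.6473	5.58e-03	up
CLCA4	-4.4741	4.45e-03	down
MS4A12	-4.4636	4.03e-03	down
AQP8	-4.3366	1.91e-03	down
CA4	-3.6607	2.16e-03	down
GCG	-3.6245	9.42e-03	down
GUCA2A	-3.4325	3.83e-03	down
CLDN8	-3.3370	1.14e-02	down
CHP2	-3.2031	1.58e-03	down
NXPE4	-3.1622	3.12e-03	down
MAMDC2	-3.0890	3.21e-03	down
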
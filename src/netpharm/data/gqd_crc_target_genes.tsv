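gene	full_name	log2fc	p_adj
PTGS2	Prostaglandin G/H synthase 2	1.7769	7.39e-03
OLR1	Oxidized low-density lipoprotein receptor 1	1.9948	4.17e-03
NR3C2	Nuclear receptor subfamily 3 group C member 2	-1.5129	3.92e-03
HSD3B2	Hydroxy-delta-5-steroid dehydrogenase, 3 beta- and steroid delta-isomerase 2	-1.1592	8.47e-03
TNFSF15	TNF superfamily member 15	1.0461	1.24e-02
MMP1	Matrix metallopeptidase 1	3.2300	2.86e-03
AKR1C3	Aldo-keto reductase family 1 member C3	-1.2267	6.79e-03
CA2	Carbonic anhydrase 2	-1.7184	9.85e-03
MMP3	Matrix metallopeptidase 3	4.1101	1.41e-03
PLAU	Plasminogen activator, urokinase	1.2642	4.83e-03
MMP9	Matrix metallopeptidase 9	1.1245	8.08e-03
IL1B	Interleukin 1 beta	2.1239	2.27e-03
DUOX2	Dual oxidase 2	1.9328	2.98e-02
CCNB1	Cyclin B1	1.0204	1.50e-02
ABCG2	ATP binding cassette subfamily G member 2	-2.9521	2.92e-03
CXCL11	C-X-C motif chemokine ligand 11	3.4122	2.12e-03
CXCL10	C-X-C motif chemokine ligand 10	2.1322	6.06e-03
SPP1	Secreted phosphoprotein 1	1.5076	7.22e-03
ADH1C	Alcohol dehydrogenase 1C (class I), gamma polypeptide	-2.9047	7.54e-03
MAOA	Monoamine oxidase A	-1.1045	7.88e-03
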
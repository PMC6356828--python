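gene	array_depletion_fc	site_offset	qpcr_depletion_fc	induction_fc	liver_enriched	chip_occupancy
SLC22A23	-4.25777	-978	N.D.	N.D.	yes	N.D.
APOA2	-7.00843	-838	-6.98	4.74	yes	yes
SFRP5	-5.56874	-789	-10.9	128.02	yes	yes
AKAP1	-5.1654	-714	N.D.	N.D.	no	N.D.
APOA1	-11.2129	-319	-13.42	54.92	yes	N.D.
PHACTR2	-4.99637	-250	-1.46	0.91	no	N.D.
C3orf15	-4.33119	-249	-6.6	23.47	no	N.D.
EPHX2	-4.47046	-238	-2.67	7.57	yes	no
N4BP2L1	-8.12692	-230	-5.86	26.96	yes	yes
CHST13	-4.49952	-184	N.D.	N.D.	yes	N.D.
SLC35D1	-4.73481	-176	-2.67	26.33	yes	yes
VTN	-7.51883	-163	-3.97	23.04	yes	no
APOM	-8.64496	-158	-2.22	1.51	yes	no
APOB	-74.4626	-156	-30.75	31.69	yes	yes
EFEMP1	-5.90295	-147	-4.53	23.08	no	N.D.
GLYCTK	-6.10731	-140	-7.18	8.99	yes	N.D.
ANKS4B	-10.9033	-131	-15.46	351.45	yes	yes
LRP2	-14.7087	-131	-18.87	152.12	no	N.D.
PLA2G12B	-30.8129	-114	-994.4	397.18	yes	yes
LGALS2	-45.8533	-102	-75.65	19.83	no	N.D.
AQP11	-5.36658	-95	N.D.	N.D.	yes	N.D.
AGMAT	-5.7087	-90	N.D.	N.D.	yes	N.D.
HNF4A	-27.3065	-82	-	5.1	yes	yes
GDF15	-6.02312	-74	N.D.	N.D.	no	N.D.
F7	-8.84201	-71	-30.51	48.04	yes	yes
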
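cAMP-mediated signaling	PBH=2.00e-14	ADRA2A	ADRB2	AGTR1	AKAP13	CAMK4	CHRM1	CHRM2	CHRM5	CNR1	CREB1	DRD1	DRD2	DRD3	DRD4	DRD5	GABBR1	GABBR2	GNAS	GRM7	HTR1F	HTR6	NPY1R	OPRM1	PDE4D	RAPGEF3
Calcium Signaling	PBH=2.00e-13	CAMK4	CHRNA1	CHRNA10	CHRNA2	CHRNA3	CHRNA4	CHRNA5	CHRNA6	CHRNA7	CHRNB1	CHRNB2	CHRNB3	CHRNB4	CHRND	CHRNG	CREB1	GRIK1	GRIN2A	GRIN2B	GRIN3A	ITPR2	TRPC7
G-Protein Coupled Receptor Signaling	PBH=3.16e-13	ADRA2A	ADRB2	AGTR1	CAMK4	CHRM1	CHRM2	CHRM5	CNR1	CREB1	DRD1	DRD2	DRD3	DRD4	DRD5	GABBR1	GABBR2	GNAS	GRM7	HTR1F	HTR2A	HTR6	NPY1R	OPRM1	PDE4D	RAPGEF3
Dopamine Receptor Signaling	PBH=2.51e-12	COMT	DRD1	DRD2	DRD3	DRD4	DRD5	GNAS	MAOA	MAOB	NCS1	PPP1R1B	PPP2R2B	SLC18A2	SLC6A3	TH
Xenobiotic Metabolism Signaling	PBH=1.41e-10	ABCB1	AHR	CAMK4	CYP1A1	CYP2B6	FMO1	GSTM1	GSTM3	GSTP1	GSTT1	IL6	MAOA	MAOB	MAP3K4	MGMT	NOS2	NQO1	PPP2R2B	SOD3	SULT1A1	TNF	UGT1A9	UGT2B10
Dopamine-DARPP32 Feedback in cAMP Signaling	PBH=1.45e-08	CAMK4	CREB1	DRD1	DRD2	DRD3	GRIN3A	DRD4	DRD5	GNAS	GRIN2A	GRIN2B	ITPR2	KCNJ6	PPP1R1B	PPP2R2B	PRKG1
Aryl Hydrocarbon Receptor Signaling	PBH=1.45e-08	AHR	CCND1	CHEK2	CYP1A1	ESR1	GSTM1	GSTM3	GSTP1	GSTT1	IL6	MDM2	NQO1	TGFB1	TNF	TP53
LPS/IL-1 Mediated Inhibition of RXR Function	PBH=1.78e-08	ABCB1	ABCC4	APOE	CD14	CETP	CYP2A6	CYP2B6	FMO1	GSTM1	GSTM3	GSTP1	GSTT1	MAOA	MAOB	MGMT	SOD3	SULT1A1	TNF
Gai Signaling	PBH=1.78e-08	ADRA2A	AGTR1	CHRM2	CNR1	DRD2	DRD3	DRD4	GABBR1	GABBR2	GNAS	GRM7	HTR1F	NPY1R	OPRM1
Superpathway of Melatonin Degradation	PBH=1.32e-07	CYP1A1	CYP2A6	CYP2B6	CYP2D6	MAOA	MAOB	MPO	SULT1A1	UGT1A9	UGT2B10
Serotonin Receptor Signaling	PBH=1.95e-07	HTR2A	HTR6	MAOA	MAOB	SLC18A2	SLC6A4	TPH1	TPH2
eNOS Signaling	PBH=3.39e-07	CAMK4	CHRNA10	CHRNA3	CHRNA4	CHRNA5	CHRNB1	CHRNB4	ESR1	GNAS	HSPA4	ITPR2	NOS3	PRKG1
Glucocorticoid Receptor Signaling	PBH=1.05e-06	ADRB2	CCNH	CREB1	ERCC2	ESR1	HSPA4	ICAM1	IFNG	IL13	IL6	IL8	NOS2	NPPA	NR3C1	PTGS2	TGFB1	TNF
Glutamate Receptor Signaling	PBH=1.29e-06	CAMK4	DLG4	GRIK1	GRIK2	GRIN2A	GRIN2B	GRIN3A	GRM7	SLC1A2
Neuropathic Pain Signaling In Dorsal Horn Neurons	PBH=1.29e-05	BDNF	CAMK4	CREB1	GRIN2A	GRIN2B	GRIN3A	GRM7	ITPR2	KCNQ3	NTRK2
AMPK Signaling	PBH=2.40e-05	ADRA2A	ADRB2	CHRNA10	CHRNA3	CHRNA4	CHRNA5	CHRNB1	CHRNB4	GNAS	NOS3	PPP2R2B
Hepatic Cholestasis	PBH=3.09e-05	ABCB1	CD14	CETP	ESR1	GNAS	IFNG	IL6	IL8	MAP3K4	SLCO3A1	TNF
Gas Signaling	PBH=3.09e-05	ADRB2	CHRM1	CHRM5	CNR1	CREB1	DRD1	DRD5	GNAS	HTR6	RAPGEF3
GABA Receptor Signaling	PBH=3.47e-05	DNM1	GABARAP	GABBR1	GABBR2	GABRA2	GABRA4	GABRE
PXR/RXR Activation	PBH=3.47e-05	ABCB1	CYP2A6	CYP2B6	GSTM1	IL6	NR3C1	TNF	UGT1A9
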
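molecular_name	genetic_name	annotation	assessment	comment	dna_binding_domain
C07G2.2	atf-7	Alternative promoters	Well-supported		bZIP
ZC376.7	atfs-1	Intron +/-	Well-supported		bZIP
C27D6.4	crh-2	Alternative promoters	Well-supported		bZIP
R13H8.1	daf-16	Alternative promoters	Well-supported		WH - Fork, AT Hook
F33H1.1	daf-19	Complex; alternative promoters & exon +/-	Possibly valid	EST evidence for alternative promoters, single EST for alternative internal exon	WH - RFX
F13G11.1	dmd-6	Alternative promoters	Possibly valid	nested transcripts only	ZF - DM
T22B7.1	egl-13	Alternative promoters	Well-supported		HMG box
F28B12.2	egl-44	Complex; alternative promoters & splice site variation	Well-supported		TEA/ATTS
F26D12.1	fkh-7	Alternative promoters	Possibly valid	nested transcripts only	ZF - C2H2 - 1 finger, WH - Fork
K03C7.2	fkh-9	Alternative promoters	Possibly valid	nested transcripts only	WH - Fork
W02C12.3	hlh-30	Complex; alternative promoters, intron +/- & exon +/-	Well-supported		bHLH
T24H10.7	jun-1	Alternative promoters	Well-supported		bZIP
F54H5.4	klf-3	Alternative promoters	Possibly valid	RT-PCR primer derived alternative start	ZF - C2H2 - 3 fingers
F16B4.12	nhr-117	Exon +/-	Possibly valid	two ESTs for alternative internal exon	ZF - NHR
C01H6.5	nhr-23	Alternative promoters	Well-supported		ZF - NHR
C45E5.6	nhr-46	Alternative promoters	Well-supported		ZF - NHR
T09A12.4	nhr-66	Alternative promoters	Well-supported		ZF - NHR
F26H11.2	nurf-1	Complex; alternative promoters & transcript ends	Well-supported		AT Hook
T28H11.4	pes-1	Alternative promoters	Possibly valid	nested transcripts only	WH - Fork
C37A2.5	pqn-21	Intron +/-	Possibly valid	single EST for extra intron	ZF - C2H2 - 1 finger
C47C12.3	ref-2	Alternative promoters	Possibly valid	nested transcripts only	ZF - C2H2 - 3 fingers
K08A8.2	sox-2	Alternative promoters	Well-supported	nested transcripts only	HMG box
C07A12.5	spr-3	Intron +/-	Possibly valid	single EST for extra intron	ZF - C2H2 - 7 fingers
ZK867.1	syd-9	Complex; alternative promoters, exon +/- & splice site variation	Possibly valid	nested transcripts, single EST for extra exon & splice site variant	ZF - C2H2 - 4 fingers
T28F12.2	unc-62	Complex; alternative promoters & exons +/-	Well-supported		HD - TALE
C30A5.7	unc-86	Exon +/-	Possibly valid	single EST for alternative internal exon	HD - POU
F14F3.1	vab-3	Alternative promoters	Well-supported		HD - PRD
F55H12.6	ztf-26	Alternative promoters	Well-supported		ZF - C2H2 - 3 fingers
F13H6.1		Alternative promoters	Possibly valid	single EST for alternative unique exon	ZF - C2H2 - 3 fingers
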
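SASP	example senescence-associated secretory phenotype set (illustrative, not a curated database export)	IL6	IL1A	IL1B	CXCL8	CXCL1	CXCL2	CCL2	CCL5	CCL20	MMP1	MMP3	MMP10	SERPINE1	IGFBP3	IGFBP7	TNF	CSF2	ICAM1
NFKB_TARGETS	example NF-kB activation target set (illustrative, not a curated database export)	NFKB1	NFKB2	RELA	RELB	NFKBIA	TNFAIP3	BIRC3	TRAF1	SOD2	PTGS2	VCAM1	IRF1	CXCL10	BCL3
PROTEOSTASIS_LOSS	example proteostasis/chaperone decline set (illustrative, not a curated database export)	HSPA1A	HSPA1B	HSPA8	HSP90AA1	HSP90AB1	DNAJB1	DNAJA1	HSPB1	BAG3	SQSTM1	UBB	UBC	PSMA1	PSMB5
CELL_CYCLE_ARREST	example senescence growth-arrest set (illustrative, not a curated database export)	CDKN1A	CDKN2A	CDKN2B	CDKN1C	TP53	RB1	E2F7	CCND1	GADD45A	MDM2
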
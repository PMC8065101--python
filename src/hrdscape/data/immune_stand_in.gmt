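IMMUNE_STAND_IN	synthetic stand-in immune signature (canonical immune-cell markers)	CD2	CD3D	CD3E	CD3G	CD8A	CD8B	CD247	GZMA	GZMB	GZMH	GZMK	PRF1	NKG7	KLRD1	KLRK1	CCL5	CXCL9	CXCL10	CXCL11	IFNG	IL2RB	IL2RG	LCK	ZAP70	CD27	CD28	ICOS	TIGIT	PDCD1	CTLA4
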
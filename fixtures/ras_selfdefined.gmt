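RAS_CLUSTER	self-defined	ACTA1	AKT1	AKT2	AKT3	ARFIP2	BCL2	BCL2L1	BRAF	CASP1	CASP10	CASP8	CASP9	CDC42	CDK5R1	CDK5RAP2	CFL1	FRAP1	FRAP2	HRAS	LIMK1	MAP2K1	MAP2K2	MAP4K2	MAPK3	MAPK8	NFKB1	NFKBIA	PIK3CA	PIK3CB	PIK3CD	PIK3CG	PIK3R1	PIK3R3	PIK3R5	PTPN6	RAC1	RALBP1	RHOA	SOS2	VAV1	VAV2	VAV3	WASF1
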
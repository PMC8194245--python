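source	source_class	target	target_class	resource
LINC00922	lncRNA	hsa-miR-361-3p	miRNA	reported
LINC00922	lncRNA	hsa-miR-29b-2-5p	miRNA	reported
hsa-miR-361-3p	miRNA	CLDN1	mRNA	reported
hsa-miR-361-3p	miRNA	PODXL	mRNA	reported
hsa-miR-29b-2-5p	miRNA	SNX30	mRNA	reported
LINC00922	lncRNA	CLDN1	mRNA	reported
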
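lncRNA	miRNA	log2fc	p_value
LINC00922	hsa-miR-874-3p	-1.42	3.09E-02
LINC00922	hsa-miR-628-5p	-1.02	3.71E-02
LINC00922	hsa-miR-497-5p	-2.34	1.81E-02
LINC00922	hsa-miR-495-3p	-3.92	1.77E-02
LINC00922	hsa-miR-361-3p	-2.31	1.15E-02
LINC00922	hsa-miR-29b-2-5p	-1.59	3.94E-02
LINC00922	hsa-miR-299-5p	-4.00	2.81E-02
LINC00922	hsa-miR-214-5p	-3.49	3.15E-02
LINC00922	hsa-miR-204-5p	-4.50	4.39E-03
LINC00922	hsa-miR-195-5p	-2.34	1.09E-02
LINC00922	hsa-miR-128-3p	-1.31	3.97E-02
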
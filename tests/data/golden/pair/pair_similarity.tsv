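gene_a	gene_b	region	rho	n	resampled	mode	policy	reason
geneA	geneB	promoter	-0.010799	1000	False	coverage	resample_min	
geneA	geneB	coding	0.542761	1287	False	coverage	resample_min	
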
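gene_id	chrom	strand	start	end	species
geneA	chrS	+	1501	2787	simulated
geneB	chrS	+	8788	10074	simulated
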
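term_id	process
GO:0016043	cell organization and biogenesis
GO:0044085	cell organization and biogenesis
GO:0007010	cell organization and biogenesis
GO:0071554	cell wall formation
GO:0009664	cell wall formation
GO:0009832	cell wall formation
GO:0032502	developmental process
GO:0009653	developmental process
GO:0008152	metabolic process
GO:0019748	metabolic process
GO:0009628	response to abiotic and biotic stimulus
GO:0009607	response to abiotic and biotic stimulus
GO:0006950	response to abiotic and biotic stimulus
GO:0009725	response to hormones
GO:0009719	response to hormones
GO:0007165	signal transduction pathway
GO:0006355	transcriptional regulation
GO:0006351	transcriptional regulation
GO:0006810	transport
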
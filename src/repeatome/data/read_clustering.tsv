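species	total_reads	clustered_reads	genome_proportion_pct	genome_size_gb
Helianthus annuus	438456	343922	78.44	3.6
Lactuca sativa	438358	280372	63.96	2.5
Cynara cardunculus	437906	264665	60.44	1.07
Artemisia annua	438250	273986	62.52	1.74
Chrysanthemum seticuspe	437612	302014	69.01	3.06
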
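# Synthetic stand-in ESE/ESS motif sets. The enhancer set mimics the
# purine-rich hexamers bound by serine/arginine-rich splicing factors; the
# silencer set mimics hnRNP-bound silencer hexamers. Swap in curated sets
# (same layout) for real analyses.
category	set	motif
ESE	SR_purine_rich	GAAGAA
ESE	SR_purine_rich	AAGAAG
ESE	SR_purine_rich	GGAAGA
ESE	SR_purine_rich	TGGAAG
ESE	SR_purine_rich	GAAGGA
ESE	SR_purine_rich	CAGAAG
ESS	hnRNP_like	TAGGGT
ESS	hnRNP_like	TTAGGG
ESS	hnRNP_like	GGGTGG
ESS	hnRNP_like	TAGACT
ESS	hnRNP_like	TTCTCC
ESS	hnRNP_like	GTTAGT
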
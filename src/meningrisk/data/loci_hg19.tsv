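name	chrom	start	end
CDKN2A/B	chr9	21967751	22009312
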
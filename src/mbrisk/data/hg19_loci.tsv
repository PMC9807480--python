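name	chrom	start	end
MYC	chr8	128748314	128753680
MYCN	chr2	16080682	16087129
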
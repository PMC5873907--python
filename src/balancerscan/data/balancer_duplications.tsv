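balancer	chrom	start	end	printed_size	predicted_bands	max_extent_end
SM5	2R	6012459	6916809	904350	42A7-42E1	6917405
SM5	2R	21972072	22689962	712929	58A4-59A2	NA
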
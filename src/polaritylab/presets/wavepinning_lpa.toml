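# LPA diagram of the wave-pinning kinetics vs c_total.
kind = "lpa"
model = "wavepinning"
name = "wavepinning_lpa"

[analysis]
p_range = [2.0, 2.4]
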
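# Threshold + polarization-time table for all four mechanisms.
kind = "compare"
model = "subpb"
name = "model_comparison"

[analysis]
models = ["subpb", "wavepinning", "legi", "turing"]
t_end = 1000.0
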
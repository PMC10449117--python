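# Gradient-reversal protocol at 2x the activation threshold.
kind = "reversal"
model = "subpb"
name = "reversal"

[analysis]
models = ["subpb", "wavepinning", "legi", "turing"]
t_end = 1000.0
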
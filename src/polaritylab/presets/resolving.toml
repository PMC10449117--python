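# Simultaneous opposed gradients with amplitude ratio 2 (resolving).
kind = "resolving"
model = "subpb"
name = "resolving"

[analysis]
models = ["subpb", "wavepinning", "legi", "turing"]
t_end = 1000.0
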
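# Consecutive transient gradients from the same direction: integration index.
kind = "integration"
model = "subpb"
name = "signal_integration"

[analysis]
models = ["subpb", "wavepinning", "legi", "turing"]
n_pulses = 3
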
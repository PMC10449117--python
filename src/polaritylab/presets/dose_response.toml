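# Dose-response scan: mean plateau polarization ratio vs stimulus difference.
kind = "dose_response"
model = "subpb"
name = "dose_response"

[analysis]
models = ["subpb", "wavepinning", "legi", "turing"]
t_end = 1000.0
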
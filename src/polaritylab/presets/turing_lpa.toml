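# LPA diagram of the Turing-like model: transcritical point at c = 1/a2.
kind = "lpa"
model = "turing"
name = "turing_lpa"

[analysis]
p_range = [1.0, 2.6]
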
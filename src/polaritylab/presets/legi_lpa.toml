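# LPA diagram of the LEGI model: a single branch, no special points.
kind = "lpa"
model = "legi"
name = "legi_lpa"

[analysis]
p_range = [0.5, 4.0]
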
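# Two-bin bifurcation diagram vs c_total: subcritical pitchfork stabilised
# by saddle-nodes; defines the organisation regions I-IV.
kind = "continuation"
model = "wavepinning"
name = "two_bin_bifurcation"

[analysis]
c_range = [2.0, 2.4]
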
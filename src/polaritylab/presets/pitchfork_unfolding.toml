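# Unfolding of the pitchfork under a left-bin step signal (sR = 0).
kind = "unfolding"
model = "subpb"
name = "pitchfork_unfolding"

[analysis]
amplitudes = [0.0, 0.005, 0.01, 0.02]
c_range = [2.05, 2.35]
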
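# Quasi-potential landscape of the SubPB preset at s = 0: a single well plus
# the shallow-slope ghost shoulder.
kind = "landscape"
model = "subpb"
name = "region_II_landscape"

[analysis]
D = 0.02
h = 0.02
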
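# Quasi-potential landscape of the region-III (wave-pinning) preset at s = 0:
# three wells (HSS + two polar states).
kind = "landscape"
model = "wavepinning"
name = "region_III_landscape"

[analysis]
D = 0.02
h = 0.02
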
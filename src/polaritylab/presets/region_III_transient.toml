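# Transient Gaussian gradient on the region-I preset (c_total = 2.1 uM):
# marginal local response, full return to the non-polar state.
kind = "simulate"
model = "region_III"
name = "region_III_transient"

[protocol]
kind = "single_transient"
s0 = 0.02
t_on = 100.0
t_off = 300.0

[integrator]
t_end = 1000.0
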
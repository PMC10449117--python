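# Spurious activation under random perturbations of the homogeneous state.
kind = "spurious"
model = "subpb"
name = "spurious_activation"

[analysis]
models = ["subpb", "wavepinning", "turing"]
xi_per = 0.01
n_reps = 10
seed = 0
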
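# polaritylab

Simulation and dynamical-systems analysis of membrane cell-polarity
mechanisms under spatial-temporal chemoattractant signals.

Migrating cells polarize: they establish a front/back asymmetry of active
signalling molecules (e.g. Rho-GTPases) on the plasma membrane in response
to external gradients, keep a transient memory of past signals, and remain
responsive to new ones. `polaritylab` implements the four standard model
classes of this behaviour as reaction–diffusion systems on a 1-D periodic
membrane and the analysis toolkit needed to tell their dynamical regimes
apart:

* **Wave-pinning / SubPB** — the mass-conserved GTPase cycle
  `∂u/∂t = f(u, v) + D_u ∂²u/∂θ² + s(θ,t) v`, `∂v/∂t = −f(u, v) + D_v ∂²v/∂θ² − s(θ,t) v`
  with `f(u, v) = (k₀ + γ u²/(K² + u²)) v − δ u`. Depending on the total
  concentration `c_total`, the two-compartment (left/right) reduction has a
  subcritical pitchfork (PB) whose unstable branches are folded back by
  saddle-nodes (SN_PB), producing four regimes: no polarity (I),
  *criticality* just below SN_PB where only the homogeneous state exists but
  the "ghost" of the polar state traps transients (II, the SubPB mechanism),
  coexistence of non-polar and polar states (III, classic wave-pinning), and
  polar-only (IV).
* **Turing-like** — mass-conserved activator-depletion kinetics
  `f(u, v) = a₁ (v − (u+v)/(a₂(u+v) + 1)²)`, organised past its
  symmetry-breaking instability.
* **LEGI** — local excitation / global inhibition, an incoherent
  feed-forward loop with a single steady state.

The toolkit provides: method-of-lines RK45 and Euler–Maruyama integrators
(kymographs), the two-bin ODE projections, native pseudo-arclength
continuation with PB/SN_PB/TC detection and the analytic odd-mode pitchfork
condition `|F_λ| = 0`, local perturbation analysis (LPA) reductions,
stationary Fokker–Planck quasi-potential landscapes `Q = −ln P_ss` with
Gaussian-curvature–based classification of wells vs ghost shoulders and
trajectory dwell times, and a standardized polarization-metric suite
(stimulus-difference thresholds, polarization / re-polarization / resolving
times, signal-integration index, spurious-activation rates).

## A worked example

```python
import numpy as np
from polaritylab import models, rd_sim, signals, metrics

domain   = rd_sim.DomainSpec()                     # N = 20 bins, perimeter 9.4 um
model    = models.preset("subpb")                  # criticality: c_total = 2.21 uM
protocol = signals.single_transient(s0=0.02, t_on=100, t_off=300)

kym = rd_sim.simulate(model, domain, protocol, t_span=(0, 1000))
for t in (290, 350, 999):
    print(f"t = {t:4d} s  u(pi)/u(0) = {metrics.polarization_ratio(kym, t=t):.2f}")
```

prints

```
t =  290 s  u(pi)/u(0) = 5.27
t =  350 s  u(pi)/u(0) = 4.11
t =  999 s  u(pi)/u(0) = 1.00
```

— the cell polarizes ~5-fold toward the gradient while it is on (t = 290 s),
is still ~4-fold polarized 50 s after the signal was removed (the
ghost-mediated memory), and has fully reset to the non-polar state by the
end of the run. Running the same protocol with the `"wavepinning"` preset
(`c_total = 2.26`) leaves the final ratio at 5.2: the bistable regime never
resets. The scripts in `examples/` walk through each capability
(region kymographs, bifurcation diagrams, landscapes and ghost dwell,
model-comparison metrics, signal integration) and print annotated numbers.

A thin CLI wraps the same machinery:

```
polaritylab simulate --model subpb --out run1
polaritylab continue --model wavepinning
polaritylab landscape --model wavepinning
polaritylab reproduce region_II_transient
polaritylab list-presets
```

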
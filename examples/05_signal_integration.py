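"""Integration of consecutive transient gradients from the same direction.

Three 100 s gradient pulses separated by 100 s gaps probe whether a model
accumulates polarity across interrupted stimulation. The signal
integration index is (time the normalised front response exceeds 1/2 minus
total stimulation time) / total time: ~0 for a memoryless responder,
positive and pulse-count-dependent for the ghost-mediated SubPB memory,
and saturated/constant for mechanisms that never reset.
"""

import numpy as np

from polaritylab import metrics, models, rd_sim, signals

domain = rd_sim.DomainSpec()

for n_pulses in (1, 3):
    print(f"--- {n_pulses} pulse(s) of 100 s, gaps 100 s ---")
    prot = signals.consecutive(s0=0.03, n_pulses=n_pulses, t_first=100.0,
                               duration=100.0, gap=100.0)
    t_max = 100.0 + n_pulses * 200.0 + 400.0
    for name in ("legi", "subpb", "wavepinning"):
        kym = rd_sim.simulate(models.preset(name), domain, prot, t_span=(0.0, t_max))
        u = kym.trace_at(np.pi)
        u_norm = (u - u.min()) / (u.max() - u.min())
        on = kym.signal_history.max(axis=1) > 0
        idx = metrics.signal_integration_index(u_norm, on, kym.times)
        print(f"  {name:12s} integration index = {idx:+.3f}")

print("\nSubPB is the only mechanism whose index grows with the pulse count:")
print("each pulse adds a finite ghost-mediated memory span. Wave-pinning's")
print("index is set by the trailing window alone (the polar state never")
print("resets). LEGI's front *level* freezes because its response component")
print("has no turnover at zero signal - its polarity contrast does reset")
print("(see example 04), so its index is likewise pulse-count-insensitive.")
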
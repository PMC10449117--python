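# Methods

## Models

All models live on a 1-D periodic membrane coordinate θ ∈ [0, 2π) with
concentrations in µM, time in s and length in µm.

**Wave-pinning family (mass-conserved GTPase cycle).** Active membrane
form u, inactive cytosolic form v:

    ∂u/∂t = f(u,v) + D_u ∂²u/∂θ² + s(θ,t)·v
    ∂v/∂t = −f(u,v) + D_v ∂²v/∂θ² − s(θ,t)·v
    f(u,v) = (k₀ + γ u²/(K² + u²)) v − δ u

with k₀ = 0.067 s⁻¹ (basal GEF activation), γ = 1 s⁻¹ (maximal feedback
conversion), K = 1 µM (feedback saturation), δ = 1 s⁻¹ (GAP inactivation),
D_u = 0.1, D_v = 10 µm²/s. The Hill exponent is 2 in every preset (exposed
for exploration). The signal converts v to u, so the mean total
concentration c_total is conserved exactly even during stimulation.
c_total selects the regime: 2.1 (region I), 2.21 (region II / SubPB),
2.26 (region III / wave-pinning), 2.32 (region IV) µM.

**Turing-like (activator-depletion).** f(u,v) = a₁(v − (u+v)/(a₂(u+v)+1)²),
a₁ = 2.5 s⁻¹, a₂ = 0.7 µM⁻¹, mass conserved, signal coupling as above. In
the local-perturbation reduction the homogeneous state destabilises at
c_total = 1/a₂ ≈ 1.43 µM; on a finite discretised membrane the spatial
mode needs more mass. The preset uses c_total = 2.5 µM, which puts the
k = 1 mode clearly past onset on the default domain (e-folding ≈ 80 s), the
canonical "organised beyond the instability" regime of this model class.

**LEGI.** Membrane activator w, fast cytosolic inhibitor v, membrane
response u (incoherent feed-forward loop):

    ∂w/∂t = −k₋w w + k_w s + D_w ∂²w/∂θ²
    ∂v/∂t = −k₋v v + k_v s + D_v ∂²v/∂θ²
    ∂u/∂t = k_u w (u_total − u) − k₋u v u + D_u ∂²u/∂θ²

k_u = k₋u = 2 s⁻¹, k_v = k₋v = 1 s⁻¹, k_w = k₋w = 1 µM⁻¹s⁻¹,
D_u = D_w = 0.5, D_v = 10 µm²/s. u_total is a free scale; the default 1 µM
makes u a fractional response in [0, 1].

## Signals

Gradients are truncated Gaussians over the N membrane bins,
s(n) = s₀ exp(−½ (n/w)²) with w = (N−1)/(2α) and n the circular bin offset
from the bin nearest the requested centre; the profile is exactly
symmetric on the ring (no seam discontinuity). Defaults s₀ = 0.02, α = 2.
Steepness is summarised by the stimulus difference
sd = (s_{θ=π} − s_{θ=0})·100 (%); dose-response scans vary s₀ at fixed α,
width scans vary α. With α = 2 and N = 20 the FWHM is ≈ 11.2 bins (56% of
the perimeter; half-width ≈ 28%). Protocols (transient, sustained,
reversal, simultaneous opposed, consecutive pulses, uniform offset) are
piecewise-constant in time; two-bin experiments use step (s_L, s_R) pairs
with s_R = 0 by convention.

## Discretisation and integration

Method of lines: N = 20 bins, centred second differences with periodic
wrap and physical spacing δθ = L/N, L = 2πR. Deterministic runs use
adaptive RK45 (`scipy.integrate.solve_ivp`, rtol 1e−6, atol 1e−9),
restarted at every signal switch so discontinuities never straddle a step;
output is sampled on a 1 s reporting grid. Stochastic runs use
Euler–Maruyama with fixed dt = 0.01 s and additive noise σ dW per bin and
component; negative excursions are clipped at 0 (violating conservation by
at most O(σ√dt) per step). σ = 0 reproduces the deterministic solution to
the scheme's O(dt) accuracy; fixed seeds give bit-identical trajectories.

**Domain scale.** The kinetic parameters do not fix the cell radius R, yet
every spatially resolved quantity depends on it through D/δθ². The default
R = 1.5 µm (perimeter 9.4 µm, near the canonical ~10 µm wave-pinning
domain) is calibrated so that the four qualitative regimes are all
realised at the canonical c_total presets *on the discretised domain*: the
polar pattern must dissolve after signal removal at c_total = 2.21 but
persist at 2.26, and the homogeneous state must be spatially unstable at
2.32. These three requirements bracket R tightly (≈ 1.50–1.53); outside
that window at least one regime is misrepresented (e.g. at R = 1.59 the
region II preset behaves like region III). R is configurable, and all
absolute times and thresholds reported by the package are understood as
"at the default domain scale".

## Two-bin projection and bifurcation analysis

The two-compartment reduction exchanges (u_L, v_L) ↔ (u_R, v_R) at rates
D̃_u = 0.01 s⁻¹ and D̃_v = 10 s⁻¹. Conservation
(u_L + v_L + u_R + v_R = 2 c_total) eliminates v_R; steady states of the
reduced 3-D system are continued in c_total with a native pseudo-arclength
scheme (secant/tangent predictor, bordered Newton corrector, adaptive
arclength 1e−5…1e−2, step halving on corrector failure). Disconnected
branches are caught by re-seeding from multi-start `fsolve` scans at
several parameter sections. Stability comes from the eigenvalues of the
reduced Jacobian (finite differences).

Special points: parameter-direction reversals are folds (SN on a symmetric
branch, SN_PB on an asymmetric one; located by a quadratic vertex through
the three neighbouring samples, and excluded when they coincide with a
pitchfork junction); eigenvalue zero-crossings away from folds are refined
by a Newton-in-parameter bisection and classified PB when the branch is
symmetric and the crossing eigenvector is odd (δu_L ≈ −δu_R), TC
otherwise. The analytic cross-check is the odd-mode condition: linearising
with δu_R = −δu_L, δv_R = −δv_L closes a 2×2 system F_λ whose determinant
vanishes at the pitchfork; with both exchange rates zero |F_λ| reduces to
4·det of the single-bin Jacobian. On the default parameters the PB sits at
c_total ≈ 2.3087 (condition and continuation agree to <1e−3) and the
SN_PB at ≈ 2.2150. Region labels: I below, II within a 2% criticality
window below SN_PB, III between SN_PB and PB, IV above. The I/II split is
not a bifurcation; the window width is a reporting convention.

LPA reductions follow the slow/fast limit (D_u → 0, D_v → ∞), requiring
D_v ≥ 10 D_u: conserved models reduce to (u_local, u_global) with the
global equation exactly the well-mixed model; LEGI reduces to five
equations. LPA branch points are reported as TC (stability exchange along
the local direction). Note the zero-diffusion limit widens the bistable
window: the local equation is already bistable near c_total ≈ 2.0, below
the two-bin SN_PB.

## Quasi-potential landscapes

The (u_L, u_R) closure uses the fast, conservation-constrained cytosol:
v̄ = c_total − (u_L + u_R)/2, giving a 2-D drift (G₁, G₃). The stationary
Fokker–Planck equation with isotropic intensity D = 0.02 is discretised by
finite volumes with Scharfetter–Gummel (exponentially fitted) fluxes and
reflecting boundaries on [0, 2 c_total]² at spacing h = 0.02 — the scheme
conserves probability exactly and reproduces Gibbs densities of gradient
drifts to machine precision — and P_ss is obtained directly as the null
vector of the sparse generator (LU solve; residual checked < 1e−7 relative,
outer-boundary mass < 1e−8; the walls at u = 0 are physical). A pseudo-time
evolution (implicit Euler) is kept for time-dependent checks.

Q = −ln max(P_ss, 1e−12); the floor caps Q at ≈ 27.6 outside the support.
Gaussian curvature K = (Q_xx Q_yy − Q_xy²)/(1 + Q_x² + Q_y²)² uses centred
differences (one-sided at edges, O(h²)). Candidate regions are connected
components of K > K_mean + 0.1 K_std with statistics over the support only
(the floor-saturation ring otherwise dominates K_std by two orders of
magnitude). A component is a **well** iff the slopes inside are
distributed around zero in both directions — operationally, it contains a
strict interior local minimum of Q and per-direction |mean|/std of the
slope samples ≤ 1.5; one-sided-slope components (the ghost shoulders) are
flagged non-well. Q_bound of a well is the mean Q on its boundary layer.
Trajectory samples are asymptotic when inside a well with Q ≤ Q_bound;
the ghost dwell is the longest contiguous transient span slower than 10%
of the epoch's peak speed (the peak, not the median, anchors the scale:
epochs ending at rest have near-zero median speed). On the default
presets: region III → 3 wells; region II → 1 well plus a non-well shoulder
at the ghost position, post-signal ghost dwell ≈ 80 s; region IV → 2 wells
plus a non-well remnant at the unstable homogeneous state.

## Polarization metrics

* Polarization ratio u(θ=π)/u(θ=0), by default averaged over the last 100
  reported samples ("plateau"); a plateau is accepted when the variance of
  the normalised trace over that window is < (1e−2)².
* Polarization time: first entry of the min-max-normalised front trace
  into ±1e−2 around the plateau mean.
* Activation threshold sd_thresh: linear interpolation of the mean plateau
  ratio at 50% of its maximum over a sd scan (grid 0.1–2.5% in 0.1 steps,
  1000 s per run). The companion quantity sd_pol is the smallest scanned sd
  that actually polarizes; time and reversal experiments stimulate at
  sd_pol because the interpolated crossing lies inside the bistable jump,
  where no stable polarization forms. LEGI and Turing respond to
  arbitrarily small gradients (no threshold structure; the 50% level sits
  below ratio 1), so they carry conventional manual thresholds of 0.5% and
  0.1%.
* Re-polarization: polarize at sd_pol for 1000 s, reverse the gradient
  centre by π with amplitude 2×sd_thresh for 1000 s; the re-polarization
  time is the plateau entry of the u trace at the new front, accepted only
  if the reversed front/back ratio reaches the activation cutoff 1.5
  (otherwise "not reached", reported as the 1000 s cap). Without the gate,
  a non-reversing model's settling transient masquerades as
  re-polarization. Resolving (two opposed gradients, amplitude ratio 2)
  uses the same entry rule at the stronger-signal bin with success
  requiring plateau contrast > 1.
* Signal integration index: (duration with normalised front response > ½ −
  total stimulation time)/total time; additive over disjoint intervals.
* Spurious activation: fraction of seeded random perturbations
  (u_s + ξ r, v_s − ξ r, r ~ U[0,1] per bin; w_s too for LEGI) whose
  zero-signal simulation reaches a plateau max/min contrast ≥ 1.5. The
  contrast is direction-free because the perturbation has no preferred
  axis.

## What the defaults show — and what they do not

With the calibrated defaults the qualitative comparison is fully
reproduced: threshold activation and fast (re-)polarization are unique to
the critically organised SubPB regime; wave-pinning polarizes fast but
locks in (no re-polarization at 2×, minimal reversing amplitude ≈ 5×
threshold here); LEGI is fast to sense but amplification-free
(plateau ratio ≈ 1.05) and memoryless; Turing is slow, spuriously
activatable and never re-polarizes. Absolute numbers inherit the domain
scale: the measured thresholds are sd_thresh ≈ 0.73% (SubPB) and ≈ 0.34%
(wave-pinning), polarization times ≈ 2.5 / 2.1 / 6.0 / 9.5 min
(SubPB / WP / LEGI / Turing at their thresholds), and SubPB re-polarizes
in ≈ 1.3 min. LEGI's re-polarization and resolving are diffusion-limited
on a ~10 µm domain and therefore fast in absolute terms; comparisons
against mechanisms with intrinsically slow kinetics should be read as
orderings, not absolute times. Note also that LEGI's response component
has no turnover at zero signal (both its production and degradation are
signal-carried), so after a pulse its absolute level freezes even though
its spatial contrast resets; level-based metrics such as the integration
index therefore overstate LEGI memory, and contrast-based readouts should
be preferred for it.

Problem sizes: dose-response scans are 25 simulations of 1000 s each per
model; reversal experiments 2000 s each; Fokker–Planck solves on ~220²
grids. The synthetic stimulation protocols are idealised (noise-free,
piecewise-constant gradients); noisy-signal robustness enters only through
the spurious-activation and SDE machinery, and no attempt is made to model
receptor-level biochemistry or 2-D cell geometry.
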
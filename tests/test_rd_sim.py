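import math

import numpy as np
import pytest

from polaritylab import landscape, models, rd_sim, signals
from polaritylab.errors import ConfigurationError, DomainError
from polaritylab.rd_sim import DomainSpec


def test_uniform_state_has_zero_diffusion(domain, wp_model):
    prot = signals.sustained(s0=0.0, t_off=10.0)
    rhs = rd_sim.discretize(wp_model, domain, prot)
    hss = models.hss_state(wp_model)
    y = np.repeat(hss[:, None], domain.N, axis=1).ravel()
    expected = models.reaction_rates(wp_model, hss)
    out = rhs(0.0, y).reshape(2, domain.N)
    assert np.allclose(out, expected[:, None], atol=1e-12)


def test_single_bin_spike_laplacian_stencil(domain, wp_model):
    rhs = rd_sim.discretize(wp_model, domain, None)
    y = np.zeros((2, domain.N))
    y[0, 5] = 1.0
    out = rhs(0.0, y.ravel()).reshape(2, domain.N)
    p = wp_model.params
    # reaction at the spike: f_u(1, 0) = -delta; diffusion: -2 Du/dtheta^2
    assert out[0, 5] == pytest.approx(-p.delta - 2 * p.Du / domain.dtheta ** 2)
    assert out[0, 4] == pytest.approx(p.k0 * 0 + p.Du / domain.dtheta ** 2)


def test_rhs_telescopes_on_the_ring(domain, wp_model):
    rng = np.random.default_rng(0)
    rhs = rd_sim.discretize(wp_model, domain, None)
    y = rng.uniform(0.1, 2.0, size=2 * domain.N)
    assert abs(rhs(0.0, y).sum()) < 1e-12


def test_rhs_rotational_equivariance(domain, wp_model):
    k = 7
    prot = signals.sustained(s0=0.02, t_off=100.0)
    prot_rot = signals.sustained(s0=0.02, t_off=100.0,
                                 center=math.pi + k * 2 * math.pi / domain.N)
    rng = np.random.default_rng(1)
    y = rng.uniform(0.1, 2.0, size=(2, domain.N))
    f = rd_sim.discretize(wp_model, domain, prot)(1.0, y.ravel()).reshape(2, -1)
    y_rot = np.roll(y, k, axis=1)
    f_rot = rd_sim.discretize(wp_model, domain, prot_rot)(1.0, y_rot.ravel()).reshape(2, -1)
    assert np.max(np.abs(f_rot - np.roll(f, k, axis=1))) < 1e-10


def test_fixed_step_solution_rotates_with_the_signal(domain, subpb_model):
    k = 5
    prot = signals.sustained(s0=0.02, t_off=100.0)
    prot_rot = signals.sustained(s0=0.02, t_off=100.0,
                                 center=math.pi + k * 2 * math.pi / domain.N)
    a = rd_sim.simulate_sde(subpb_model, domain, prot, sigma=0.0, dt=0.01, t_span=(0, 100))
    b = rd_sim.simulate_sde(subpb_model, domain, prot_rot, sigma=0.0, dt=0.01, t_span=(0, 100))
    assert np.max(np.abs(b.u - np.roll(a.u, k, axis=1))) < 1e-10


def test_hss_is_stationary(domain):
    for name in ("region_I", "subpb", "wavepinning"):
        m = models.preset(name)
        kym = rd_sim.simulate(m, domain, None, t_span=(0.0, 50.0))
        assert np.max(np.abs(kym.fields[:, -1] - kym.fields[:, 0])) < 1e-8


def test_mass_conservation_during_stimulation(region_kymographs):
    for name in ("region_I", "region_II", "region_III"):
        assert region_kymographs[name].conservation_drift() < 1e-6


def test_sde_with_zero_noise_matches_ode(domain, subpb_model):
    prot = signals.sustained(s0=0.02, t_off=100.0)
    ode = rd_sim.simulate(subpb_model, domain, prot, t_span=(0, 100))
    sde = rd_sim.simulate_sde(subpb_model, domain, prot, sigma=0.0, dt=0.01, t_span=(0, 100))
    assert np.max(np.abs(sde.u - ode.u)) < 1e-3


def test_sde_seed_reproducibility(domain, subpb_model):
    prot = signals.sustained(s0=0.02, t_off=50.0)
    a = rd_sim.simulate_sde(subpb_model, domain, prot, sigma=1e-3, seed=42, t_span=(0, 50))
    b = rd_sim.simulate_sde(subpb_model, domain, prot, sigma=1e-3, seed=42, t_span=(0, 50))
    assert np.array_equal(a.fields, b.fields)
    c = rd_sim.simulate_sde(subpb_model, domain, prot, sigma=1e-3, seed=43, t_span=(0, 50))
    assert not np.array_equal(a.fields, c.fields)


def test_ornstein_uhlenbeck_stationary_variance():
    # du = -u dt + sigma dW has stationary variance sigma^2 / 2; the 2-D
    # sampler uses dx = g dt + sqrt(2 D) dW, so D = sigma^2 / 2
    sigma = 0.5
    D = sigma ** 2 / 2.0
    path = landscape.simulate_reduced_sde(lambda x, y: (-x, -y), D=D, x0=(0.0, 0.0),
                                          t_end=2000.0, dt=0.02, seed=7,
                                          clip_min=-np.inf, record_every=1)
    samples = path[5000:]
    var = samples.var(axis=0).mean()
    assert var == pytest.approx(sigma ** 2 / 2.0, rel=0.05)


def test_refinement_in_bin_number(subpb_model):
    prot20 = signals.sustained(s0=0.03, t_off=600.0, N=20)
    prot40 = signals.sustained(s0=0.03, t_off=600.0, N=40)
    k20 = rd_sim.simulate(subpb_model, DomainSpec(N=20), prot20, t_span=(0, 600))
    k40 = rd_sim.simulate(subpb_model, DomainSpec(N=40), prot40, t_span=(0, 600))

    def ratio(k):
        return k.trace_at(math.pi)[-100:].mean() / k.trace_at(0.0)[-100:].mean()

    assert ratio(k40) == pytest.approx(ratio(k20), rel=0.05)


def test_negative_sigma_rejected(domain, subpb_model):
    with pytest.raises(DomainError):
        rd_sim.simulate_sde(subpb_model, domain, None, sigma=-1.0)


def test_protocol_domain_mismatch(domain, subpb_model):
    prot = signals.sustained(s0=0.02, N=30)
    with pytest.raises(ConfigurationError):
        rd_sim.discretize(subpb_model, domain, prot)


def test_kymograph_bin_lookup(region_kymographs):
    kym = region_kymographs["region_II"]
    assert kym.bin_nearest(0.0) == 0
    assert kym.bin_nearest(math.pi) == 10
    assert np.array_equal(kym.trace_at(math.pi), kym.u[:, 10])
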
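import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from polaritylab import metrics, models, rd_sim
from polaritylab.errors import DomainError
from polaritylab.rd_sim import DomainSpec, Kymograph


def make_kym(u, times=None, model=None, domain=None):
    """Synthetic kymograph from a (T, N) membrane-response matrix."""
    u = np.asarray(u, dtype=float)
    model = model or models.preset("subpb")
    domain = domain or DomainSpec(N=u.shape[1])
    times = np.arange(u.shape[0], dtype=float) if times is None else times
    fields = np.stack([u, np.full_like(u, 1.0)])
    return Kymograph(times=times, theta=domain.theta, fields=fields,
                     signal_history=np.zeros_like(u), model=model, domain=domain)


def test_homogeneous_field_ratio_is_one():
    kym = make_kym(np.ones((150, 20)))
    assert metrics.polarization_ratio(kym) == 1.0


def test_mirrored_field_gives_reciprocal_ratio():
    rng = np.random.default_rng(0)
    profile = rng.uniform(0.5, 2.0, 20)
    mirrored = profile[(10 - np.arange(20)) % 20]  # theta -> pi - theta swaps poles
    a = metrics.polarization_ratio(make_kym(np.tile(profile, (150, 1))))
    b = metrics.polarization_ratio(make_kym(np.tile(mirrored, (150, 1))))
    assert a * b == pytest.approx(1.0)


def test_zero_back_bin_flags_infinite_ratio():
    u = np.ones((150, 20))
    u[:, 0] = 0.0
    assert math.isinf(metrics.polarization_ratio(make_kym(u)))


def test_polarization_time_of_constant_trace_is_first_sample():
    kym = make_kym(np.ones((200, 20)))
    t, reached = metrics.polarization_time(kym)
    assert t == 0.0 and reached


def test_polarization_time_of_ramp_matches_hand_value():
    # normalized ramp to a 300-sample plateau: plateau mean = 1, band entry
    # at the first sample with x >= 0.99, i.e. t = ceil(0.99 * 100) = 99
    T, N = 400, 20
    u = np.ones((T, N))
    ramp = np.concatenate([np.linspace(0.0, 1.0, 101), np.ones(T - 101)])
    u[:, 10] = 2.0 * ramp + 1.0
    t, reached = metrics.polarization_time(make_kym(u))
    assert reached
    assert t == pytest.approx(99.0, abs=1.0)  # one-sample slack for fp rounding


def test_polarization_time_short_epoch_rejected(region_kymographs):
    with pytest.raises(DomainError):
        metrics.polarization_time(region_kymographs["region_II"], epoch=(0.0, 50.0))


def test_threshold_from_synthetic_logistic_curve():
    def logistic(sd, mid=1.0):
        return 1.0 + 6.0 / (1.0 + np.exp(-(sd - mid) / 0.05))

    grid = np.arange(0.1, 2.01, 0.1)
    th, sd_pol, ok = metrics.threshold_from_curve(grid, logistic(grid))
    assert ok
    # 50% of max (3.5) sits just below the midpoint of the logistic
    assert th == pytest.approx(1.0, abs=0.1)
    fine = np.arange(0.1, 2.001, 0.02)
    th_fine, _, _ = metrics.threshold_from_curve(fine, logistic(fine))
    assert abs(th_fine - th) <= 0.1  # invariant to refinement within one step


def test_flat_curve_is_not_estimable():
    grid = np.arange(0.1, 1.01, 0.1)
    th, sd_pol, ok = metrics.threshold_from_curve(grid, np.ones_like(grid))
    assert not ok and math.isnan(th)


def test_manual_overrides_attached_to_spurious_models(small_scans):
    curves, grid = small_scans
    est = metrics.SdThreshold(model="legi", sd_grid=grid, ratios=curves["legi"],
                              sd_thresh=math.nan, sd_pol=math.nan, estimable=False,
                              manual_override=metrics.MANUAL_SD_THRESH["legi"])
    assert est.effective == 0.5
    assert metrics.MANUAL_SD_THRESH == {"legi": 0.5, "turing": 0.1}


def test_already_reversed_field_reverses_immediately():
    # polarized toward theta = 0 from the start of the "reversal" epoch
    u = np.tile(1.0 + np.cos(DomainSpec().theta), (300, 1)) + 0.1
    kym = make_kym(u)
    t, reached, amp = metrics.repolarization_metrics(kym, t_reverse=0.0)
    assert reached and t == 0.0
    assert amp > metrics.ACTIVATION_CUTOFF


def test_unreversed_field_reports_cap():
    u = np.tile(1.0 + np.cos(DomainSpec().theta + math.pi), (1100, 1)) + 0.1
    kym = make_kym(u)
    t, reached, amp = metrics.repolarization_metrics(kym, t_reverse=0.0)
    assert not reached
    assert t == metrics.NOT_REACHED_CAP_S
    assert amp < 1.0


def test_resolving_degenerates_to_polarization_time(domain, subpb_model):
    from polaritylab import signals
    prot = signals.sustained(s0=0.03, t_off=400.0)
    kym = rd_sim.simulate(subpb_model, domain, prot, t_span=(0.0, 400.0))
    t_pol, _ = metrics.polarization_time(kym)
    t_res, resolved, _ = metrics.resolving_metrics(kym, stronger_angle=math.pi)
    assert resolved
    assert t_res == t_pol


class TestIntegrationIndex:
    times = np.arange(0.0, 1000.0 + 0.5, 1.0)

    def test_never_above_threshold(self):
        u = np.zeros_like(self.times)
        on = (self.times >= 100) & (self.times < 300)
        idx = metrics.signal_integration_index(u, on, self.times)
        dt = np.gradient(self.times)
        assert idx == pytest.approx(-dt[on].sum() / 1000.0)

    def test_persistent_polarity_independent_of_pulse_count(self):
        u = np.ones_like(self.times)
        for n_pulses in (1, 3):
            on = np.zeros_like(self.times, dtype=bool)
            for k in range(n_pulses):
                on |= (self.times >= 100 + 200 * k) & (self.times < 200 + 200 * k)
            idx = metrics.signal_integration_index(u, on, self.times)
            dt = np.gradient(self.times)
            assert idx == pytest.approx((dt.sum() - dt[on].sum()) / 1000.0)

    def test_memory_seconds_beyond_signal(self):
        on = (self.times >= 100) & (self.times < 300)
        u = np.where((self.times >= 100) & (self.times < 300 + 150), 1.0, 0.0)
        idx = metrics.signal_integration_index(u, on, self.times)
        dt = np.gradient(self.times)
        above = u > 0.5
        assert idx == pytest.approx((dt[above].sum() - dt[on].sum()) / 1000.0)
        assert idx == pytest.approx(150.0 / 1000.0, abs=2e-3)

    @given(split=st.integers(120, 280))
    @settings(deadline=None, derandomize=True, max_examples=20)
    def test_additive_over_disjoint_intervals(self, split):
        on = np.zeros_like(self.times, dtype=bool)
        u1 = ((self.times >= 100) & (self.times < split)).astype(float)
        u2 = ((self.times >= split) & (self.times < 300)).astype(float)
        u12 = np.clip(u1 + u2, 0, 1)
        f = lambda u: metrics.signal_integration_index(u, on, self.times)
        assert f(u12) == pytest.approx(f(u1) + f(u2), abs=5e-3)


def test_spurious_activation_zero_perturbation(domain, subpb_model):
    frac = metrics.spurious_activation(subpb_model, xi_per=0.0, n_reps=2,
                                       domain=domain, T=200.0)
    assert frac == 0.0


def test_metrics_are_pure(region_kymographs):
    kym = region_kymographs["region_II"]
    assert metrics.polarization_ratio(kym) == metrics.polarization_ratio(kym)
    a = metrics.polarization_time(kym, epoch=(100.0, 300.0))
    b = metrics.polarization_time(kym, epoch=(100.0, 300.0))
    assert a == b
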
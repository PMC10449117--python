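import numpy as np
import pytest
from scipy.optimize import fsolve

from polaritylab import models, stability
from polaritylab.errors import ConfigurationError, DomainError


def _single_bin_jacobian(model):
    p = model.params
    u, v = models.hss_state(model)
    h = 1e-7
    fu_u = (p.f_u(u + h, v) - p.f_u(u - h, v)) / (2 * h)
    fu_v = (p.f_u(u, v + h) - p.f_u(u, v - h)) / (2 * h)
    return np.array([[fu_u, fu_v], [-fu_u, -fu_v]])


def test_pb_condition_reduces_to_single_bin_determinant(wp_model):
    # with both exchange rates zero the bins decouple and |F| = 4 det(J1)
    det_f = stability.pb_condition(wp_model, Du_tilde=0.0, Dv_tilde=0.0)
    det_j = np.linalg.det(_single_bin_jacobian(wp_model))
    assert det_f == pytest.approx(4.0 * det_j, rel=1e-6)


def test_pb_condition_determinant_homogeneity(wp_model):
    # scaling all rates (and exchange) by c scales G1..G4 by c, |F| by c^2
    c = 3.0
    p = wp_model.params
    scaled = wp_model.with_params(k0=c * p.k0, gamma=c * p.gamma, delta=c * p.delta)
    det1 = stability.pb_condition(wp_model, Du_tilde=0.01, Dv_tilde=10.0)
    det2 = stability.pb_condition(scaled, Du_tilde=c * 0.01, Dv_tilde=c * 10.0)
    assert det2 == pytest.approx(c ** 2 * det1, rel=1e-6)


def test_pb_condition_rejects_asymmetric_state(wp_model):
    with pytest.raises(DomainError):
        stability.pb_condition(wp_model, hss=np.array([0.2, 2.0, 0.4, 1.8]))


def test_pb_location_agrees_with_continuation(wp_model, two_bin_diagram):
    c_pb_cond = stability.find_pb_from_condition(wp_model, (2.0, 2.45))
    pbs = two_bin_diagram.points_of("PB")
    assert len(pbs) == 1
    assert abs(pbs[0].param - c_pb_cond) < 1e-3


def test_region_ordering_along_c_total(wp_model, two_bin_diagram):
    sns = two_bin_diagram.points_of("SN_PB")
    pbs = two_bin_diagram.points_of("PB")
    assert len(sns) >= 1 and len(pbs) == 1
    c_sn = min(s.param for s in sns)
    c_pb = pbs[0].param
    assert 2.21 < c_sn < 2.26 < c_pb < 2.32
    bounds = stability.RegionBoundaries(c_sn=c_sn, c_pb=c_pb)
    assert [stability.classify_region(c, bounds) for c in (2.1, 2.21, 2.26, 2.32)] == \
        ["I", "II", "III", "IV"]


def test_branches_come_in_mirror_pairs(two_bin_diagram):
    def mirror(x, c):
        uL, vL, uR = x
        vR = 2 * c - uL - vL - uR
        return np.array([uR, vR, uL])

    asym = [b for b in two_bin_diagram.branches if not b.symmetric]
    assert len(asym) >= 2
    b = asym[0]
    mid = len(b.params) // 2
    c, x = b.params[mid], b.states[mid]
    xm = mirror(x, c)
    found = any(
        np.min(np.linalg.norm(o.states - xm, axis=1) + np.abs(o.params - c)) < 1e-2
        for o in asym)
    assert found


def test_saddle_node_has_zero_eigenvalue(wp_model, two_bin_diagram):
    # refine the located fold with the extended system (f = 0, det J = 0)
    sn = min(two_bin_diagram.points_of("SN_PB"), key=lambda s: s.param)
    f = stability.two_bin_steady_system(wp_model)

    def jac(x, c):
        h = 1e-7
        J = np.empty((3, 3))
        for j in range(3):
            e = np.zeros(3)
            e[j] = h
            J[:, j] = (f(x + e, c) - f(x - e, c)) / (2 * h)
        return J

    def ext(z):
        x, c = z[:3], z[3]
        return np.concatenate([f(x, c), [np.linalg.det(jac(x, c))]])

    sol = fsolve(ext, np.concatenate([sn.state, [sn.param]]), xtol=1e-13)
    assert abs(sol[3] - sn.param) < 1e-3
    lead = np.max(np.linalg.eigvals(jac(sol[:3], sol[3])).real)
    assert abs(lead) < 1e-6


def test_lpa_local_equals_global_when_initialised_equal(wp_model):
    sys = stability.lpa_reduce(wp_model)
    u = 0.7
    d = sys.rhs(np.array([u, u]), 2.26)
    assert d[0] == pytest.approx(d[1], abs=1e-14)


def test_lpa_global_subsystem_is_well_mixed(wp_model):
    sys = stability.lpa_reduce(wp_model)
    p = wp_model.params
    for u in (0.1, 0.5, 1.2):
        assert sys.global_rhs(np.array([u]), 2.26)[0] == pytest.approx(p.f_u(u, 2.26 - u))


@pytest.mark.parametrize("c_total,n_roots", [(1.8, 1), (2.26, 3)])
def test_lpa_local_root_structure(c_total, n_roots):
    # the zero-diffusion (LPA) limit is bistable on a wider c_total window
    # than the finite-diffusion system: already 3 local roots by c ~= 2.0
    # dense scalar root scan of f_u(u_local, c - u_global) at the frozen HSS
    m = models.preset("wavepinning").with_params(c_total=c_total)
    p = m.params
    ug = models.hss_state(m)[0]
    v = c_total - ug
    grid = np.linspace(0.0, 2 * c_total, 2000)
    vals = p.f_u(grid, v)
    crossings = np.sum(vals[:-1] * vals[1:] < 0)
    assert crossings == n_roots


def test_turing_lpa_shows_transcritical_point():
    m = models.preset("turing")
    diag = stability.continue_lpa(m, (1.0, 2.6))
    tcs = diag.points_of("TC")
    assert len(tcs) >= 1
    assert min(abs(tc.param - 1.0 / m.params.a2) for tc in tcs) < 1e-3


def test_legi_continuation_single_branch_no_special_points():
    diag = stability.continue_lpa(models.preset("legi"), (0.5, 4.0))
    assert len(diag.branches) == 1
    assert diag.special_points == []
    # at zero signal the response variable is marginal (no drive), so the
    # leading eigenvalue sits at 0; no growth anywhere on the branch
    assert np.max(diag.branches[0].leading_re) <= 1e-8


def test_lpa_requires_diffusivity_separation():
    m = models.preset("wavepinning").with_params(Du=5.0, Dv=10.0)
    with pytest.raises(ConfigurationError):
        stability.lpa_reduce(m)


class TestUnfolding:
    @pytest.fixture(scope="class")
    def diagrams(self, subpb_model):
        return stability.unfolding_diagram(subpb_model, [0.0, 0.005, 0.02],
                                           c_range=(2.05, 2.35))

    def test_zero_signal_has_symmetric_pitchfork(self, diagrams):
        assert len(diagrams[0].points_of("PB")) >= 1

    def test_any_signal_destroys_the_symmetric_branch(self, diagrams):
        for diag in diagrams[1:]:
            assert diag.points_of("PB") == []
            for br in diag.branches:
                mid = len(br.params) // 2
                uL, _, uR = br.states[mid]
                assert abs(uL - uR) > 1e-4

    def test_polar_state_only_stable_solution_at_max_amplitude(self, diagrams):
        diag = diagrams[-1]
        c0 = 2.21
        stable_states = []
        for br in diag.branches:
            for c, x, st in zip(br.params, br.states, br.stable):
                if abs(c - c0) < 5e-3 and st:
                    stable_states.append(x)
        assert stable_states
        assert all(abs(x[0] - x[2]) > 0.2 for x in stable_states)
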
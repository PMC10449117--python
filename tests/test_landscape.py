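import numpy as np
import pytest

from polaritylab import landscape, models, projection, signals
from polaritylab.errors import DomainError
from polaritylab.landscape import gaussian_curvature, quasi_potential


class TestFokkerPlanck:
    def test_linear_gradient_flow_gives_product_gaussian(self):
        D = 0.02
        P, x, y = landscape.solve_fokker_planck(lambda X, Y: (-X, -Y), D=D,
                                                extent=((-1, 1), (-1, 1)), h=0.02,
                                                return_grid=True)
        X, Y = np.meshgrid(x, y, indexing="ij")
        exact = np.exp(-(X ** 2 + Y ** 2) / (2 * D))
        exact /= exact.sum() * 0.02 ** 2
        bulk = exact > exact.max() * 1e-3
        assert np.max(np.abs(P[bulk] - exact[bulk]) / exact[bulk]) < 0.02

    def test_zero_drift_reflecting_box_is_uniform(self):
        # the uniform density necessarily touches the outer wall, so the
        # grid-extent guard is disabled for this degenerate case
        P = landscape.solve_fokker_planck(lambda X, Y: (np.zeros_like(X), np.zeros_like(Y)),
                                          D=0.02, extent=((0, 1), (0, 1)), h=0.05,
                                          boundary_tol=1.0)
        assert np.max(np.abs(P - P.mean()) / P.mean()) < 1e-8

    def test_probability_is_normalised(self, region_surfaces):
        surf = region_surfaces["wavepinning"]
        assert surf.P_ss.sum() * surf.h ** 2 == pytest.approx(1.0, abs=1e-6)
        assert np.all(surf.P_ss >= 0)

    def test_nongradient_extent_guard(self):
        # a drift pushing mass outward must trip the grid-extent error
        with pytest.raises(DomainError):
            landscape.solve_fokker_planck(lambda X, Y: (np.ones_like(X), np.ones_like(Y)),
                                          D=0.02, extent=((0, 1), (0, 1)), h=0.05)

    def test_quasi_potential_of_exact_gradient_drift(self):
        # for drift = -grad U, Q = -ln P_ss recovers U/D up to a constant
        D = 0.05

        def drift(X, Y):
            return (-X ** 3, -Y)

        P, x, y = landscape.solve_fokker_planck(drift, D=D, extent=((-1.5, 1.5), (-1.5, 1.5)),
                                                h=0.02, return_grid=True)
        X, Y = np.meshgrid(x, y, indexing="ij")
        U = 0.25 * X ** 4 + 0.5 * Y ** 2
        Q = quasi_potential(P)
        bulk = U / D < 8.0
        resid = (Q - U / D)[bulk]
        resid = resid - resid.mean()
        rms = np.sqrt(np.mean(resid ** 2)) / (np.max(U[bulk] / D) - np.min(U[bulk] / D))
        assert rms < 0.03

    def test_pseudo_time_evolution_conserves_probability(self):
        h = 0.05
        x = np.arange(0.0, 1.0 + h / 2, h)
        P0 = np.ones((len(x), len(x)))
        P0 /= P0.sum() * h * h
        P = landscape.evolve_fokker_planck(lambda X, Y: (-(X - 0.5), -(Y - 0.5)), P0,
                                           t_end=5.0, D=0.02, extent=((0, 1), (0, 1)), h=h)
        assert P.sum() * h * h == pytest.approx(1.0, abs=1e-6)


class TestQuasiPotential:
    def test_uniform_density_flat_potential(self):
        Q = quasi_potential(np.full((10, 10), 0.01))
        assert np.ptp(Q) == 0.0

    def test_floor_saturation(self):
        P = np.array([[1.0, 1e-15], [1e-13, 0.5]])
        Q = quasi_potential(P, floor=1e-12)
        assert Q[0, 1] == Q[1, 0] == pytest.approx(-np.log(1e-12))

    def test_gaussian_density_gives_quadratic_potential(self):
        h = 0.02
        x = np.arange(-1, 1 + h / 2, h)
        X, Y = np.meshgrid(x, x, indexing="ij")
        D = 0.05
        P = np.exp(-(X ** 2 + Y ** 2) / (2 * D))
        Q = quasi_potential(P / (P.sum() * h * h))
        expected = (X ** 2 + Y ** 2) / (2 * D)
        resid = Q - expected
        resid -= resid.mean()
        assert np.max(np.abs(resid)) < 0.01 * np.ptp(expected)


class TestCurvature:
    h = 0.05
    x = np.arange(-1, 1 + 0.025, 0.05)

    def _grid(self):
        return np.meshgrid(self.x, self.x, indexing="ij")

    def test_paraboloid_bowl(self):
        X, Y = self._grid()
        K = gaussian_curvature((X ** 2 + Y ** 2) / 2, self.h)
        i = len(self.x) // 2
        assert K[i, i] == pytest.approx(1.0, abs=1e-10)

    def test_plane_is_flat(self):
        X, Y = self._grid()
        K = gaussian_curvature(1.0 + 2 * X - 3 * Y, self.h)
        assert np.max(np.abs(K)) < 1e-10

    def test_saddle(self):
        X, Y = self._grid()
        K = gaussian_curvature((X ** 2 - Y ** 2) / 2, self.h)
        i = len(self.x) // 2
        assert K[i, i] == pytest.approx(-1.0, abs=1e-10)

    def test_second_order_convergence(self):
        # analytic oracle for Q = cos(x) cos(y) at the origin: K = 1
        def err(h):
            x = np.arange(-0.5, 0.5 + h / 2, h)
            X, Y = np.meshgrid(x, x, indexing="ij")
            K = gaussian_curvature(np.cos(X) * np.cos(Y), h)
            i = len(x) // 2
            return abs(K[i, i] - 1.0)

        e1, e2 = err(0.02), err(0.01)
        assert e2 < e1 / 3.0  # ~quarter for O(h^2)

    def test_small_grid_rejected(self):
        with pytest.raises(DomainError):
            gaussian_curvature(np.zeros((4, 4)), 0.1)


class TestWells:
    def test_product_gaussian_single_well(self):
        h = 0.02
        x = np.arange(-1, 1 + h / 2, h)
        X, Y = np.meshgrid(x, x, indexing="ij")
        P = np.exp(-(X ** 2 + Y ** 2) / (2 * 0.02))
        P /= P.sum() * h * h
        surf = landscape.asymptotic_regions(x, x, P)
        assert len(surf.wells) == 1
        w = surf.wells[0]
        assert np.hypot(*w.minimum) < 0.05
        assert w.Q_bound > w.Q_min

    def test_region_III_has_three_wells(self, region_surfaces):
        surf = region_surfaces["wavepinning"]
        assert len(surf.wells) == 3
        minima = sorted(w.minimum for w in surf.wells)
        assert minima[0][0] < minima[1][0] < minima[2][0]
        # one symmetric (HSS) + two mirror polar wells
        sym = [w for w in surf.wells if abs(w.minimum[0] - w.minimum[1]) < 0.05]
        assert len(sym) == 1

    def test_region_II_single_well_plus_ghost_shoulder(self, region_surfaces):
        surf = region_surfaces["subpb"]
        assert len(surf.wells) == 1
        assert abs(surf.wells[0].minimum[0] - surf.wells[0].minimum[1]) < 0.05
        assert len(surf.non_wells) >= 1  # the positive-curvature, sloped shoulder


class TestTrajectoryClassification:
    @pytest.fixture(scope="class")
    def post_signal(self):
        out = {}
        for name in ("subpb", "wavepinning"):
            m = models.preset(name)
            prot = signals.step_protocol([(0.03, 0.0, 400.0), (0.0, 0.0, 600.0)])
            traj = projection.simulate_projection(m, prot)
            sl = traj.epoch_slice(1)
            out[name] = (traj.times[sl], np.column_stack([traj.uL[sl], traj.uR[sl]]))
        return out

    def test_resting_trajectory_is_fully_asymptotic(self, region_surfaces):
        surf = region_surfaces["wavepinning"]
        w = surf.wells[0]
        times = np.arange(50.0)
        pts = np.tile(w.minimum, (50, 1))
        cls = landscape.classify_trajectory(times, pts, surf)
        assert all(lab == "asymptotic" for lab in cls.labels)
        assert cls.ghost_dwell == 0.0

    def test_region_II_post_signal_ghost_dwell(self, region_surfaces, post_signal):
        times, pts = post_signal["subpb"]
        cls = landscape.classify_trajectory(times, pts, region_surfaces["subpb"])
        assert cls.ghost_dwell > 0.0
        assert cls.labels[-1] == "asymptotic"      # finally back in the HSS well

    def test_region_III_post_signal_immediately_asymptotic(self, region_surfaces, post_signal):
        times, pts = post_signal["wavepinning"]
        cls = landscape.classify_trajectory(times, pts, region_surfaces["wavepinning"])
        assert cls.ghost_dwell == 0.0
        assert (cls.labels == "asymptotic").mean() > 0.95

    def test_out_of_grid_point_rejected(self, region_surfaces):
        surf = region_surfaces["subpb"]
        with pytest.raises(DomainError):
            landscape.classify_trajectory(np.arange(3.0), np.full((3, 2), 99.0), surf)


def test_sde_histogram_matches_stationary_density():
    # monostable (region I) drift: the long-run Euler-Maruyama histogram and
    # the discrete stationary density must agree in total variation
    m = models.preset("wavepinning").with_params(c_total=2.1)
    drift = projection.two_bin_reduced_drift(m)
    D = 0.02
    P, x, y = landscape.solve_fokker_planck(drift, D=D, extent=((0, 4.2), (0, 4.2)),
                                            h=0.02, return_grid=True)
    hss = models.hss_state(m)[0]
    path = landscape.simulate_reduced_sde(drift, D=D, x0=(hss, hss), t_end=10000.0,
                                          dt=0.01, seed=11, record_every=10)
    edges = np.arange(0.0, 4.2001, 0.1)
    hist, _, _ = np.histogram2d(path[1000:, 0], path[1000:, 1], bins=(edges, edges))
    hist = hist / hist.sum()
    # coarsen P onto the same 0.1-wide boxes
    Pc = P[:-1, :-1].reshape(42, 5, 42, 5).sum(axis=(1, 3))
    Pc = Pc / Pc.sum()
    tv = 0.5 * np.abs(hist - Pc).sum()
    assert tv < 0.05
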
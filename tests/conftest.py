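"""Shared fixtures. Expensive scans and landscapes are session-scoped."""

import numpy as np
import pytest

from polaritylab import landscape, metrics, models, projection, rd_sim, signals


@pytest.fixture(scope="session")
def domain():
    return rd_sim.DomainSpec()


@pytest.fixture(scope="session")
def wp_model():
    return models.preset("wavepinning")


@pytest.fixture(scope="session")
def subpb_model():
    return models.preset("subpb")


SD_GRID = np.round(np.arange(0.1, 2.51, 0.1), 3)


@pytest.fixture(scope="session")
def thresholds(domain):
    """Dose-response thresholds for the two wave-pinning-family presets."""
    return {name: metrics.estimate_sd_thresh(models.preset(name), SD_GRID, domain)
            for name in ("subpb", "wavepinning")}


@pytest.fixture(scope="session")
def small_scans(domain):
    """Low-sd dose-response curves for LEGI and Turing (sensitivity checks)."""
    grid = [0.1, 0.2, 0.3, 0.4, 0.5]
    return {name: metrics.dose_response(models.preset(name), grid, domain)
            for name in ("legi", "turing")}, np.asarray(grid)


@pytest.fixture(scope="session")
def region_surfaces():
    """Quasi-potential landscapes of the region II and III presets at s = 0."""
    out = {}
    for name, c in (("subpb", 2.21), ("wavepinning", 2.26)):
        m = models.preset(name)
        drift = projection.two_bin_reduced_drift(m)
        out[name] = landscape.surface_from_drift(drift, extent=((0.0, 2 * c), (0.0, 2 * c)))
    return out


@pytest.fixture(scope="session")
def two_bin_diagram(wp_model):
    from polaritylab import stability
    return stability.continue_two_bin(wp_model, (2.0, 2.4))


@pytest.fixture(scope="session")
def region_kymographs(domain):
    """Transient-gradient simulations of the four region presets."""
    prot = signals.single_transient(s0=0.02, t_on=100.0, t_off=300.0)
    out = {}
    for name, pert in (("region_I", 0.0), ("region_II", 0.0),
                       ("region_III", 0.0), ("region_IV", 1e-3)):
        out[name] = rd_sim.simulate(models.preset(name), domain, prot,
                                    t_span=(0.0, 1000.0), ic_perturbation=pert)
    return out
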
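import numpy as np
import pytest

from cytostream.geometry import build_grid, make_capsule, make_sphere
from cytostream.inference import Observations
from cytostream.solver import solve_stokes
from cytostream.synthetic import benchmark_case


def tau0(z):
    """Analytic benchmark stress on the unit sphere."""
    return 3.0 * np.sqrt(np.maximum(1.0 - np.asarray(z, dtype=float) ** 2, 0.0))


@pytest.fixture(scope="session")
def sphere():
    return make_sphere(1.0)


@pytest.fixture(scope="session")
def capsule():
    return make_capsule(1.0, 55.0 / 13.0)


@pytest.fixture(scope="session")
def sphere_grid(sphere):
    """The reference mouse-oocyte resolution on the unit sphere."""
    return build_grid(sphere, 25, 13)


@pytest.fixture(scope="session")
def capsule_grid(capsule):
    """The reference C. elegans resolution on the 55/13 capsule."""
    return build_grid(capsule, 56, 14)


@pytest.fixture(scope="session")
def benchmark_flow(sphere_grid):
    """Converged flow under the analytic benchmark stress."""
    flow = solve_stokes(sphere_grid, tau0)
    assert flow.converged
    return flow


@pytest.fixture(scope="session")
def benchmark_spline_flow(sphere_grid):
    """Converged flow under the spline-fitted benchmark stress."""
    _, spline, _ = benchmark_case()
    flow = solve_stokes(sphere_grid, spline)
    assert flow.converged
    return flow, spline


@pytest.fixture(scope="session")
def benchmark_observations(sphere_grid, benchmark_spline_flow):
    """Noiseless grid-sampled observations of the benchmark flow."""
    flow, spline = benchmark_spline_flow
    zz = np.broadcast_to(sphere_grid.z_nodes[:, None], flow.v_z.shape)
    rr = sphere_grid.r
    mask = (rr > 0) & (np.abs(zz) < 0.95)
    return Observations(zz[mask], rr[mask], flow.v_z[mask], flow.v_r[mask])
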
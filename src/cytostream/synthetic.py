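"""Synthetic test inputs: observations, particle-image pairs, benchmark.

Everything the other modules need for testing is generated here from known
ground truth, with no external data:

* noisy velocity observations sampled from a forward Stokes solve under a
  known stress parameter vector;
* particle-image stack pairs advected by a known flow, for the PIV surface;
* the analytic spherical benchmark pairing stress ``tau0 = 3 (1-z^2)^{1/2}``
  with cortical slip ``u0 = (1-z^2)^{1/2}``;
* a SYNTHETIC stand-in for the deposited per-cell flow-table workbook
  (sheets Ce1..Ce6 / Mm1..Mm7) at realistic physical scales.

Every generated artifact records the seed and a hash of its generating
specification; regeneration with the same spec is bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .geometry import BoundaryShape, build_grid, make_capsule, make_sphere
from .inference import Observations
from .piv import DEFAULT_SEARCHES, ImageStack
from .solver import FlowField, SolverParams, solve_stokes
from .stress import StressSpline, default_node_positions, fit_amplitudes

__all__ = [
    "SyntheticSpec",
    "synth_observations",
    "synth_particle_stacks",
    "benchmark_case",
    "synth_s1_dataset",
]


@dataclass
class SyntheticSpec:
    """Generation settings for synthetic observations and image pairs."""

    shape_kind: str = "sphere"  # sphere | capsule
    long_axis: float = 55.0 / 13.0  # capsule only
    stress: tuple = ()  # ground-truth amplitudes Theta*; empty = benchmark fit
    noise_sd: float = 0.05  # fraction of the maximum speed
    n_points: int = 200
    particle_density: float = 0.02  # particles per um^2 (2D rendering)
    psf_sd: float = 0.5  # um
    dt: float = 5.0  # s
    seed: int = 0

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    def spec_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=list)
        return hashlib.sha1(payload.encode()).hexdigest()[:12]

    def make_shape(self) -> BoundaryShape:
        if self.shape_kind == "sphere":
            return make_sphere(1.0)
        return make_capsule(1.0, self.long_axis)


def benchmark_case(n_nodes: int = 7):
    """The analytic spherical benchmark.

    Returns ``(shape, stress_spline, u0)``: the unit sphere, the stress
    spline least-squares fitted to ``tau0(z) = 3 (1-z^2)^{1/2}`` over the
    node layout, and the analytic cortical slip profile
    ``u0(z) = (1-z^2)^{1/2}`` that this stress generates at unit viscosity.
    """
    shape = make_sphere(1.0)
    nodes = default_node_positions(1.0, n_nodes)
    spline = fit_amplitudes(
        lambda z: 3.0 * np.sqrt(np.maximum(1.0 - z * z, 0.0)), nodes, 1.0
    )

    def u0(z):
        return np.sqrt(np.maximum(1.0 - np.asarray(z, dtype=float) ** 2, 0.0))

    return shape, spline, u0


def _stratified_points(shape, n_points, rng):
    """Stratified-random (z, s) positions mapped inside the boundary."""
    hl = shape.half_length
    n_bins = max(int(np.sqrt(n_points)), 1)
    zs, ss = [], []
    total = 0
    while total < n_points:
        iz = np.arange(n_bins)
        z = -hl + (iz + rng.uniform(size=n_bins)) * (2 * hl / n_bins)
        s = rng.uniform(0.05, 0.98, size=n_bins)
        zs.append(z)
        ss.append(s)
        total += n_bins
    z = np.concatenate(zs)[:n_points]
    s = np.concatenate(ss)[:n_points]
    # keep points off the degenerate pole caps
    z = np.clip(z, -0.97 * hl, 0.97 * hl)
    sign = np.where(rng.uniform(size=n_points) < 0.5, -1.0, 1.0)
    r = sign * s * shape.F(z)
    return z, r


def synth_observations(
    spec: SyntheticSpec,
    grid_nz: int | None = None,
    grid_ns: int | None = None,
    solver: SolverParams | None = None,
) -> tuple[Observations, StressSpline]:
    """Noisy velocity observations from a known stress profile.

    Forward-solves the Stokes problem under the ground-truth amplitudes,
    samples velocities at stratified-random interior positions, and adds
    i.i.d. Gaussian noise with SD ``noise_sd`` times the maximum speed.
    Returns ``(observations, ground_truth_spline)``.
    """
    shape = spec.make_shape()
    if grid_nz is None:
        grid_nz, grid_ns = (25, 13) if spec.shape_kind == "sphere" else (56, 14)
    grid = build_grid(shape, grid_nz, grid_ns)
    # bilinear interpolation cannot add information beyond ~the cell count;
    # refuse absurd oversampling of a coarse grid
    if spec.n_points > 50 * grid_nz * grid_ns:
        raise ValueError(
            f"{spec.n_points} observation points exceed the support of a "
            f"{grid_nz}x{grid_ns} grid"
        )
    if len(spec.stress):
        truth = StressSpline(
            np.asarray(spec.stress, dtype=float),
            default_node_positions(shape.half_length, len(spec.stress)),
            shape.half_length,
        )
    else:
        _, truth, _ = benchmark_case()
        if spec.shape_kind != "sphere":
            truth = StressSpline(
                truth.amplitudes,
                default_node_positions(shape.half_length),
                shape.half_length,
            )
    flow = solve_stokes(grid, truth, params=solver)
    rng = np.random.default_rng(spec.seed)
    z, r = _stratified_points(shape, spec.n_points, rng)
    s = np.abs(r) / shape.F(z)
    pts = np.column_stack([z, np.clip(s, 0.0, 1.0)])
    vz = RegularGridInterpolator((grid.z_nodes, grid.s_nodes), flow.v_z)(pts)
    vr = RegularGridInterpolator((grid.z_nodes, grid.s_nodes), flow.v_r)(pts)
    vr = vr * np.where(r < 0, -1.0, 1.0)
    vmax = float(np.hypot(vz, vr).max())
    sd = spec.noise_sd * vmax
    vz = vz + sd * rng.standard_normal(vz.size)
    vr = vr + sd * rng.standard_normal(vr.size)
    obs = Observations(
        z=z,
        r=r,
        v_z=vz,
        v_r=vr,
        scale={"seed": spec.seed, "spec_hash": spec.spec_hash(), "noise_sd_abs": sd},
        label=f"synthetic-{spec.spec_hash()}",
    )
    return obs, truth


def _render_particles(pos_um, weights, extent_um, voxel, psf_sd):
    """Sum of Gaussian blobs sampled on the pixel grid (2D plane)."""
    nx = int(round(extent_um[0] / voxel[0]))
    ny = int(round(extent_um[1] / voxel[1]))
    img = np.zeros((ny, nx))
    xs = (np.arange(nx) + 0.5) * voxel[0]
    ys = (np.arange(ny) + 0.5) * voxel[1]
    half = 4.0 * psf_sd
    for (px, py), w in zip(pos_um, weights):
        ix0, ix1 = np.searchsorted(xs, [px - half, px + half])
        iy0, iy1 = np.searchsorted(ys, [py - half, py + half])
        if ix0 >= ix1 or iy0 >= iy1:
            continue
        gx = np.exp(-0.5 * ((xs[ix0:ix1] - px) / psf_sd) ** 2)
        gy = np.exp(-0.5 * ((ys[iy0:iy1] - py) / psf_sd) ** 2)
        img[iy0:iy1, ix0:ix1] += w * gy[:, None] * gx[None, :]
    return img


def synth_particle_stacks(
    spec: SyntheticSpec,
    flow,
    extent_um: tuple = (66.0, 66.0),
    voxel_size: tuple = (0.26, 0.26, 1.0),
    length_um: float = 13.0,
    velocity_um_s: float = 1.0,
) -> tuple[ImageStack, ImageStack]:
    """Particle-image pair advected by a known flow (2D meridional plane).

    ``flow`` is either a callable ``(x_um, y_um) -> (vx, vy)`` in um/s or a
    :class:`FlowField`, in which case the meridional plane is rendered with
    the image centre at the cell centre, ``length_um`` per non-dimensional
    length unit and ``velocity_um_s`` per non-dimensional velocity unit.
    The second stack displaces every particle by its local velocity times
    ``spec.dt``; displacements beyond the PIV search reach trigger a
    warning.
    """
    rng = np.random.default_rng(spec.seed)
    n = int(spec.particle_density * extent_um[0] * extent_um[1])
    pos = rng.uniform([0, 0], extent_um, size=(n, 2))
    weights = rng.uniform(0.5, 1.0, size=n)

    if isinstance(flow, FlowField):
        grid = flow.grid
        vz_i = RegularGridInterpolator(
            (grid.z_nodes, grid.s_nodes), flow.v_z, bounds_error=False, fill_value=0.0
        )
        vr_i = RegularGridInterpolator(
            (grid.z_nodes, grid.s_nodes), flow.v_r, bounds_error=False, fill_value=0.0
        )
        shape = grid.shape

        def velocity(p):
            z = (p[:, 0] - extent_um[0] / 2) / length_um
            r = (p[:, 1] - extent_um[1] / 2) / length_um
            zc = np.clip(z, -shape.half_length, shape.half_length)
            F = shape.F(zc)
            inside = (np.abs(z) < shape.half_length) & (np.abs(r) < F)
            s = np.where(F > 0, np.abs(r) / np.where(F > 0, F, 1.0), 0.0)
            pts = np.column_stack([zc, np.clip(s, 0, 1)])
            vx = vz_i(pts) * velocity_um_s
            vy = vr_i(pts) * np.sign(r) * velocity_um_s
            return np.column_stack([vx, vy]) * inside[:, None]

    else:

        def velocity(p):
            vx, vy = flow(p[:, 0], p[:, 1])
            return np.column_stack([np.broadcast_to(vx, p[:, 0].shape),
                                    np.broadcast_to(vy, p[:, 1].shape)])

    disp = velocity(pos) * spec.dt
    reach_px = sum(s[0] for s in DEFAULT_SEARCHES) + 1  # cumulative + sub-pixel
    if np.any(np.abs(disp[:, 0] / voxel_size[0]) > reach_px) or np.any(
        np.abs(disp[:, 1] / voxel_size[1]) > reach_px
    ):
        warnings.warn(
            "particle displacement exceeds the PIV search reach; "
            "reduce dt or the flow amplitude",
            stacklevel=2,
        )
    img1 = _render_particles(pos, weights, extent_um, voxel_size, spec.psf_sd)
    img2 = _render_particles(pos + disp, weights, extent_um, voxel_size, spec.psf_sd)
    return (
        ImageStack(img1, voxel_size, time=0.0),
        ImageStack(img2, voxel_size, time=spec.dt),
    )


# --- synthetic stand-in for the deposited flow tables -----------------------

#: physical scales used for the synthetic cells (viscosity in Poise, short
#: radius in um, velocity unit in um/s per non-dimensional velocity)
S1_SCALES = {
    "celegans": {"viscosity_poise": 10.0, "length_um": 15.0, "velocity_um_s": 0.15},
    "mouse": {"viscosity_poise": 1.0, "length_um": 35.0, "velocity_um_s": 0.0015},
}


def synth_s1_dataset(
    seed: int = 0,
    n_celegans: int = 6,
    n_mouse: int = 7,
    n_points: int = 150,
    noise_sd: float = 0.05,
) -> dict:
    """SYNTHETIC stand-in for the deposited per-cell flow-table workbook.

    The real supplementary workbook (13 sheets, Ce1..Ce6 and Mm1..Mm7, four
    columns each) is not redistributable here; this generator emulates its
    layout and physical scales from known ground-truth stress profiles so
    the full inference pipeline, including unit conversion, can be
    exercised.  C. elegans cells use the 55/13 capsule with a broad
    posterior-weighted stress profile and peak speeds ~0.1 um/s (viscosity
    10 Poise, short radius ~15 um); mouse cells use the unit sphere with a
    source-concentrated profile and peak speeds ~1.5 nm/s (1 Poise).

    Returns ``{sheet_name: (Observations, truth_spline)}``; the
    ``Observations.scale`` dict carries the physical scales, and velocities
    are stored in um/s as in the deposited tables.
    """
    rng = np.random.default_rng(seed)
    out = {}
    for i in range(n_celegans):
        hl = 55.0 / 26.0
        nodes = default_node_positions(hl)
        # broad profile, slightly source-shifted, per-cell variation
        peak = rng.uniform(1.5, 2.5)
        centre = rng.uniform(0.2, 0.6) * hl
        width = rng.uniform(0.8, 1.2) * hl
        amps = peak * np.exp(-0.5 * ((nodes - centre) / width) ** 2)
        spec = SyntheticSpec(
            shape_kind="capsule",
            stress=tuple(amps),
            noise_sd=noise_sd,
            n_points=n_points,
            seed=int(rng.integers(2**31 - 1)),
        )
        obs, truth = synth_observations(spec)
        scl = dict(S1_SCALES["celegans"])
        obs.v_z *= scl["velocity_um_s"]
        obs.v_r *= scl["velocity_um_s"]
        obs.scale.update(scl)
        obs.label = f"Ce{i + 1}"
        out[obs.label] = (obs, truth)
    for i in range(n_mouse):
        nodes = default_node_positions(1.0)
        peak = rng.uniform(2.0, 3.0)
        centre = rng.uniform(0.55, 0.75)
        width = rng.uniform(0.2, 0.35)
        amps = peak * np.exp(-0.5 * ((nodes - centre) / width) ** 2)
        spec = SyntheticSpec(
            shape_kind="sphere",
            stress=tuple(amps),
            noise_sd=noise_sd,
            n_points=n_points,
            seed=int(rng.integers(2**31 - 1)),
        )
        obs, truth = synth_observations(spec)
        scl = dict(S1_SCALES["mouse"])
        obs.v_z *= scl["velocity_um_s"]
        obs.v_r *= scl["velocity_um_s"]
        obs.scale.update(scl)
        obs.label = f"Mm{i + 1}"
        out[obs.label] = (obs, truth)
    return out
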
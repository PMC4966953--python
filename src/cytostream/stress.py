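"""Cortical shear-stress distribution parametrized by a clamped cubic B-spline.

The tangential stress profile tau(z) along the source-drain axis is described
by ``N_nodes`` free amplitudes Theta = (tau_1, ..., tau_7 by default), one per
interior node position ``nz_i``.  Three additional zero-amplitude nodes are
pinned at each pole (z = -R and z = +R, where R is half the source-drain
distance), the standard clamped-cubic construction that forces tau and its
slope to vanish exactly at both poles.  Amplitudes act as B-spline control
points, so tau is linear in Theta and non-negative amplitudes guarantee a
non-negative profile (convex-hull property).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import quad
from scipy.interpolate import BSpline

from .geometry import BoundaryShape, surface_element

__all__ = [
    "StressSpline",
    "evaluate_stress",
    "total_stress",
    "normalize_total",
    "fit_amplitudes",
    "default_node_positions",
]

N_NODES_DEFAULT = 7
DEGREE_DEFAULT = 3


def default_node_positions(r_half: float, n_nodes: int = N_NODES_DEFAULT) -> np.ndarray:
    """Uniform interior node layout on (-R, R)."""
    return np.linspace(-r_half, r_half, n_nodes + 2)[1:-1]


def _knots(node_z: np.ndarray, r_half: float, degree: int) -> np.ndarray:
    """Clamped knot vector by knot averaging over the extended node sites.

    The sites are the pole position repeated ``degree`` times on each side
    plus the interior nodes; interior knots are 3-point running means of the
    sites (Greville-style averaging), giving a strictly valid clamped vector
    for arbitrary node layouts.
    """
    sites = np.concatenate(
        [np.full(degree, -r_half), node_z, np.full(degree, r_half)]
    )
    ncoef = sites.size
    n_interior = ncoef - degree - 1
    interior = np.array(
        [sites[j : j + degree].mean() for j in range(1, n_interior + 1)]
    )
    return np.concatenate(
        [np.full(degree + 1, -r_half), interior, np.full(degree + 1, r_half)]
    )


@dataclass
class StressSpline:
    """Parameter vector Theta with its evaluable B-spline representation."""

    amplitudes: np.ndarray
    node_z: np.ndarray = None
    r_half: float = 1.0
    degree: int = DEGREE_DEFAULT
    _bspline: BSpline = field(init=False, repr=False, default=None)

    def __post_init__(self):
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if self.node_z is None:
            self.node_z = default_node_positions(self.r_half, self.amplitudes.size)
        self.node_z = np.asarray(self.node_z, dtype=float)
        if self.amplitudes.size != self.node_z.size:
            raise ValueError("amplitudes and node_z must have the same length")
        if np.any(np.abs(self.node_z) >= self.r_half):
            raise ValueError("interior nodes must lie strictly inside (-R, R)")
        t = _knots(self.node_z, self.r_half, self.degree)
        c = np.concatenate(
            [np.zeros(self.degree), self.amplitudes, np.zeros(self.degree)]
        )
        self._bspline = BSpline(t, c, self.degree, extrapolate=False)

    @property
    def n_nodes(self) -> int:
        return self.amplitudes.size

    def __call__(self, z) -> np.ndarray:
        return evaluate_stress(self, z)

    def with_amplitudes(self, amplitudes) -> "StressSpline":
        return StressSpline(amplitudes, self.node_z.copy(), self.r_half, self.degree)

    # -- plain-text round trip ------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "node_z": self.node_z.tolist(),
            "tau": self.amplitudes.tolist(),
            "r_half": self.r_half,
            "degree": self.degree,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StressSpline":
        return cls(
            np.asarray(d["tau"], dtype=float),
            np.asarray(d["node_z"], dtype=float),
            float(d["r_half"]),
            int(d.get("degree", DEGREE_DEFAULT)),
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "StressSpline":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def evaluate_stress(spline: StressSpline, z) -> np.ndarray:
    """Evaluate tau(z); exact zero at both poles, error outside [-R, R]."""
    z = np.asarray(z, dtype=float)
    if np.any(z < -spline.r_half) or np.any(z > spline.r_half):
        raise ValueError("z outside the stress spline domain [-R, R]")
    out = spline._bspline(z)
    # clamped construction: value at the poles is identically zero
    return np.where(np.abs(z) >= spline.r_half, 0.0, out)


def basis_matrix(node_z, r_half: float, z, degree: int = DEGREE_DEFAULT) -> np.ndarray:
    """Matrix B with ``B[i, m] = basis_i(z_m)``: tau(z) = Theta @ B."""
    node_z = np.asarray(node_z, dtype=float)
    n = node_z.size
    rows = []
    for i in range(n):
        e = np.zeros(n)
        e[i] = 1.0
        rows.append(evaluate_stress(StressSpline(e, node_z, r_half, degree), z))
    return np.vstack(rows)


def fit_amplitudes(
    target, node_z, r_half: float, degree: int = DEGREE_DEFAULT, n_fit: int = 201
) -> StressSpline:
    """Least-squares fit of the amplitudes to a target profile tau(z).

    ``target`` is a callable evaluated on a dense uniform grid strictly
    inside (-R, R).
    """
    z = np.linspace(-r_half, r_half, n_fit)
    B = basis_matrix(node_z, r_half, z, degree)
    y = np.asarray(target(z), dtype=float)
    theta, *_ = np.linalg.lstsq(B.T, y, rcond=None)
    return StressSpline(theta, np.asarray(node_z, dtype=float), r_half, degree)


def total_stress(spline: StressSpline, shape: BoundaryShape) -> float:
    """Surface integral of tau over the axisymmetric boundary.

    ``integral tau(z) dA`` with ``dA = 2 pi F sqrt(1 + F'^2) dz``, by
    adaptive quadrature with breakpoints at the spline knots and the
    cap-cylinder junctions.
    """
    hl = shape.half_length
    pts = sorted(
        {float(t) for t in spline._bspline.t if -hl < t < hl}
        | ({hl - shape.short_radius, shape.short_radius - hl} if shape.kind == "capsule" else set())
    )
    pts = [p for p in pts if -hl < p < hl]

    def integrand(z):
        return evaluate_stress(spline, np.clip(z, -spline.r_half, spline.r_half)) * (
            2.0 * np.pi * surface_element(shape, z)
        )

    val, _ = quad(integrand, -hl, hl, points=pts or None, limit=200)
    return float(val)


def total_stress_axial(spline: StressSpline) -> float:
    """Axial line integral ``integral tau(z) dz`` (alternative normalization)."""
    val, _ = quad(
        lambda z: float(evaluate_stress(spline, z)),
        -spline.r_half,
        spline.r_half,
        limit=200,
    )
    return float(val)


def normalize_total(
    spline: StressSpline,
    shape: BoundaryShape,
    target: float = 1.5,
    mode: str = "surface",
) -> StressSpline:
    """Rescale the amplitudes so the total stress equals ``target``.

    ``mode`` selects the surface integral (default) or the axial line
    integral as the definition of "total".  Pure scaling: the profile shape
    is preserved.
    """
    if mode == "surface":
        tot = total_stress(spline, shape)
    elif mode == "axial":
        tot = total_stress_axial(spline)
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    if tot <= 0:
        raise ValueError(f"total stress must be positive to normalize, got {tot}")
    return spline.with_amplitudes(spline.amplitudes * (target / tot))
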
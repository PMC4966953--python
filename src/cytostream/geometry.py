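"""Axisymmetric cell boundaries and boundary-fitted curvilinear grids.

The cell is a solid of revolution around the source-drain axis ``z`` with
meridional outline ``r = F(z)``.  Two idealized outlines are supported:

* a sphere of radius ``a`` (mouse oocyte, non-dimensional ``a = 1``), and
* a capsule -- a cylinder of radius ``a`` capped by two hemispheres of the
  same radius (C. elegans embryo, long axis ``55/13`` in units of the short
  radius).

The interior is mapped onto a rectangle by the boundary-fitted coordinate
``s = r / F(z)`` with ``s = 0`` on the symmetry axis and ``s = 1`` on the
boundary.  The metric terms of that transformation,

    S_r  = 1/F(z)
    S_z  = -(s/F) dF/dz
    S_zz = (s/F) * (2 (dF/dz)^2 / F - d2F/dz^2)
    S_rr = 0

connect derivatives in the physical ``(z, r)`` frame to derivatives on the
rectangular ``(z, s)`` grid and are what the flow solver consumes.

Conventions: the source pole sits at ``z = +half_length`` and the drain pole
at ``z = -half_length``.  Experimental tables index positions by the distance
from the source pole; :func:`centered_from_source_distance` /
:func:`source_distance_from_centered` convert between the two frames.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Literal

import numpy as np
import pandas as pd

__all__ = [
    "BoundaryShape",
    "CurvilinearGrid",
    "make_sphere",
    "make_capsule",
    "build_grid",
    "surface_curvature_radius",
    "surface_element",
    "centered_from_source_distance",
    "source_distance_from_centered",
]


@dataclass(frozen=True)
class BoundaryShape:
    """Axisymmetric outline ``r = F(z)`` with analytic derivatives.

    ``F`` is strictly positive on the open interval
    ``(-half_length, half_length)`` and vanishes at the poles.  For the
    capsule, ``dF`` is continuous across the cap-cylinder junction (tangency)
    while ``d2F`` jumps; the stored value at the junction is the cap-side
    one-sided limit.
    """

    kind: Literal["sphere", "capsule"]
    short_radius: float
    half_length: float
    F: Callable[[np.ndarray], np.ndarray]
    dF: Callable[[np.ndarray], np.ndarray]
    d2F: Callable[[np.ndarray], np.ndarray]

    @property
    def long_axis(self) -> float:
        return 2.0 * self.half_length


def make_sphere(radius: float = 1.0) -> BoundaryShape:
    """Spherical outline ``F(z) = sqrt(radius^2 - z^2)`` on ``[-radius, radius]``."""
    if radius <= 0:
        raise ValueError(f"radius must be positive, got {radius}")
    a2 = radius * radius

    def F(z):
        z = np.asarray(z, dtype=float)
        return np.sqrt(np.maximum(a2 - z * z, 0.0))

    def dF(z):
        z = np.asarray(z, dtype=float)
        f = np.sqrt(np.maximum(a2 - z * z, 0.0))
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(f > 0, -z / np.where(f > 0, f, 1.0), -np.sign(z) * np.inf)

    def d2F(z):
        z = np.asarray(z, dtype=float)
        f = np.sqrt(np.maximum(a2 - z * z, 0.0))
        with np.errstate(divide="ignore"):
            return np.where(f > 0, -a2 / np.where(f > 0, f, 1.0) ** 3, -np.inf)

    return BoundaryShape("sphere", float(radius), float(radius), F, dF, d2F)


def make_capsule(short_radius: float, long_axis: float) -> BoundaryShape:
    """Cylinder of radius ``short_radius`` with hemispherical caps.

    ``long_axis`` is the total pole-to-pole extent; the cylindrical section
    has length ``long_axis - 2 * short_radius`` (zero gives a sphere).
    """
    if short_radius <= 0:
        raise ValueError(f"short_radius must be positive, got {short_radius}")
    if long_axis < 2 * short_radius:
        raise ValueError(
            f"long_axis ({long_axis}) must be >= 2*short_radius ({2 * short_radius})"
        )
    a = float(short_radius)
    a2 = a * a
    hl = float(long_axis) / 2.0
    zj = hl - a  # cap-cylinder junction distance from center

    def _cap_excess(z):
        # distance into the cap, zero on the cylindrical section
        return np.maximum(np.abs(np.asarray(z, dtype=float)) - zj, 0.0)

    def F(z):
        e = _cap_excess(z)
        return np.sqrt(np.maximum(a2 - e * e, 0.0))

    def dF(z):
        z = np.asarray(z, dtype=float)
        e = _cap_excess(z)
        f = np.sqrt(np.maximum(a2 - e * e, 0.0))
        with np.errstate(divide="ignore", invalid="ignore"):
            slope = np.where(f > 0, -e / np.where(f > 0, f, 1.0), -np.inf)
        return np.where(z >= 0, slope, -slope) * np.where(e > 0, 1.0, 0.0)

    def d2F(z):
        e = _cap_excess(z)
        f = np.sqrt(np.maximum(a2 - e * e, 0.0))
        with np.errstate(divide="ignore"):
            cap = np.where(f > 0, -a2 / np.where(f > 0, f, 1.0) ** 3, -np.inf)
        # cap-side one-sided value at the junction node, zero strictly inside
        # the cylindrical section
        return np.where(e > 0, cap, np.where(np.abs(z) >= zj, cap, 0.0))

    return BoundaryShape("capsule", a, hl, F, dF, d2F)


def surface_curvature_radius(shape: BoundaryShape, z) -> np.ndarray:
    """Meridional curvature radius of the outline at axial position ``z``.

    ``R = (1 + F'^2)^{3/2} / |F''|``; straight (cylindrical) segments return
    ``+inf`` so the wall term ``2 v_t / R`` vanishes there.  ``z`` must lie
    strictly between the poles.
    """
    z = np.asarray(z, dtype=float)
    if np.any(np.abs(z) >= shape.half_length):
        raise ValueError("curvature radius is undefined at the poles")
    d1 = shape.dF(z)
    d2 = shape.d2F(z)
    with np.errstate(divide="ignore"):
        R = np.where(d2 != 0.0, (1.0 + d1 * d1) ** 1.5 / np.abs(d2), np.inf)
    return R


def surface_element(shape: BoundaryShape, z) -> np.ndarray:
    """Arc-length weighted radius ``F * sqrt(1 + F'^2)`` of the outline.

    This is the factor turning an axial integral into a surface integral:
    ``dA = 2*pi * surface_element(z) dz``.  Computed as
    ``sqrt(F^2 + (F F')^2)`` so the pole limit (where ``F' -> inf`` but
    ``F F'`` stays finite) is well behaved; for spherical caps it equals the
    cap radius identically.
    """
    z = np.asarray(z, dtype=float)
    eps = 1e-12 * max(shape.half_length, 1.0)
    zc = np.clip(z, -shape.half_length + eps, shape.half_length - eps)
    f = shape.F(zc)
    ffp = f * shape.dF(zc)
    return np.sqrt(f * f + ffp * ffp)


def centered_from_source_distance(d, half_length: float) -> np.ndarray:
    """Convert distance-from-source-pole coordinates to centered ``z``.

    ``d = 0`` is the source pole (``z = +half_length``); ``d = 2*half_length``
    is the drain pole (``z = -half_length``).
    """
    return half_length - np.asarray(d, dtype=float)


def source_distance_from_centered(z, half_length: float) -> np.ndarray:
    """Inverse of :func:`centered_from_source_distance`."""
    return half_length - np.asarray(z, dtype=float)


@dataclass
class CurvilinearGrid:
    """Boundary-fitted ``(z, s)`` mesh with pre-evaluated metric terms.

    ``Nz`` and ``Ns`` are numbers of grid divisions; the node arrays have
    ``Nz + 1`` axial stations (pole to pole, uniform in ``z``) and ``Ns + 1``
    radial stations (uniform in ``s`` from the axis to the boundary).  Metric
    arrays are indexed ``[j, k]`` for station ``(z_j, s_k)``; the two pole
    columns are excluded from interior stencils (the whole column collapses
    to a point) and their metric entries are zeroed.
    """

    shape: BoundaryShape
    Nz: int
    Ns: int
    z_nodes: np.ndarray  # (Nz+1,)
    s_nodes: np.ndarray  # (Ns+1,)
    F_nodes: np.ndarray  # (Nz+1,)
    dF_nodes: np.ndarray
    d2F_nodes: np.ndarray
    S_r: np.ndarray  # (Nz+1, Ns+1)
    S_z: np.ndarray
    S_zz: np.ndarray
    S_rr: np.ndarray
    r: np.ndarray = field(repr=False, default=None)

    @property
    def hz(self) -> float:
        return float(self.z_nodes[1] - self.z_nodes[0])

    @property
    def hs(self) -> float:
        return float(self.s_nodes[1] - self.s_nodes[0])

    def r_of(self, j: int, k: int) -> float:
        """Physical radius of node ``(j, k)``: ``r = s * F(z)``."""
        return float(self.s_nodes[k] * self.F_nodes[j])

    def to_table(self) -> pd.DataFrame:
        """Tidy node table (j, k, z, s, r, S_r, S_z, S_zz) for inspection."""
        jj, kk = np.meshgrid(
            np.arange(self.Nz + 1), np.arange(self.Ns + 1), indexing="ij"
        )
        return pd.DataFrame(
            {
                "j": jj.ravel(),
                "k": kk.ravel(),
                "z": np.broadcast_to(self.z_nodes[:, None], jj.shape).ravel(),
                "s": np.broadcast_to(self.s_nodes[None, :], jj.shape).ravel(),
                "r": self.r.ravel(),
                "S_r": self.S_r.ravel(),
                "S_z": self.S_z.ravel(),
                "S_zz": self.S_zz.ravel(),
            }
        )


def build_grid(shape: BoundaryShape, Nz: int, Ns: int) -> CurvilinearGrid:
    """Build the uniform boundary-fitted grid with metric terms.

    The reference grids are 56x14 divisions for the C. elegans capsule and
    25x13 for the mouse sphere.
    """
    if Nz < 8 or Ns < 4:
        raise ValueError(f"grid too coarse: Nz={Nz} (>=8), Ns={Ns} (>=4)")
    hl = shape.half_length
    z = np.linspace(-hl, hl, Nz + 1)
    s = np.linspace(0.0, 1.0, Ns + 1)
    F = shape.F(z)
    if np.any(F[1:-1] <= 0.0):
        raise ValueError("degenerate shape: F(z) = 0 at an interior node")
    dF = shape.dF(z)
    d2F = shape.d2F(z)

    interior = np.ones_like(z, dtype=bool)
    interior[0] = interior[-1] = False  # pole columns
    Fsafe = np.where(interior, F, 1.0)
    dFi = np.where(interior, dF, 0.0)
    d2Fi = np.where(interior, d2F, 0.0)

    S_r = np.where(interior, 1.0 / Fsafe, 0.0)[:, None] * np.ones_like(s)[None, :]
    S_z = (-dFi / Fsafe)[:, None] * s[None, :]
    S_zz = ((2.0 * dFi * dFi / Fsafe - d2Fi) / Fsafe)[:, None] * s[None, :]
    S_rr = np.zeros_like(S_z)
    r = F[:, None] * s[None, :]

    return CurvilinearGrid(
        shape=shape,
        Nz=Nz,
        Ns=Ns,
        z_nodes=z,
        s_nodes=s,
        F_nodes=F,
        dF_nodes=dF,
        d2F_nodes=d2F,
        S_r=S_r,
        S_z=S_z,
        S_zz=S_zz,
        S_rr=S_rr,
        r=r,
    )
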
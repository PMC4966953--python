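"""Particle image velocimetry for 2D frames and anisotropic 3D volumes.

Displacement between an image pair is estimated in two stages per
interrogation point:

1. *Integer stage* -- the pixel-level shift ``(xi, eta, lam)`` maximizing
   the windowed cross-correlation ``R = sum_A I1(x) I2(x + shift)``, searched
   in three passes with successively smaller interrogation windows
   (33x33x1, 29x29x1, 25x25x1 voxels) and search ranges ((+-5,+-5,0),
   (+-2,+-2,+-1), (+-1,+-1,0)), each pass re-centred on the previous
   optimum.  The z ranges are kept small because axial voxels are ~4x
   coarser than lateral ones (defaults 1.0 vs 0.26 um).
2. *Sub-pixel stage* -- the gradient-based (Lucas-Kanade style) 3x3 normal
   equation system built from the windowed sums of the intensity gradients,
   solved for the fractional displacement ``(u, v, w)`` added to the integer
   shift.

Velocities are the total displacement converted per axis with the voxel
size and frame interval.  Arrays are indexed ``(z, y, x)``; displacements
are reported in ``(x, y, z)`` order to match the acquisition convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ImageStack",
    "VelocityField",
    "integer_displacement",
    "subpixel_displacement",
    "piv_field",
    "average_fields",
    "DEFAULT_WINDOWS",
    "DEFAULT_SEARCHES",
]

# (x, y, z) extents / ranges per pass
DEFAULT_WINDOWS = ((33, 33, 1), (29, 29, 1), (25, 25, 1))
DEFAULT_SEARCHES = ((5, 5, 0), (2, 2, 1), (1, 1, 0))

FLAG_VALID = 0
FLAG_FLAT = 1  # zero-variance window
FLAG_RANGE = 2  # correlation peak clipped at the search boundary
FLAG_SINGULAR = 4  # ill-conditioned sub-pixel system
FLAG_LARGE_SUBPIXEL = 8  # |sub-pixel| component above 1 voxel


@dataclass
class ImageStack:
    """Intensity volume ``I[z, y, x]`` with anisotropic voxel sizes in um.

    2D frames are volumes with a z extent of 1.  ``voxel_size`` is
    ``(dx, dy, dz)``; ``time`` is the acquisition timestamp in seconds.
    """

    intensities: np.ndarray
    voxel_size: tuple = (0.26, 0.26, 1.0)
    time: float = 0.0

    def __post_init__(self):
        arr = np.asarray(self.intensities, dtype=float)
        if arr.ndim == 2:
            arr = arr[None, :, :]
        if arr.ndim != 3:
            raise ValueError("image stack must be 2D or 3D")
        if np.any(arr < 0):
            raise ValueError("intensities must be non-negative")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel sizes must be positive")
        self.intensities = arr

    @property
    def shape_zyx(self) -> tuple:
        return self.intensities.shape

    @classmethod
    def from_tiff(cls, path, voxel_size=(0.26, 0.26, 1.0), time=0.0) -> "ImageStack":
        import tifffile

        return cls(tifffile.imread(path), voxel_size, time)

    def to_tiff(self, path) -> None:
        import tifffile

        tifffile.imwrite(path, np.asarray(self.intensities, dtype=np.float32))


class Shift(NamedTuple):
    x: int
    y: int
    z: int


def _window_slices(center_zyx, win_xyz):
    """Half-open slices of a window centred on a voxel (odd extents)."""
    cz, cy, cx = center_zyx
    wx, wy, wz = win_xyz
    return (
        slice(cz - wz // 2, cz + wz // 2 + 1),
        slice(cy - wy // 2, cy + wy // 2 + 1),
        slice(cx - wx // 2, cx + wx // 2 + 1),
    )


def _shift_ok(shape, sl, shift_zyx):
    for extent, s, d in zip(shape, sl, shift_zyx):
        if s.start + d < 0 or s.stop + d > extent:
            return False
    return True


def integer_displacement(
    I1: ImageStack,
    I2: ImageStack,
    center,
    windows: Sequence = DEFAULT_WINDOWS,
    searches: Sequence = DEFAULT_SEARCHES,
) -> tuple[Shift, int]:
    """Multi-pass integer voxel displacement at an interrogation centre.

    ``center`` is ``(x, y, z)`` voxel indices.  Each pass searches around
    the optimum of the previous one; ties are broken toward the smallest
    shift magnitude, then lexicographically.  Returns ``(shift, flags)``;
    the flags mark flat windows and peaks clipped at the cumulative search
    boundary (the nearest in-range shift is still returned).
    """
    a = I1.intensities
    b = I2.intensities
    if a.shape != b.shape:
        raise ValueError("image stacks must have identical shapes")
    cx, cy, cz = center
    flags = FLAG_VALID
    best = (0, 0, 0)  # (z, y, x)
    for win, rng in zip(windows, searches):
        sl = _window_slices((cz, cy, cx), win)
        for s, extent in zip(sl, a.shape):
            if s.start < 0 or s.stop > extent:
                raise ValueError(
                    f"interrogation window {win} at centre {center} leaves the stack"
                )
        w1 = a[sl]
        if w1.max() == w1.min():
            return Shift(best[2], best[1], best[0]), flags | FLAG_FLAT
        w1c = w1 - w1.mean()
        rx, ry, rz = rng
        cands = []
        for dz in range(-rz, rz + 1):
            for dy in range(-ry, ry + 1):
                for dx in range(-rx, rx + 1):
                    d = (best[0] + dz, best[1] + dy, best[2] + dx)
                    cands.append(d)
        # smallest magnitude first, then lexicographic: ties keep the earler
        cands.sort(key=lambda d: (d[0] * d[0] + d[1] * d[1] + d[2] * d[2], d))
        best_score = -np.inf
        best_cand = best
        clipped_all = True
        for d in cands:
            if not _shift_ok(a.shape, sl, d):
                continue
            clipped_all = False
            w2 = b[sl[0].start + d[0] : sl[0].stop + d[0],
                   sl[1].start + d[1] : sl[1].stop + d[1],
                   sl[2].start + d[2] : sl[2].stop + d[2]]
            # windowed product with the window means removed: insensitive to
            # slow luminance drift, reduces to the plain product for
            # zero-background particle images
            score = float(np.sum(w1c * (w2 - w2.mean())))
            if score > best_score:
                best_score = score
                best_cand = d
        if clipped_all:
            raise ValueError("no admissible shift: window leaves the stack")
        # peak on the boundary of this pass's search box -> possibly clipped
        if any(
            abs(bc - bs) == r and r > 0
            for bc, bs, r in zip(best_cand, best, (rz, ry, rx))
        ):
            flags |= FLAG_RANGE
        else:
            flags &= ~FLAG_RANGE
        best = best_cand
    return Shift(best[2], best[1], best[0]), flags


def subpixel_displacement(
    w1: np.ndarray, w2: np.ndarray, integer_shift=(0, 0, 0), cond_max: float = 1e8
) -> tuple[np.ndarray, int]:
    """Gradient-based fractional displacement between aligned windows.

    ``w1`` and ``w2`` are interrogation windows (``(z, y, x)``) already
    aligned by ``integer_shift``; the shift itself only matters for the
    caller.  Spatial gradients are central differences on the first window
    (one-sided at volume faces), the temporal gradient is the two-frame
    difference.  Solves the 3x3 normal-equation system; directions with
    negligible structure (rank-deficient system) are zeroed and flagged
    rather than amplifying noise.  Returns ``((u, v, w), flags)`` in
    ``(x, y, z)`` order.
    """
    w1 = np.asarray(w1, dtype=float)
    w2 = np.asarray(w2, dtype=float)
    if w1.ndim == 2:
        w1 = w1[None]
    if w2.ndim == 2:
        w2 = w2[None]
    if w1.shape != w2.shape:
        raise ValueError("windows must have identical shapes")
    # axes with spatial extent; a 2D frame simply has no z equation
    active = [ax for ax, axis in zip((0, 1, 2), (2, 1, 0)) if w1.shape[axis] >= 2]
    axes_zyx = (2, 1, 0)  # x, y, z order
    ft = w2 - w1
    g = np.stack(
        [np.gradient(w1, axis=axes_zyx[ax]).ravel() for ax in active]
    )
    M = g @ g.T
    rhs = -(g @ ft.ravel())
    flags = FLAG_VALID
    d = np.zeros(3)
    # scale-aware rank decision, then solve in the resolved subspace
    evals, evecs = np.linalg.eigh(M)
    emax = evals[-1]
    if emax <= 0:
        return d, FLAG_SINGULAR
    keep = evals > emax / cond_max
    if not np.all(keep):
        flags |= FLAG_SINGULAR
    inv = np.where(keep, 1.0 / np.where(keep, evals, 1.0), 0.0)
    d[active] = evecs @ (inv * (evecs.T @ rhs))
    if np.any(np.abs(d) > 1.0):
        flags |= FLAG_LARGE_SUBPIXEL
    return d, flags


@dataclass
class VelocityField:
    """PIV vectors on a regular interrogation grid.

    ``positions`` are voxel coordinates ``(x, y, z)`` of the interrogation
    centres; ``displacement`` is the total (integer + sub-pixel) shift in
    voxels per axis; ``velocity`` is in um/s
    (``displacement * voxel_size / dt`` per axis).
    """

    positions: np.ndarray  # (n, 3) in voxels
    displacement: np.ndarray  # (n, 3) in voxels
    velocity: np.ndarray  # (n, 3) in um/s
    flags: np.ndarray  # (n,)
    voxel_size: tuple = (0.26, 0.26, 1.0)
    dt: float = 1.0

    @property
    def valid(self) -> np.ndarray:
        return self.flags == FLAG_VALID

    def to_dataframe(self) -> pd.DataFrame:
        p, d, v = self.positions, self.displacement, self.velocity
        return pd.DataFrame(
            {
                "x": p[:, 0], "y": p[:, 1], "z": p[:, 2],
                "u_px": d[:, 0], "v_px": d[:, 1], "w_px": d[:, 2],
                "vx_um_s": v[:, 0], "vy_um_s": v[:, 1], "vz_um_s": v[:, 2],
                "flag": self.flags,
            }
        )


def piv_field(
    I1: ImageStack,
    I2: ImageStack,
    grid_spacing: int | None = None,
    dt: float | None = None,
    windows: Sequence = DEFAULT_WINDOWS,
    searches: Sequence = DEFAULT_SEARCHES,
) -> VelocityField:
    """Dense PIV between two stacks on a regular interrogation grid.

    ``grid_spacing`` defaults to half the final interrogation window.
    Interrogation points whose first-pass window would leave the volume are
    skipped (no padding).  ``dt`` defaults to the stacks' timestamp
    difference.  Invalid vectors are flagged, never interpolated.
    """
    if I1.intensities.shape != I2.intensities.shape:
        raise ValueError("image stacks must have identical shapes")
    if dt is None:
        dt = I2.time - I1.time
    if dt <= 0:
        raise ValueError(f"frame interval must be positive, got {dt}")
    if grid_spacing is None:
        grid_spacing = windows[-1][0] // 2
    nz, ny, nx = I1.intensities.shape
    wx, wy, wz = windows[0]
    margin_x = wx // 2 + searches[0][0]
    margin_y = wy // 2 + searches[0][1]
    margin_z = wz // 2 + max(s[2] for s in searches)
    xs = np.arange(margin_x, nx - margin_x, grid_spacing, dtype=int)
    ys = np.arange(margin_y, ny - margin_y, grid_spacing, dtype=int)
    zs = (
        np.arange(margin_z, nz - margin_z, max(grid_spacing // 4, 1), dtype=int)
        if nz > 1
        else np.array([0])
    )
    positions, disps, flags_out = [], [], []
    final_win = windows[-1]
    for cz in zs:
        for cy in ys:
            for cx in xs:
                shift, flags = integer_displacement(
                    I1, I2, (cx, cy, cz), windows, searches
                )
                sl = _window_slices((cz, cy, cx), final_win)
                d_zyx = (shift.z, shift.y, shift.x)
                if (flags & FLAG_FLAT) or not _shift_ok(
                    I1.intensities.shape, sl, d_zyx
                ):
                    sub = np.zeros(3)
                else:
                    w1 = I1.intensities[sl]
                    w2 = I2.intensities[
                        sl[0].start + d_zyx[0] : sl[0].stop + d_zyx[0],
                        sl[1].start + d_zyx[1] : sl[1].stop + d_zyx[1],
                        sl[2].start + d_zyx[2] : sl[2].stop + d_zyx[2],
                    ]
                    sub, sflags = subpixel_displacement(w1, w2)
                    flags |= sflags
                positions.append((cx, cy, cz))
                disps.append((shift.x + sub[0], shift.y + sub[1], shift.z + sub[2]))
                flags_out.append(flags)
    positions = np.asarray(positions, dtype=float)
    disps = np.asarray(disps, dtype=float)
    flags_out = np.asarray(flags_out, dtype=int)
    vel = disps * np.asarray(I1.voxel_size)[None, :] / dt
    return VelocityField(positions, disps, vel, flags_out, I1.voxel_size, dt)


def average_fields(fields: Sequence[VelocityField]) -> VelocityField:
    """Componentwise time average, excluding invalid vectors per position.

    All fields must share the interrogation grid.  A position with no valid
    vector in any field stays flagged.
    """
    if len(fields) == 0:
        raise ValueError("cannot average an empty list of fields")
    f0 = fields[0]
    for f in fields[1:]:
        if f.positions.shape != f0.positions.shape or not np.allclose(
            f.positions, f0.positions
        ):
            raise ValueError("velocity fields have different interrogation grids")
    disp = np.stack([f.displacement for f in fields])  # (T, n, 3)
    vel = np.stack([f.velocity for f in fields])
    valid = np.stack([f.valid for f in fields])  # (T, n)
    count = valid.sum(axis=0)
    w = valid[:, :, None].astype(float)
    with np.errstate(invalid="ignore"):
        mean_disp = np.where(
            count[:, None] > 0, (disp * w).sum(axis=0) / np.maximum(count[:, None], 1), 0.0
        )
        mean_vel = np.where(
            count[:, None] > 0, (vel * w).sum(axis=0) / np.maximum(count[:, None], 1), 0.0
        )
    flags = np.where(count > 0, FLAG_VALID, FLAG_FLAT)
    return VelocityField(
        f0.positions.copy(), mean_disp, mean_vel, flags, f0.voxel_size, f0.dt
    )
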
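"""Mapping measured PIV points into the idealized simulation boundary.

Raw PIV points live in image coordinates.  They are repositioned into the
non-dimensional simulation frame in two steps:

* *Axial rescaling* -- the distance of each point from the source pole is
  ``f * (Z_max - Z_PIV) / (Z_max - Z_min)`` with ``f = 55/13`` for the
  C. elegans capsule and ``f = 2.0`` for the mouse sphere (``Z_max``/
  ``Z_min`` are the source/drain pole image coordinates).
* *Radial fitting* -- at each axial station, the minimum and maximum
  measured ``r`` are pinned to the lower (-F(z)) and upper (+F(z))
  simulation boundary, with points in between interpolated linearly.

Observation tables follow the deposited sheet layout with four columns
``D(Sc(z))``, ``Sc(r)``, ``v_z``, ``v_r`` (one sheet per cell, sheets named
Ce1..Ce6 and Mm1..Mm7), as CSV or multi-sheet spreadsheet.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import BoundaryShape, centered_from_source_distance, source_distance_from_centered
from .inference import Observations

__all__ = [
    "RawFlowPoints",
    "AXIAL_SCALE",
    "rescale_axial",
    "fit_radial",
    "project_cortical",
    "read_observations",
    "write_observations",
    "OBS_COLUMNS",
]

log = logging.getLogger(__name__)

AXIAL_SCALE = {"celegans": 55.0 / 13.0, "mouse": 2.0}
OBS_COLUMNS = ["D(Sc(z))", "Sc(r)", "v_z", "v_r"]


@dataclass
class RawFlowPoints:
    """PIV points in image coordinates with the pole positions."""

    z_piv: np.ndarray
    r: np.ndarray
    v_z: np.ndarray
    v_r: np.ndarray
    z_max: float  # source pole image coordinate
    z_min: float  # drain pole image coordinate

    def __post_init__(self):
        self.z_piv = np.asarray(self.z_piv, dtype=float)
        self.r = np.asarray(self.r, dtype=float)
        self.v_z = np.asarray(self.v_z, dtype=float)
        self.v_r = np.asarray(self.v_r, dtype=float)
        if not self.z_min < self.z_max:
            raise ValueError("z_min must be strictly less than z_max")
        if np.any(self.z_piv < self.z_min) or np.any(self.z_piv > self.z_max):
            raise ValueError("all Z_PIV must lie within [z_min, z_max]")


def rescale_axial(points: RawFlowPoints, species: str) -> np.ndarray:
    """Non-dimensional distance of each point from the source pole.

    Affine and order-reversing in the image coordinate: the source pole
    maps to 0 and the drain pole to the species' long-axis length.
    """
    try:
        f = AXIAL_SCALE[species]
    except KeyError:
        raise ValueError(f"unknown species {species!r}; use 'celegans' or 'mouse'")
    return f * (points.z_max - points.z_piv) / (points.z_max - points.z_min)


def fit_radial(
    points: RawFlowPoints,
    shape: BoundaryShape,
    species: str | None = None,
    n_bins: int | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Map measured radial positions onto the simulation boundary.

    Points are binned by their nearest axial station (``n_bins`` uniform
    stations, default one per distinct axial coordinate up to 56).  Within
    each bin the minimum and maximum measured ``r`` are pinned to -F(z) and
    +F(z) and the rest interpolated linearly.  A bin holding a single point
    cannot define the affine map; the point is centred (r = 0) and flagged.

    Returns ``(z_centered, r_fitted, flags)``.
    """
    if species is None:
        species = "celegans" if shape.kind == "capsule" else "mouse"
    d = rescale_axial(points, species)
    z = centered_from_source_distance(d, shape.half_length)
    if n_bins is None:
        n_bins = min(np.unique(np.round(d, 9)).size, 56)
    edges_z = np.linspace(-shape.half_length, shape.half_length, n_bins + 1)
    stations = 0.5 * (edges_z[:-1] + edges_z[1:])
    idx = np.clip(np.searchsorted(edges_z, z) - 1, 0, n_bins - 1)

    r_out = np.empty_like(z)
    flags = np.zeros(z.size, dtype=int)
    for b in np.unique(idx):
        m = idx == b
        zb = stations[b]
        Fb = float(shape.F(np.clip(zb, -shape.half_length, shape.half_length)))
        rb = points.r[m]
        lo, hi = rb.min(), rb.max()
        if lo == hi:
            r_out[m] = 0.0
            flags[m] = 1
            continue
        r_out[m] = -Fb + (rb - lo) * (2.0 * Fb) / (hi - lo)
    return z, r_out, flags


def project_cortical(
    z,
    v_z,
    v_r,
    shape: BoundaryShape,
    r_sign=None,
) -> np.ndarray:
    """Tangential velocity component along the cell boundary.

    ``z`` are centred axial positions of boundary-adjacent points; ``r_sign``
    indicates which half of the meridional section a point sits on (upper
    ``+1`` / lower ``-1``, default upper).  The projection is the inner
    product with the unit boundary tangent oriented from the source pole
    (z = +half_length) toward the drain pole, so cortical flow driven by
    positive stress projects positive.
    """
    z = np.asarray(z, dtype=float)
    v_z = np.asarray(v_z, dtype=float)
    v_r = np.asarray(v_r, dtype=float)
    sign = np.ones_like(z) if r_sign is None else np.sign(np.asarray(r_sign, dtype=float))
    sign = np.where(sign == 0, 1.0, sign)
    eps = 1e-9 * shape.half_length
    zc = np.clip(z, -shape.half_length + eps, shape.half_length - eps)
    dF = shape.dF(zc)
    norm = np.sqrt(1.0 + dF * dF)
    # upper-boundary tangent (source -> drain): (-1, -F') / sqrt(1+F'^2)
    return (-v_z - sign * dF * v_r) / norm


def cortical_profile(
    obs: Observations, shape: BoundaryShape, depth: float = 0.85, n_bins: int = 20
) -> tuple[np.ndarray, np.ndarray]:
    """Tangential speed of the outermost observation ring.

    Points with ``|r| >= depth * F(z)`` are treated as cortical; their
    velocities are projected onto the boundary tangent (source -> drain
    positive) and averaged per axial bin.  Returns ``(z_centres, v_t)`` for
    the non-empty bins.
    """
    eps = 1e-9 * shape.half_length
    zc = np.clip(obs.z, -shape.half_length + eps, shape.half_length - eps)
    F = shape.F(zc)
    m = np.abs(obs.r) >= depth * F
    if not m.any():
        raise ValueError("no cortical points at the requested depth")
    vt = project_cortical(obs.z[m], obs.v_z[m], obs.v_r[m], shape, r_sign=obs.r[m])
    edges = np.linspace(-shape.half_length, shape.half_length, n_bins + 1)
    centres = 0.5 * (edges[:-1] + edges[1:])
    idx = np.clip(np.searchsorted(edges, obs.z[m]) - 1, 0, n_bins - 1)
    z_out, vt_out = [], []
    for b in np.unique(idx):
        z_out.append(centres[b])
        vt_out.append(vt[idx == b].mean())
    return np.asarray(z_out), np.asarray(vt_out)


def _frame_to_observations(
    df: pd.DataFrame, shape: BoundaryShape, label: str, scale: dict
) -> Observations:
    missing = [c for c in OBS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"observation table is missing columns {missing}")
    numeric = df[OBS_COLUMNS].apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna().any(axis=1)
    if bad.any():
        log.warning("%s: skipped %d malformed row(s)", label or "<obs>", int(bad.sum()))
    numeric = numeric[~bad]
    d = numeric[OBS_COLUMNS[0]].to_numpy()
    r = numeric[OBS_COLUMNS[1]].to_numpy()
    z = centered_from_source_distance(d, shape.half_length)
    F_at = shape.F(np.clip(z, -shape.half_length, shape.half_length))
    tol = 1e-9 * max(shape.half_length, 1.0)
    if np.any(np.abs(r) > F_at + tol):
        worst = float((np.abs(r) - F_at).max())
        raise ValueError(
            f"{label or '<obs>'}: {int((np.abs(r) > F_at + tol).sum())} point(s) "
            f"outside the boundary (max excess {worst:.3g})"
        )
    return Observations(
        z=z,
        r=np.clip(r, -F_at, F_at),
        v_z=numeric["v_z"].to_numpy(),
        v_r=numeric["v_r"].to_numpy(),
        scale=dict(scale),
        label=label,
    )


def read_observations(
    path, shape: BoundaryShape, scale: dict | None = None, sheet: str | None = None
):
    """Read observation tables in the 4-column sheet layout.

    CSV files yield a single :class:`Observations`; spreadsheets yield a
    ``{sheet_name: Observations}`` dict (or a single object when ``sheet``
    is given).  Malformed rows are skipped with a logged warning; points
    outside the boundary are an error.
    """
    scale = scale or {}
    p = str(path)
    if p.endswith((".xlsx", ".xls")):
        sheets = pd.read_excel(p, sheet_name=sheet)
        if isinstance(sheets, pd.DataFrame):
            return _frame_to_observations(sheets, shape, sheet or "", scale)
        return {
            name: _frame_to_observations(df, shape, name, scale)
            for name, df in sheets.items()
        }
    return _frame_to_observations(pd.read_csv(p), shape, "", scale)


def observations_to_frame(obs: Observations, half_length: float) -> pd.DataFrame:
    return pd.DataFrame(
        {
            OBS_COLUMNS[0]: source_distance_from_centered(obs.z, half_length),
            OBS_COLUMNS[1]: obs.r,
            "v_z": obs.v_z,
            "v_r": obs.v_r,
        }
    )


def write_observations(obs, path, half_length: float) -> None:
    """Write observations in the 4-column layout (CSV, or multi-sheet
    spreadsheet when given a dict of labelled observations)."""
    p = str(path)
    if isinstance(obs, dict):
        if not p.endswith((".xlsx", ".xls")):
            raise ValueError("multi-cell observation sets require a spreadsheet path")
        with pd.ExcelWriter(p, engine="openpyxl") as xw:
            for name, o in obs.items():
                observations_to_frame(o, half_length).to_excel(
                    xw, sheet_name=name, index=False
                )
        return
    observations_to_frame(obs, half_length).to_csv(p, index=False)
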
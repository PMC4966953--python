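"""Steady axisymmetric Stokes flow driven by cortical shear stress.

Stream function-vorticity formulation on the boundary-fitted ``(z, s)`` grid.
With ``v_z = (1/r) dPsi/dr`` and ``v_r = -(1/r) dPsi/dz``, the steady Stokes
equations reduce to a vorticity transport equation and a Poisson equation,

    (S_r^2+S_z^2) O_ss + 2 S_z O_sz + O_zz + (S_zz + S_r/r) O_s - O/r^2 = 0
    (S_r^2+S_z^2) P_ss + 2 S_z P_sz + P_zz + (S_zz - S_r/r) P_s + r O   = 0

(``O`` = vorticity Omega, ``P`` = stream function Psi, ``r = s F(z)``),
subject to

* ``Psi = Omega = 0`` on the symmetry axis (``s = 0``) and at the poles,
* ``Psi = 0`` and ``Omega = tau/mu + 2 v_t / R`` on the cell surface
  (``s = 1``), where ``tau`` is the applied cortical shear stress, ``v_t``
  the tangential slip speed (positive from source toward drain) and ``R``
  the meridional curvature radius of the outline.

Sign conventions: the source pole sits at ``z = +half_length``, vorticity is
``Omega = dv_r/dz - dv_z/dr``, and positive stress drives cortical flow from
source to drain.  These choices reproduce the analytic interior-squirmer
pairing on the unit sphere (stress ``3 (1-z^2)^{1/2}`` yielding slip
``(1-z^2)^{1/2}``), which serves as the solver's benchmark.

The vorticity transport equation is advanced to steady state with an
explicit Euler pseudo-time iteration (per-node stable steps by default), the
Poisson equation is relaxed with red-black successive over-relaxation, and
the wall vorticity is re-coupled to the stream function every iteration with
under-relaxation (Thom-type coupling).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Union

import numpy as np
import pandas as pd

from .geometry import BoundaryShape, CurvilinearGrid, surface_curvature_radius
from .stress import StressSpline, evaluate_stress

__all__ = [
    "FlowField",
    "SolverParams",
    "SolverBlowupError",
    "solve_stokes",
    "velocity_from_stream",
    "cortical_velocity",
    "cross_section_flux",
]

StressLike = Union[StressSpline, Callable[[np.ndarray], np.ndarray]]


class SolverBlowupError(RuntimeError):
    """Raised when the pseudo-time iteration produces non-finite values."""


@dataclass
class SolverParams:
    """Numerical settings for the steady-state iteration.

    ``tol`` is the non-dimensional maximum per-iteration update below which
    (simultaneously for Psi and Omega) convergence is declared.  The pseudo
    time step is per-node stable by default (``time_step='local'``); the
    classical global diffusive bound ``c * h_min^2`` with ``c = dt_safety_global``
    is available via ``time_step='global'``.
    """

    tol: float = 1e-7
    max_iter: int = 200_000
    sor_omega: float = 1.7
    sor_sweeps: int = 1
    bc_relax: float = 0.5
    time_step: str = "local"
    dt_safety: float = 0.8
    dt_safety_global: float = 0.2
    check_every: int = 50
    raise_on_divergence: bool = False


@dataclass
class FlowField:
    """Converged (or best-effort) flow solution on a curvilinear grid."""

    grid: CurvilinearGrid
    psi: np.ndarray
    omega: np.ndarray
    v_z: np.ndarray
    v_r: np.ndarray
    mu: float
    converged: bool
    iterations: int
    residuals: dict = field(default_factory=dict)

    def to_table(self) -> pd.DataFrame:
        """Tidy export (z, r, v_z, v_r, Psi, Omega) of every grid node."""
        g = self.grid
        zz = np.broadcast_to(g.z_nodes[:, None], self.psi.shape)
        return pd.DataFrame(
            {
                "z": zz.ravel(),
                "r": g.r.ravel(),
                "v_z": self.v_z.ravel(),
                "v_r": self.v_r.ravel(),
                "Psi": self.psi.ravel(),
                "Omega": self.omega.ravel(),
            }
        )


def _stress_on(stress: StressLike, z: np.ndarray) -> np.ndarray:
    if isinstance(stress, StressSpline):
        zc = np.clip(z, -stress.r_half, stress.r_half)
        return evaluate_stress(stress, zc)
    return np.asarray(stress(z), dtype=float)


def _wall_slip(psi: np.ndarray, grid: CurvilinearGrid) -> np.ndarray:
    """Tangential slip speed at interior surface nodes from Psi.

    Second-order one-sided normal derivative of Psi at the wall;
    ``v_t = -Psi_s sqrt(1+F'^2)/F^2``, positive source -> drain.
    """
    Ns = grid.Ns
    hs = grid.hs
    psi_s = (3.0 * psi[:, Ns] - 4.0 * psi[:, Ns - 1] + psi[:, Ns - 2]) / (2.0 * hs)
    F = grid.F_nodes
    dF = grid.dF_nodes
    vt = np.zeros_like(psi_s)
    inner = slice(1, grid.Nz)
    vt[inner] = (
        -psi_s[inner]
        * np.sqrt(1.0 + dF[inner] ** 2)
        / (F[inner] * F[inner])
    )
    return vt


def solve_stokes(
    grid: CurvilinearGrid,
    stress: StressLike,
    mu: float = 1.0,
    params: SolverParams | None = None,
) -> FlowField:
    """Solve steady Stokes flow for a cortical stress distribution.

    ``stress`` is a :class:`~cytostream.stress.StressSpline` or any callable
    ``tau(z)`` defined over the grid's axial span.  Returns a
    :class:`FlowField`; ``converged`` is False when the iteration budget is
    exhausted (the residual history is attached either way).
    """
    p = params or SolverParams()
    Nz, Ns = grid.Nz, grid.Ns
    hz, hs = grid.hz, grid.hs
    z = grid.z_nodes
    s = grid.s_nodes
    r = grid.r
    Sr, Sz, Szz = grid.S_r, grid.S_z, grid.S_zz

    with np.errstate(divide="ignore"):
        invr = np.where(r > 0, 1.0 / np.where(r > 0, r, 1.0), 0.0)
    A = Sr * Sr + Sz * Sz
    B_om = Szz + Sr * invr
    B_ps = Szz - Sr * invr
    C = invr * invr

    J, K = slice(1, Nz), slice(1, Ns)
    Ai, Szi = A[J, K], Sz[J, K]
    Bomi, Bpsi, Ci, ri = B_om[J, K], B_ps[J, K], C[J, K], r[J, K]
    center_om = 2.0 * Ai / hs**2 + 2.0 / hz**2 + Ci
    center_ps = 2.0 * Ai / hs**2 + 2.0 / hz**2

    if p.time_step == "local":
        dt = p.dt_safety / center_om
    elif p.time_step == "global":
        hmin = min(hz, hs / np.sqrt(A[J, K].max()))
        dt = p.dt_safety_global * hmin * hmin
    else:
        raise ValueError(f"unknown time_step mode {p.time_step!r}")

    # wall data at interior surface nodes
    zi = z[1:Nz]
    tau_wall = _stress_on(stress, zi) / mu
    with np.errstate(divide="ignore"):
        kappa = 1.0 / surface_curvature_radius(grid.shape, zi)
    kappa = np.where(np.isfinite(kappa), kappa, 0.0)

    psi = np.zeros((Nz + 1, Ns + 1))
    omega = np.zeros_like(psi)

    jj, kk = np.meshgrid(np.arange(1, Nz), np.arange(1, Ns), indexing="ij")
    red = (jj + kk) % 2 == 0
    black = ~red

    hist_it, hist_dpsi, hist_dom = [], [], []
    d_psi = d_om = np.inf
    it = 0
    # non-finite values are detected explicitly and raised as a diagnostic;
    # silence the transient overflow warnings on the way there
    with np.errstate(over="ignore", invalid="ignore"):
      for it in range(1, p.max_iter + 1):
          # --- wall vorticity (Thom coupling, under-relaxed) ----------------
          vt = _wall_slip(psi, grid)[1:Nz]
          om_wall = tau_wall + 2.0 * vt * kappa
          prev_wall = omega[1:Nz, Ns]
          omega[1:Nz, Ns] = (1.0 - p.bc_relax) * prev_wall + p.bc_relax * om_wall

          # --- vorticity transport: explicit Euler pseudo-time step ---------
          om = omega
          lap = (
              Ai * (om[J, 2:] - 2.0 * om[J, K] + om[J, :-2]) / hs**2
              + 2.0
              * Szi
              * (om[2:, 2:] - om[2:, :-2] - om[:-2, 2:] + om[:-2, :-2])
              / (4.0 * hz * hs)
              + (om[2:, K] - 2.0 * om[J, K] + om[:-2, K]) / hz**2
              + Bomi * (om[J, 2:] - om[J, :-2]) / (2.0 * hs)
              - Ci * om[J, K]
          )
          d_omega_int = dt * lap
          omega[J, K] += d_omega_int
          d_om = max(
              np.abs(d_omega_int).max(), np.abs(omega[1:Nz, Ns] - prev_wall).max()
          )

          # --- stream function: red-black SOR sweeps ------------------------
          d_psi = 0.0
          for _ in range(p.sor_sweeps):
              for mask in (red, black):
                  ps = psi
                  rhs = (
                      Ai * (ps[J, 2:] + ps[J, :-2]) / hs**2
                      + (ps[2:, K] + ps[:-2, K]) / hz**2
                      + 2.0
                      * Szi
                      * (ps[2:, 2:] - ps[2:, :-2] - ps[:-2, 2:] + ps[:-2, :-2])
                      / (4.0 * hz * hs)
                      + Bpsi * (ps[J, 2:] - ps[J, :-2]) / (2.0 * hs)
                      + ri * omega[J, K]
                  )
                  new = rhs / center_ps
                  sub = psi[J, K]
                  upd = p.sor_omega * (new[mask] - sub[mask])
                  sub[mask] += upd
                  if upd.size:
                      d_psi = max(d_psi, np.abs(upd).max())

          if it % p.check_every == 0 or (d_psi < p.tol and d_om < p.tol):
              if not (np.isfinite(d_psi) and np.isfinite(d_om)):
                  raise SolverBlowupError(
                      f"non-finite update at iteration {it}; "
                      "reduce dt_safety or bc_relax"
                  )
              hist_it.append(it)
              hist_dpsi.append(d_psi)
              hist_dom.append(d_om)
          if d_psi < p.tol and d_om < p.tol:
              break

    if not hist_it or hist_it[-1] != it:
        hist_it.append(it)
        hist_dpsi.append(d_psi)
        hist_dom.append(d_om)
    converged = d_psi < p.tol and d_om < p.tol
    if not converged and p.raise_on_divergence:
        raise RuntimeError(
            f"Stokes iteration did not converge in {p.max_iter} iterations "
            f"(last updates: dPsi={d_psi:.3e}, dOmega={d_om:.3e})"
        )

    v_z, v_r = velocity_from_stream(psi, grid)
    return FlowField(
        grid=grid,
        psi=psi,
        omega=omega,
        v_z=v_z,
        v_r=v_r,
        mu=mu,
        converged=bool(converged),
        iterations=it,
        residuals={
            "iteration": np.asarray(hist_it),
            "d_psi": np.asarray(hist_dpsi),
            "d_omega": np.asarray(hist_dom),
        },
    )


def velocity_from_stream(
    psi: np.ndarray, grid: CurvilinearGrid
) -> tuple[np.ndarray, np.ndarray]:
    """Velocities ``v_z = (1/r) Psi_r``, ``v_r = -(1/r) Psi_z`` on the grid.

    Finite everywhere including the symmetry axis, where the limit
    ``v_z(r=0) = Psi_rr`` is evaluated by fitting ``Psi = a r^2 + b r^4`` to
    the two nearest off-axis rows; ``v_r = 0`` on the axis.  Requires
    ``Psi = 0`` on the axis.
    """
    if np.abs(psi[:, 0]).max() > 1e-12:
        raise ValueError("Psi must vanish on the symmetry axis")
    Nz, Ns = grid.Nz, grid.Ns
    hz, hs = grid.hz, grid.hs
    s = grid.s_nodes
    F = grid.F_nodes
    r = grid.r
    Sz = grid.S_z

    # d/ds: central interior, 2nd-order one-sided at the edges
    psi_s = np.empty_like(psi)
    psi_s[:, 1:-1] = (psi[:, 2:] - psi[:, :-2]) / (2.0 * hs)
    psi_s[:, 0] = (-3.0 * psi[:, 0] + 4.0 * psi[:, 1] - psi[:, 2]) / (2.0 * hs)
    psi_s[:, -1] = (3.0 * psi[:, -1] - 4.0 * psi[:, -2] + psi[:, -3]) / (2.0 * hs)
    # d/dz at constant s
    psi_z = np.empty_like(psi)
    psi_z[1:-1, :] = (psi[2:, :] - psi[:-2, :]) / (2.0 * hz)
    psi_z[0, :] = (-3.0 * psi[0, :] + 4.0 * psi[1, :] - psi[2, :]) / (2.0 * hz)
    psi_z[-1, :] = (3.0 * psi[-1, :] - 4.0 * psi[-2, :] + psi[-3, :]) / (2.0 * hz)

    with np.errstate(divide="ignore", invalid="ignore"):
        v_z = np.where(r > 0, psi_s / (np.where(r > 0, r, 1.0) * F[:, None]), 0.0)
        v_r = np.where(
            r > 0,
            -(Sz * psi_s + psi_z) / np.where(r > 0, r, 1.0),
            0.0,
        )

    # axis limit: Psi ~ a r^2 + b r^4  =>  v_z(axis) = 2 a
    inner = slice(1, Nz)
    r1 = r[inner, 1]
    r2 = r[inner, 2]
    p1 = psi[inner, 1]
    p2 = psi[inner, 2]
    den = r1**2 * r2**4 - r2**2 * r1**4
    a = np.where(den != 0, (p1 * r2**4 - p2 * r1**4) / np.where(den != 0, den, 1.0), 0.0)
    v_z[inner, 0] = 2.0 * a
    v_r[inner, 0] = 0.0
    # pole columns collapse to single points: carry the adjacent axis value
    v_z[0, :] = v_z[1, 0]
    v_z[Nz, :] = v_z[Nz - 1, 0]
    v_r[0, :] = 0.0
    v_r[Nz, :] = 0.0
    return v_z, v_r


def cortical_velocity(
    flow: FlowField, grid: CurvilinearGrid | None = None, shape: BoundaryShape | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Tangential slip-speed profile v_t(z) at the cell surface.

    Positive values indicate cortical flow from the source pole toward the
    drain pole.  Returns ``(z_nodes, v_t)`` including zero entries at the
    poles.
    """
    grid = grid or flow.grid
    vt = _wall_slip(flow.psi, grid)
    return grid.z_nodes.copy(), vt


def cross_section_flux(flow: FlowField, j: int) -> float:
    """Net volumetric flux through the cross-section at axial station ``j``.

    For the stream-function discretization the flux between axis and
    boundary is exactly ``2 pi (Psi_boundary - Psi_axis)``; with both held
    at zero, mass is conserved identically at every station.
    """
    return float(2.0 * np.pi * (flow.psi[j, flow.grid.Ns] - flow.psi[j, 0]))
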
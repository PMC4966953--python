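"""Bayesian estimation of the cortical stress amplitudes from flow data.

The stress distribution tau(z) is parametrized by the B-spline amplitude
vector Theta (one amplitude per interior node).  Estimation is by prior
sampling and importance-style posterior averaging:

1. draw ``N_Sample`` parameter vectors from a truncated-Gaussian prior
   (independent per node, common SD, restricted to positive amplitudes);
2. run the forward Stokes simulation for each sample and evaluate the
   Gaussian likelihood of the observed velocities with the maximum-likelihood
   plug-in residual covariance (sigma_z^2, sigma_r^2, sigma_zr);
3. average the ``M`` samples with the highest posterior values, weighted by
   their (normalized) likelihoods -- since sampling follows the prior, the
   non-normalized posterior of a sample equals its likelihood;
4. repeat once more with the prior means re-centred on the first-round
   estimate (same SD): the standard two-round refinement.

Because Stokes flow is linear in the boundary stress, the forward map
Theta -> velocities-at-observation-points is linear; the default forward
strategy solves once per spline node (unit amplitude) and superposes, which
is exact to solver tolerance and reduces ~1e5 simulations to ``N_nodes``
solves.  A per-sample ``direct`` strategy with memoization and an optional
process pool is retained and cross-checked against superposition in tests;
its results are independent of worker count and ordering.

With the plug-in covariance the log-likelihood reduces to
``-N (1 + log 2 pi) - (N/2) log det(Sigma_hat)`` where ``N`` is the number
of observation locations.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from joblib import Parallel, delayed
from scipy.interpolate import RegularGridInterpolator
from scipy.stats import truncnorm

from .geometry import CurvilinearGrid
from .solver import SolverParams, solve_stokes
from .stress import StressSpline, default_node_positions

__all__ = [
    "PriorSpec",
    "Observations",
    "PosteriorEstimate",
    "InferenceConfig",
    "sample_prior",
    "log_likelihood",
    "estimate_posterior",
    "run_inference",
    "stress_to_physical",
    "nondimensionalize_observations",
    "prior_from_cortical_profile",
]

DET_FLOOR = 1e-24  # non-dimensional covariance determinant floor
LOG2PI = float(np.log(2.0 * np.pi))


@dataclass
class PriorSpec:
    """Independent truncated-Gaussian prior over the node amplitudes."""

    means: np.ndarray
    sd: float = 0.75
    positivity: bool = True

    def __post_init__(self):
        self.means = np.atleast_1d(np.asarray(self.means, dtype=float))
        if self.sd <= 0:
            raise ValueError(f"prior sd must be positive, got {self.sd}")


@dataclass
class Observations:
    """Velocity observations at points inside the boundary.

    Coordinates are in the centred non-dimensional frame (source pole at
    ``z = +half_length``); velocities are non-dimensional unless ``scale``
    records the physical factors used to non-dimensionalize them
    (``velocity_um_s`` per non-dimensional velocity unit, ``length_um`` per
    non-dimensional length unit, ``viscosity_poise``).
    """

    z: np.ndarray
    r: np.ndarray
    v_z: np.ndarray
    v_r: np.ndarray
    scale: dict = field(default_factory=dict)
    label: str = ""

    def __post_init__(self):
        self.z = np.asarray(self.z, dtype=float)
        self.r = np.asarray(self.r, dtype=float)
        self.v_z = np.asarray(self.v_z, dtype=float)
        self.v_r = np.asarray(self.v_r, dtype=float)
        n = self.z.size
        if not (self.r.size == self.v_z.size == self.v_r.size == n):
            raise ValueError("observation columns must have equal length")

    @property
    def n_location(self) -> int:
        return self.z.size

    @property
    def y(self) -> np.ndarray:
        """The stacked observation vector of length 2 N_location."""
        return np.concatenate([self.v_z, self.v_r])


@dataclass
class PosteriorEstimate:
    """Top-M weighted posterior summary for one estimation round."""

    theta_hat: np.ndarray
    top_samples: np.ndarray  # (M, N_nodes)
    weights: np.ndarray  # (M,), sums to 1
    loglik: np.ndarray  # (M,) log-likelihood of the top samples
    sigma_hat: tuple  # plug-in (sigma_z^2, sigma_r^2, sigma_zr) at theta_hat
    round: int
    seed: int
    n_sample: int
    m: int
    n_discarded: int = 0
    node_z: np.ndarray | None = None
    r_half: float | None = None
    history: list = field(default_factory=list)  # estimates of earlier rounds


@dataclass
class InferenceConfig:
    """Settings for :func:`run_inference`."""

    n_sample: int = 120_000
    m: int = 100
    rounds: int = 2
    seed: int = 0
    mu: float = 1.0
    forward: str = "superpose"  # or "direct"
    n_jobs: int = 1
    node_z: np.ndarray | None = None
    solver: SolverParams | None = None
    max_discard_frac: float = 0.10


def sample_prior(prior: PriorSpec, n: int, seed) -> np.ndarray:
    """Draw ``n`` amplitude vectors from the prior; reproducible given seed.

    Positive-truncated components are drawn by rejection; nodes whose
    acceptance probability falls below 1% switch to inverse-CDF sampling.
    An acceptance probability below 1e-6 for any node is an error.

    ``seed`` may be an integer or a ``numpy.random.Generator``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    means = prior.means
    k = means.size
    if not prior.positivity:
        return means[None, :] + prior.sd * rng.standard_normal((n, k))
    from scipy.stats import norm

    accept = norm.cdf(means / prior.sd)
    if np.any(accept < 1e-6):
        bad = int(np.argmin(accept))
        raise ValueError(
            f"prior mean {means[bad]:.3g} at node {bad} makes positive "
            f"truncation acceptance {accept[bad]:.2e} (< 1e-6)"
        )
    out = np.empty((n, k))
    for i in range(k):
        if accept[i] >= 0.01:
            draws = np.empty(0)
            need = n
            while need > 0:
                cand = means[i] + prior.sd * rng.standard_normal(int(need / accept[i]) + 8)
                cand = cand[cand > 0]
                draws = np.concatenate([draws, cand])
                need = n - draws.size
            out[:, i] = draws[:n]
        else:
            a = (0.0 - means[i]) / prior.sd
            out[:, i] = truncnorm.ppf(
                rng.uniform(size=n), a, np.inf, loc=means[i], scale=prior.sd
            )
    return out


def _plugin_sigma(dz: np.ndarray, dr: np.ndarray) -> tuple[float, float, float]:
    return (
        float(np.mean(dz * dz)),
        float(np.mean(dr * dr)),
        float(np.mean(dz * dr)),
    )


def log_likelihood(
    obs: Observations, sim_vz: np.ndarray, sim_vr: np.ndarray
) -> tuple[float, tuple, bool]:
    """Gaussian log-likelihood with the MLE plug-in residual covariance.

    ``sim_vz``/``sim_vr`` are the simulated velocities evaluated at the
    observation points.  Returns ``(value, (sigma_z2, sigma_r2, sigma_zr),
    degenerate)``; with the plug-in covariance the value equals
    ``-N (1 + log 2 pi) - (N/2) log det(Sigma_hat)``.  A determinant at or
    below the floor (perfect or rank-deficient fit) yields a capped value
    with ``degenerate=True``, never NaN.
    """
    dz = np.asarray(sim_vz, dtype=float) - obs.v_z
    dr = np.asarray(sim_vr, dtype=float) - obs.v_r
    n = obs.n_location
    s_z2, s_r2, s_zr = _plugin_sigma(dz, dr)
    det = s_z2 * s_r2 - s_zr * s_zr
    degenerate = not (det > DET_FLOOR)
    det = max(det, DET_FLOOR)
    value = -n * (1.0 + LOG2PI) - 0.5 * n * np.log(det)
    return float(value), (s_z2, s_r2, s_zr), degenerate


def estimate_posterior(
    samples: np.ndarray, logliks: np.ndarray, M: int = 100
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Weighted average of the M samples with the largest posterior values.

    Weights are ``exp(loglik - max)`` normalized over the top M (sampling
    followed the prior, so likelihood is the non-normalized posterior).
    Ties are broken by sample index.  Returns
    ``(theta_hat, top_samples, weights, top_logliks)``.
    """
    samples = np.asarray(samples, dtype=float)
    logliks = np.asarray(logliks, dtype=float)
    if samples.shape[0] < M:
        raise ValueError(f"need at least M={M} samples, got {samples.shape[0]}")
    order = np.argsort(-logliks, kind="stable")[:M]
    top = samples[order]
    ll = logliks[order]
    w = np.exp(ll - ll.max())
    w /= w.sum()
    return w @ top, top, w, ll


# node-basis flow solutions are reusable across observation sets on the
# same grid; keyed by (shape, grid, nodes, viscosity, tolerance)
_BASIS_FLOW_CACHE: dict = {}


def _basis_cache_key(grid, node_z, mu, solver: SolverParams):
    sh = grid.shape
    return (
        sh.kind,
        round(sh.short_radius, 12),
        round(sh.half_length, 12),
        grid.Nz,
        grid.Ns,
        tuple(np.round(node_z, 12)),
        round(mu, 12),
        solver.tol,
    )


class _ForwardModel:
    """Maps amplitude vectors to velocities at the observation points."""

    def __init__(
        self,
        grid: CurvilinearGrid,
        node_z: np.ndarray,
        obs: Observations,
        mu: float,
        solver: SolverParams | None,
        mode: str = "superpose",
        n_jobs: int = 1,
    ):
        self.grid = grid
        self.node_z = np.asarray(node_z, dtype=float)
        self.mu = mu
        self.solver = solver or SolverParams()
        self.mode = mode
        self.n_jobs = n_jobs
        self.r_half = grid.shape.half_length
        self.n_discarded = 0
        self._cache: dict[bytes, tuple[np.ndarray, np.ndarray] | None] = {}
        # observation points in (z, s)
        F_at = grid.shape.F(np.clip(obs.z, -self.r_half, self.r_half))
        if np.any(np.abs(obs.r) > F_at * (1 + 1e-9) + 1e-12):
            raise ValueError("observation points must lie inside the boundary")
        s = np.where(F_at > 0, np.abs(obs.r) / np.where(F_at > 0, F_at, 1.0), 0.0)
        self._pts = np.column_stack([obs.z, np.clip(s, 0.0, 1.0)])
        self._mirror = np.where(obs.r < 0, -1.0, 1.0)  # v_r is odd in r
        if mode == "superpose":
            self._basis = self._build_basis()
        elif mode != "direct":
            raise ValueError(f"unknown forward mode {mode!r}")

    def _interp(self, flow) -> tuple[np.ndarray, np.ndarray]:
        g = self.grid
        vz = RegularGridInterpolator(
            (g.z_nodes, g.s_nodes), flow.v_z, method="linear"
        )(self._pts)
        vr = RegularGridInterpolator(
            (g.z_nodes, g.s_nodes), flow.v_r, method="linear"
        )(self._pts)
        return vz, vr * self._mirror

    def _solve(self, theta: np.ndarray):
        spline = StressSpline(theta, self.node_z, self.r_half)
        flow = solve_stokes(self.grid, spline, mu=self.mu, params=self.solver)
        if not flow.converged:
            return None
        return self._interp(flow)

    def _build_basis(self) -> np.ndarray:
        k = self.node_z.size
        key = _basis_cache_key(self.grid, self.node_z, self.mu, self.solver)
        flows = _BASIS_FLOW_CACHE.get(key)
        if flows is None:
            flows = []
            for i in range(k):
                e = np.zeros(k)
                e[i] = 1.0
                spline = StressSpline(e, self.node_z, self.r_half)
                flow = solve_stokes(self.grid, spline, mu=self.mu, params=self.solver)
                if not flow.converged:
                    raise RuntimeError(
                        f"forward solve for basis node {i} did not converge"
                    )
                flows.append(flow)
            _BASIS_FLOW_CACHE[key] = flows
        return np.vstack(
            [np.concatenate(self._interp(f)) for f in flows]
        )  # (N_nodes, 2 N_location)

    def simulate(self, thetas: np.ndarray) -> np.ndarray:
        """Velocities at observation points for each sample.

        Returns an array ``(n_samples, 2 N_location)``; rows of NaN mark
        discarded (non-converged) samples.
        """
        thetas = np.atleast_2d(np.asarray(thetas, dtype=float))
        if self.mode == "superpose":
            return thetas @ self._basis

        def one(theta):
            key = hashlib.sha1(np.ascontiguousarray(theta).tobytes()).digest()
            if key in self._cache:
                return self._cache[key]
            res = self._solve(theta)
            self._cache[key] = res
            return res

        if self.n_jobs == 1:
            results = [one(t) for t in thetas]
        else:
            results = Parallel(n_jobs=self.n_jobs)(
                delayed(self._solve)(t) for t in thetas
            )
        out = np.full((thetas.shape[0], 2 * self._pts.shape[0]), np.nan)
        for i, res in enumerate(results):
            if res is None:
                self.n_discarded += 1
            else:
                out[i] = np.concatenate(res)
        return out


def _vectorized_loglik(
    sims: np.ndarray, y_z: np.ndarray, y_r: np.ndarray
) -> np.ndarray:
    """Plug-in log-likelihood for many samples at once (NaN rows -> -inf)."""
    n = y_z.size
    dz = sims[:, :n] - y_z[None, :]
    dr = sims[:, n:] - y_r[None, :]
    s_z2 = np.mean(dz * dz, axis=1)
    s_r2 = np.mean(dr * dr, axis=1)
    s_zr = np.mean(dz * dr, axis=1)
    det = np.maximum(s_z2 * s_r2 - s_zr * s_zr, DET_FLOOR)
    ll = -n * (1.0 + LOG2PI) - 0.5 * n * np.log(det)
    return np.where(np.isfinite(ll), ll, -np.inf)


def run_inference(
    obs: Observations,
    prior: PriorSpec,
    grid: CurvilinearGrid,
    config: InferenceConfig | None = None,
) -> PosteriorEstimate:
    """Full two-round sampling-based estimation of the stress amplitudes.

    Round 1 samples the supplied prior; round 2 re-centres the prior means
    on the round-1 estimate (same SD) and repeats.  The returned estimate is
    from the final round, with earlier rounds attached in ``history``.
    Deterministic for a fixed seed and configuration, independent of worker
    count.
    """
    cfg = config or InferenceConfig()
    node_z = (
        np.asarray(cfg.node_z, dtype=float)
        if cfg.node_z is not None
        else default_node_positions(grid.shape.half_length, prior.means.size)
    )
    if prior.means.size != node_z.size:
        raise ValueError("prior means and node positions differ in length")
    if obs.n_location < node_z.size:
        raise ValueError(
            f"need at least {node_z.size} observation points, got {obs.n_location}"
        )
    if cfg.n_sample < cfg.m:
        raise ValueError(f"n_sample ({cfg.n_sample}) must be >= M ({cfg.m})")

    fwd = _ForwardModel(
        grid, node_z, obs, cfg.mu, cfg.solver, mode=cfg.forward, n_jobs=cfg.n_jobs
    )
    rng = np.random.default_rng(cfg.seed)
    current = PriorSpec(prior.means.copy(), prior.sd, prior.positivity)
    history: list[PosteriorEstimate] = []
    est = None
    for rnd in range(1, cfg.rounds + 1):
        thetas = sample_prior(current, cfg.n_sample, rng)
        sims = fwd.simulate(thetas)
        n_bad = int(np.isnan(sims[:, 0]).sum())
        if n_bad > cfg.max_discard_frac * cfg.n_sample:
            raise RuntimeError(
                f"{n_bad}/{cfg.n_sample} forward solves discarded "
                f"(> {cfg.max_discard_frac:.0%})"
            )
        lls = _vectorized_loglik(sims, obs.v_z, obs.v_r)
        theta_hat, top, w, ll_top = estimate_posterior(thetas, lls, cfg.m)
        sim_hat = fwd.simulate(theta_hat[None, :])[0]
        n = obs.n_location
        _, sigma_hat, _ = log_likelihood(obs, sim_hat[:n], sim_hat[n:])
        est = PosteriorEstimate(
            theta_hat=theta_hat,
            top_samples=top,
            weights=w,
            loglik=ll_top,
            sigma_hat=sigma_hat,
            round=rnd,
            seed=cfg.seed,
            n_sample=cfg.n_sample,
            m=cfg.m,
            n_discarded=n_bad,
            node_z=node_z,
            r_half=grid.shape.half_length,
            history=list(history),
        )
        history.append(est)
        current = PriorSpec(theta_hat.copy(), prior.sd, prior.positivity)
    est.history = history[:-1]
    return est


def nondimensionalize_observations(obs: Observations) -> Observations:
    """Divide stored physical velocities (um/s) by the recorded velocity
    unit, leaving coordinates untouched (already non-dimensional)."""
    u = obs.scale.get("velocity_um_s")
    if not u:
        raise ValueError("observations carry no velocity_um_s scale")
    return Observations(
        z=obs.z.copy(),
        r=obs.r.copy(),
        v_z=obs.v_z / u,
        v_r=obs.v_r / u,
        scale=dict(obs.scale),
        label=obs.label,
    )


def stress_to_physical(
    tau_nd, viscosity_poise: float, length_um: float, velocity_um_s: float
) -> np.ndarray:
    """Convert non-dimensional stress to pN/um^2 (= Pa).

    The non-dimensionalization sets viscosity and the cell short radius to
    one; the physical stress scale is ``mu * U / a`` with ``mu`` the
    viscosity (1 Poise = 0.1 Pa s), ``U`` the velocity unit in um/s and
    ``a`` the short radius in um.  1 Pa = 1 pN/um^2.
    """
    mu_pa_s = 0.1 * viscosity_poise
    return np.asarray(tau_nd, dtype=float) * mu_pa_s * velocity_um_s / length_um


def prior_from_cortical_profile(
    z: Sequence[float],
    v_t: Sequence[float],
    node_z,
    r_half: float,
    stress_per_velocity: float = 3.0,
    floor: float = 0.05,
) -> PriorSpec:
    """Prior means from a measured cortical-velocity profile.

    Fits the stress spline to the tangential cortical speed, scaled by the
    stress-to-slip ratio of the spherical benchmark (3.0), and floors the
    result at a small positive amplitude so positive truncation remains
    well-behaved.  This automates the common practice of hand-fitting the
    spline to the cortical velocity of each cell.
    """
    from .stress import basis_matrix

    z = np.asarray(z, dtype=float)
    v_t = np.asarray(v_t, dtype=float)
    B = basis_matrix(node_z, r_half, z)
    theta, *_ = np.linalg.lstsq(B.T, v_t, rcond=None)
    means = np.maximum(stress_per_velocity * theta, floor)
    return PriorSpec(means)
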
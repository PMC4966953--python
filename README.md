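# cytostream

Inference of the cortical shear-stress distribution that drives
cytoplasmic streaming, from measured intracellular flow fields.

## The problem

In large cells such as the *C. elegans* one-cell embryo and the mouse
oocyte, motor activity at the cell cortex drags the entire cytoplasm into a
cell-wide circulation (cytoplasmic streaming).  The force generators sit at
the cortex, but the flow they produce reaches everywhere through the
hydrodynamics of the cytoplasm, so the *spatial distribution* of the
driving stress cannot be read off the velocity field directly.  This
package solves the inverse problem: given a flow field measured by particle
image velocimetry (PIV), estimate the tangential stress profile τ(z) along
the cell surface that best explains it.

## The method

The cytoplasm is modelled as a Newtonian Stokes fluid in an axisymmetric
cell (a sphere for the oocyte, a 55/13 capsule for the embryo; viscosity
and short radius non-dimensionalized to 1).  Streaming diverges from a
**source pole** (z = +R) and converges into a **drain pole** (z = −R).

* **Forward model** — stream function–vorticity formulation of steady
  axisymmetric Stokes flow on a boundary-fitted (z, s = r/F(z)) grid, with
  wall condition Ω = τ/μ + 2 v_t/R linking wall vorticity to the applied
  cortical stress τ and the slip speed v_t.  Euler pseudo-time relaxation
  for the vorticity transport equation, red–black SOR for the stream
  function Poisson equation.
* **Stress parametrization** — τ(z) is a clamped cubic B-spline over
  Θ = (τ₁ … τ₇), seven free amplitudes at interior nodes with triple zero
  nodes at both poles (τ = 0, τ′ = 0 there).
* **Estimation** — Bayesian data assimilation: draw N_Sample parameter
  vectors from a positive truncated-Gaussian prior (SD 0.75), forward
  simulate each, score against the observations with a bivariate Gaussian
  likelihood using the maximum-likelihood plug-in residual covariance
  (σ̂_z², σ̂_r², σ̂_zr), and average the top M = 100 samples weighted by
  their posterior values; a second round re-centres the prior on the
  first-round estimate.  Because Stokes flow is linear in τ, the default
  forward strategy superposes seven precomputed node-basis solutions,
  making ~10⁵ samples cheap.
* **Pressure analysis** — the pressure field is reconstructed by line
  integration of ∇p = μ∇²**v** from the drain pole, and the pressure
  gradient at the source end compares how focused vs broad stress profiles
  position intracellular cargo (e.g. the meiotic spindle).
* **PIV** — multi-pass windowed cross-correlation (33→29→25 px windows)
  with a gradient-based (Lucas–Kanade) sub-pixel solve, for 2D frames and
  anisotropic 3D volumes (0.26 × 0.26 × 1.0 µm voxels).

The analytic anchor is the interior squirmer: on the unit sphere the
stress τ₀(z) = 3·(1−z²)^½ produces exactly the cortical slip
u₀(z) = (1−z²)^½.

## Worked example

Solve the benchmark and re-estimate its stress from the flow it generates:

```python
import numpy as np
from cytostream import (build_grid, solve_stokes, cortical_velocity,
                        run_inference, PriorSpec, InferenceConfig, Observations)
from cytostream.synthetic import benchmark_case

shape, spline, u0 = benchmark_case()          # unit sphere, tau0 fitted spline
grid = build_grid(shape, 25, 13)
flow = solve_stokes(grid, spline)
print("converged:", flow.converged, "iterations:", flow.iterations)
z, vt = cortical_velocity(flow)
print("peak cortical slip:", round(float(vt.max()), 3))

zz = np.broadcast_to(grid.z_nodes[:, None], flow.v_z.shape)
mask = (grid.r > 0) & (np.abs(zz) < 0.95)
obs = Observations(zz[mask], grid.r[mask], flow.v_z[mask], flow.v_r[mask])
est = run_inference(obs, PriorSpec(np.full(7, 1.5), 0.75), grid,
                    InferenceConfig(n_sample=5000, m=100, rounds=2, seed=0))
print("estimated amplitudes:", np.round(est.theta_hat, 2))
```

prints

```
converged: True iterations: 832
peak cortical slip: 0.953
estimated amplitudes: [2.95 2.22 3.86 1.82 3.44 2.15 3.26]
```

The peak slip is within 5% of the analytic value 1.0, and the estimated
amplitudes track the generating spline (amplitudes ≈ 2.1–3.3, the spline
fit of τ₀); individual amplitudes wobble because distinct amplitude vectors
produce nearly identical flow fields, while the implied stress *curve* is
recovered to within 10% of its peak.

A command-line interface covers the same pipeline for shell use:

```bash
cytostream synth benchmark --out work/
cytostream simulate --stress work/benchmark_stress.json --grid 25x13 --out work/flow.csv
cytostream pressure --flow work/flow.csv --out work/pressure.csv
cytostream infer --obs cell.csv --shape capsule --grid 56x14 --nsample 120000 --out est.json
```

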
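# Methods

## Model and assumptions

Cytoplasmic streaming is modelled as steady, inertialess, incompressible
Newtonian flow (Reynolds numbers for these cells are of order 10⁻¹²) inside
a rigid axisymmetric boundary, driven solely by a tangential stress τ(z)
exerted on the fluid at the cell surface.  Forces generated in the bulk
cytoplasm are neglected, consistent with the cortical localization of the
actomyosin machinery in both systems this package targets.  Axisymmetry
about the source–drain axis reduces the problem to the meridional plane.

All variables are non-dimensional: the cell short radius and the viscosity
are 1.  The source pole — the point the cortical stress diverges from — is
at z = +R and the drain pole at z = −R, where R is half the pole-to-pole
distance (R = 1 for the sphere, R = 55/26 for the capsule in units of the
short radius).  Positive τ drives cortical flow from source to drain;
continuity returns the core flow from drain to source.  Measured data
indexed by distance-from-source D convert to this frame by z = R − D.

## Forward solver

With the Stokes stream function (v_z = Ψ_r/r, v_r = −Ψ_z/r) and the
meridional vorticity Ω = ∂v_r/∂z − ∂v_z/∂r, the steady Stokes equations
become a vorticity transport equation and a Poisson equation for Ψ.  Both
are discretized with second-order central differences (including the mixed
∂²/∂s∂z term) on the boundary-fitted rectangle (z, s = r/F(z)), using the
metric terms S_r = 1/F, S_z = −sF′/F, S_zz = (s/F)(2F′²/F − F″), S_rr = 0.

Boundary conditions: Ψ = Ω = 0 on the symmetry axis and at the pole
columns; Ψ = 0 and Ω = τ/μ + 2 v_t/R_c at the surface, where v_t is the
tangential slip (second-order one-sided normal difference of Ψ, refreshed
every iteration with under-relaxation 0.5 — Thom-type coupling) and R_c the
meridional curvature radius of the outline (∞ on the cylindrical section,
where the term vanishes).  The sign of the τ term is fixed by requiring the
solver to reproduce the analytic interior-squirmer solution
Ψ = ½ r²(1 − z² − r²), for which the surface pairing is
τ = 3 sin θ ↔ v_t = sin θ and the wall vorticity is 5 sin θ.

Iteration: explicit Euler pseudo-time steps on the vorticity equation and
one red–black SOR sweep (relaxation factor 1.7) on the Poisson equation per
outer iteration.  The pseudo-time step is per-node (0.8 divided by the
local diagonal stencil weight).  A global diffusive step c·h²_min (c = 0.2)
is available as an option, but the metric coefficient S_r² + S_z² grows
near the poles and makes the global bound ~10⁻⁵, so local stepping is the
default; for a linear steady problem both converge to the same fixed point.
Convergence requires the maximum per-iteration update of both Ψ and Ω to
fall below 10⁻⁷ simultaneously; non-convergence within the iteration budget
(2·10⁵) is reported on the returned field, and non-finite values raise a
diagnostic error suggesting smaller steps.

Grids are uniform in z (pole to pole) and s ∈ [0, 1], with the reference
division counts as defaults: 25×13 (sphere/oocyte) and 56×14
(capsule/embryo).  The pole columns collapse to points and are excluded
from interior stencils; velocities there are carried from the adjacent axis
value.  Mass conservation is exact by construction: the flux through any
cross-section equals 2π(Ψ_wall − Ψ_axis) = 0.

Verification: on the benchmark, the amplitude coefficient c (stress
c·(1−z²)^½ producing slip (1−z²)^½) evaluates to 3.12 at 25×13, 3.03 at
50×26 and 3.01 at 100×52 against the analytic 3; the interior stream
function matches the closed form to 1.4% L∞ at 25×13.

## Stress parametrization

τ(z) is a clamped cubic B-spline: seven free control amplitudes
Θ = (τ₁ … τ₇) at interior nodes (uniform in (−R, R) by default,
configurable per cell) plus three zero amplitudes pinned at each pole.  The
knot vector is built by 3-point running averages of the extended node sites
(standard knot averaging), which stays valid for arbitrary node layouts.
Consequences used throughout: τ(±R) = 0 and τ′(±R) = 0 exactly; evaluation
is linear in Θ; non-negative amplitudes give a non-negative profile
(convex-hull property).

The zero-slope clamp means the spline cannot follow targets with a vertical
tangent at the poles: the best fit to 3(1−z²)^½ deviates < 5% of peak for
|z| ≤ 0.4 but up to ~34% near |z| ≈ 0.9.  This is a property of the
parametrization, not the fit (an unclamped spline on the same knots fits to
< 2%).

"Total stress" for the normalized pressure comparison is the surface
integral ∫ τ dA (dA = 2πF√(1+F′²) dz) by adaptive quadrature; an axial line
integral ∫ τ dz is offered as an alternative since either reading of
"total" is defensible.  The normalization target is 1.5.

## Estimation

Priors are independent Gaussians per amplitude, truncated to (0, ∞)
(stress acts source→drain by assumption), common SD 0.75.  For
embryo-style data the prior means come from a least-squares fit of the
spline to the measured cortical tangential velocity scaled by the spherical
stress-to-slip ratio 3.0 and floored at 0.05 — an automated version of
hand-fitting the spline to the cortical profile.  For oocyte-style data a
fixed prior is used: mean 2.5 at nodes in the source-proximal third, 0.5
elsewhere.  Sampling is by rejection, switching to inverse-CDF below 1%
acceptance; acceptance below 10⁻⁶ is an error.

The likelihood of an amplitude vector is the product over observation
points of bivariate Gaussians for (v_z, v_r) with the MLE plug-in
covariance computed from the residuals, which collapses to
−N(1 + log 2π) − (N/2) log det Σ̂.  The determinant is floored at 10⁻²⁴
(flagged) because the expression is unbounded for a perfect fit.
Simulated velocities are bilinearly interpolated to the observation points
in (z, s); points below the axis use the odd symmetry of v_r.

The estimate is the weighted mean of the M = 100 samples with the largest
posterior values (weights ∝ exp(loglik − max), ties broken by sample
index); since sampling follows the prior, a sample's likelihood is its
non-normalized posterior.  Two rounds are run, the second with prior means
re-centred on the first-round estimate and the same SD.

Forward strategy: Stokes flow is linear in τ, so the map Θ → velocities is
linear.  The default precomputes the seven node-basis flow solutions
(cached per grid/nodes/viscosity) and evaluates each sample as a 7-vector
contraction — exact to solver tolerance and verified in tests against the
per-sample "direct" strategy, which remains available with memoization and
an optional joblib pool (results independent of worker count and order).
Non-converged forward solves discard the sample; more than 10% discards is
a hard error.

Identifiability: the forward map strongly smooths amplitude oscillations,
so individual node amplitudes carry substantial posterior spread (node
RMSE ~15–18% of peak at N_Sample = 10⁴ with 5% observation noise) while
the implied stress curve is recovered much more tightly (RMS ~9% of peak at
the nodes for the noiseless benchmark with N_Sample = 5·10³).  The reference
protocol uses N_Sample ≈ 1.2·10⁵; the test suite and examples use 5·10²–10⁴ to
keep runs to seconds, which is the dominant source of their residual error.

Physical units enter only at reporting: stress in pN/µm² (= Pa) is
τ · μ·U/a with μ the viscosity (1 Poise = 0.1 Pa·s), U the velocity unit in
µm/s and a the short radius in µm.  Defaults mirror the measured scales:
embryo μ ≈ 10 P, a ≈ 15 µm, speeds ~0.1 µm/s; oocyte μ ≈ 1 P, speeds
~1 nm/s.

## Pressure reconstruction

∇p = μ∇²**v**, evaluated through the identity ∇²**v** = −∇×(Ω e_φ), i.e.
∂p/∂z = −(1/r)∂(rΩ)/∂r and ∂p/∂r = ∂Ω/∂z.  The radial momentum component
includes the −v_r/r² term of the axisymmetric vector Laplacian, without
which the gradient field is not curl-free even analytically.  Evaluating
the gradient from the solved vorticity rather than by stacking second
differences of reconstructed velocities avoids amplifying the axis-row
discretization kink; the two forms are algebraically identical for
incompressible axisymmetric flow.  Differencing is first-order one-sided by
default with a second-order central option for validation.

The field is line-integrated from the drain pole (reference p = 0): along
the axis, then radially at each station.  A loop-closure residual —
the mismatch against an independent path (axis to the mid column, radial
leg there, then along constant-s rows) over the stations where the outline
radius is at least half the short radius — is attached as a quality metric;
it is ~3.6% of the pressure range at 25×13 and shrinks roughly linearly
with the mesh under the first-order scheme (quadratically under central).
The near-pole region is excluded from the metric because the mapping
degenerates there.

"Pressure gradient at the source end" is the least-squares slope of p(z)
on the axis over the 10% of the axial extent nearest the source pole
(window configurable; at least 3 nodes).  Group comparisons use Welch's
unequal-variance t test; two zero-variance groups are flagged as
degenerate.

## Particle image velocimetry

Integer displacements maximize the windowed product of the two frames with
the window means removed — insensitive to slow luminance drift and
identical to the plain product for zero-background particle images — in
three passes with windows (33, 33, 1), (29, 29, 1), (25, 25, 1) voxels and
search ranges (±5, ±5, 0), (±2, ±2, ±1), (±1, ±1, 0), each re-centred on
the previous optimum (cumulative reach ±8 px laterally).  Axial ranges are
small because axial voxels (1.0 µm) are ~4× coarser than lateral ones
(0.26 µm).  Ties prefer the smallest shift, then lexicographic order; flat
windows and boundary-clipped peaks are flagged.

Sub-pixel refinement solves the 3×3 Lucas–Kanade normal equations built
from central spatial differences of the first window and the two-frame
temporal difference.  The system is solved in the eigenspace with
eigenvalues above 10⁻⁸ of the largest; unresolved directions (aperture
problem, or the absent axial axis of 2D frames) are zeroed, flagged only
when genuinely rank-deficient for the input dimensionality.  Sub-pixel
components above one voxel are flagged as suspect.

Interrogation centres form a regular grid (spacing: half the final window
by default); windows that would leave the volume are skipped, never padded,
and invalid vectors are flagged, never interpolated.  Velocities are
displacement × per-axis voxel size / frame interval.  Time averaging over
a sequence of fields excludes invalid vectors per position.

## Data preparation

Measured PIV points are mapped into the idealized boundary exactly as the
estimation expects: axial positions are rescaled affinely so the poles map
to 0 and 55/13 (capsule) or 2.0 (sphere) in distance-from-source units;
radially, the minimum and maximum measured r per axial bin (nearest-station
binning) are pinned to ∓F(z) with linear interpolation between, single-point
bins centred and flagged.  Observation tables round-trip through the
four-column layout D(Sc(z)), Sc(r), v_z, v_r as CSV or multi-sheet
spreadsheets (sheets Ce1..Ce6, Mm1..Mm7); malformed rows are skipped with a
logged count, and points outside the boundary are an error.  Cortical
profiles take the outermost observation ring (|r| ≥ 0.85·F(z) by default)
projected onto the boundary tangent, source→drain positive.

## Synthetic data

The fixtures module generates every test input from known ground truth:
velocity observations (forward solve under a known Θ*, stratified-random
interior positions covering all axial stations, i.i.d. Gaussian noise with
SD a fraction — default 5% — of the maximum speed), particle-image pairs
(uniform random Gaussian-blob particles of 0.5 µm PSF advected by a known
flow on 0.26 µm pixels), and the analytic benchmark.  A synthetic stand-in
for the deposited 13-sheet workbook reproduces its layout and physical
scales: capsule cells with broad, slightly source-shifted stress profiles
and peak speeds ~0.1 µm/s (viscosity 10 P, short radius 15 µm), spherical
cells with source-concentrated profiles and ~1.5 nm/s speeds (1 P).  Every
artifact embeds its seed and a hash of the generating spec; regeneration is
bit-identical.

What the synthetic data do not emulate: optical distortions, depth
attenuation and out-of-plane motion in the images; spatially correlated or
heteroscedastic measurement noise; deviations of real cell outlines from
the idealized sphere/capsule; any non-Newtonian or unsteady rheology.
Passing tests therefore demonstrate the correctness of the numerics and the
estimation machinery under the model's assumptions, not the validity of
those assumptions for a given cell.

## Problem sizes and defaults used in tests

Tests and examples run the reference grids (25×13, 56×14) but scale the
sampling budget to 5·10²–10⁴ (vs the reference ~1.2·10⁵) and use 6 + 7
synthetic cells with 150 points each, keeping the full suite under a
minute on one core.  All seeds are fixed and every stochastic check quotes
the tolerance its sampling error implies.

## Known limitations

* The pole columns of the boundary-fitted grid are degenerate; fields
  within one cell of a pole are first-order accurate at best, which
  dominates the pressure loop-closure residual.
* The clamped spline cannot represent stress profiles with non-zero slope
  at the poles (see above).
* Node amplitudes are only weakly identified individually; report the
  stress curve, not single amplitudes.
* The estimator is a prior-sampling importance average; with noiseless data
  the likelihood is so peaked that it effectively returns the best sampled
  candidate, so accuracy scales with N_Sample^(1/N_nodes).
* Rigid, idealized boundaries; no free-surface or membrane mechanics, no
  estimation of viscosity.
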
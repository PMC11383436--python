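# Methods

This note records the model behind `frapgrid`, the measurement operator,
the estimators, the numerical choices, and what the synthetic studies do
and do not establish.

## Physical model and its particle dual

The tubulin concentration in a contracting network is modeled by the
advection–diffusion equation

    dc/dt = D laplacian(c) + div(alpha * r * c),

with the radially linear inward flow `v(r) = -alpha r`. Two facts about
this equation organize the whole package:

1. It is the Fokker–Planck equation of an Ornstein–Uhlenbeck (OU)
   process, `dX = -alpha X dt + sqrt(2D) dW`. A point source therefore
   evolves into an isotropic Gaussian with mean `x0 exp(-alpha t)` and
   per-axis variance `(D/alpha)(1 - exp(-2 alpha t))` (Brownian limit
   `2Dt` as `alpha -> 0`). This Green's function is the analytic oracle
   for the solver, and independent OU particles are the *exact*
   stochastic dual of the PDE — the basis of both the synthetic-data
   generator and the forward-modeled measurement (below).
2. The flow is affine (`v(x) = -alpha x` componentwise), so a change to
   co-moving coordinates `y = x exp(alpha t)` removes advection exactly.
   With the diffusive pseudo-time `s(t) = (exp(2 alpha t) - 1)/(2 alpha)`
   the equation becomes a plain heat equation `dc/ds = D laplacian_y(c)`.

Material points in the steady field decay exponentially,
`r(t) = r0 exp(-alpha t)`; the short-time linearization `r0 (1 - alpha t)`
gives the pair-distance law `d(t) = d0 (1 - alpha t)` and the pure
contraction area bound `A(t) = A0 (1 - alpha t)^2`, the no-diffusion
reference against which measured areas are compared.

## Synthetic data generator

`simulate_filaments` places point filaments uniformly on a disk
(default radius 100 um) and propagates them either as OU particles using
the exact transition density at every step (no integrator bias at any
step size; default step 10 s, matching the frame interval) or with the
linearized-Lagrangian map `x(t) = (x0 + B(t)) (1 - alpha t)` with
co-moving Brownian motion `B`. The linearized mode exists because the
distance-vs-time analysis is a *linear-fit* analysis: it provides a
ground truth for which that estimator is exact, while the OU mode
provides the dynamically consistent truth.

`apply_bleach_mask` keeps fluorescence only inside 12-um square windows
on a 25-um center-to-center lattice (the measured geometry of the
photobleached grid); the `extent` option restricts the lattice to the
central n x n block. Filaments are points because the median filament
(~1.5 um) is an order of magnitude shorter than a window side; length and
orientation are not modeled.

`render_movie` bins fluorescent filaments into 0.5 um/px pixels (512 x
512 field, a plausible 20x-objective scale), blurs with a Gaussian PSF
(sigma 0.5 um), scales to 80 expected photons per filament and applies
Poisson shot noise plus Gaussian read noise (sd 2 counts). At the default
density this gives a plateau signal-to-noise ratio of roughly 5–10,
dominated by filament-count speckle rather than shot noise, as in a real
sparse filament preparation. The frame interval, pixel size and disk
radius are package choices (the corresponding experimental values are
not printed in the main text they emulate); everything is configurable.

What the generator does *not* emulate: filament–filament interactions and
network formation, motor binding kinetics, orientation-dependent
transport, spatially heterogeneous or anisotropic contraction,
photobleaching decay during imaging, and illumination falloff. Passing
recovery tests therefore demonstrate estimator correctness under the
stated transport model, not robustness to those real-data effects.

## Measurement operator

Unit cells are segmented by Gaussian smoothing, thresholding, and
8-connected components; regions outside 25–400 um^2 or touching the
frame border are discarded. Two details matter and are deliberate:

- **The threshold is anchored at the first post-bleach frame** (midpoint
  between the modal bleached-line and modal plateau intensities there,
  with Otsu as fallback) and held fixed for the movie. A per-frame
  adaptive threshold tracks the half-maximum contour, and a half-maximum
  contour is first-order invariant under symmetric edge blur — it would
  erase precisely the diffusive signal this measurement exists to
  capture. Anchoring is also standard FRAP practice: the fixed intensity
  level follows the *initial* fluorescent material. As the network
  compresses, the plateau rises as `exp(2 alpha t)` above the anchored
  level, the measured contour rides outward on the blurred edge, and the
  bleached lines visibly fill in — reproducing the observed blending of
  neighboring cells at late times.
- **Areas are measured sub-pixel** by tracing the threshold-level
  marching-squares contour around each cell and taking the polygon area.
  Pixel counting with hole-filling has a one-pixel-ring quantization and
  an asymmetric noise-attachment bias; the contour area has neither.

Tracking-side smoothing defaults to 2 px (1.0 um): at the anchored
(relatively low) threshold the edge profile is convex, so speckle noise
inflates areas (a Jensen bias). Ground-truth calibration showed 0.5 um
smoothing leaves a sizable upward bias on the fitted diffusion constant,
1.0 um is near-neutral, and 1.5 um oversmooths (the fit collapses toward
the sweep floor). Detection-only use (`segment_unit_cells`) keeps a 1 px
default.

The network center is the intensity-weighted centroid of the first
post-bleach frame after median-background subtraction; recovery is
insensitive to +-2 px perturbations of this choice (tested). Per-cell
normalization uses the area in the cell's first valid frame. Cells are
linked frame-to-frame by nearest centroid with a pitch/4 gate; zero or
ambiguous candidates truncate the track.

## Contraction-rate estimator

Each cell's radial distance vs time is fit by ordinary least squares over
the 0–150 s analysis window (the grid pattern dissolves by about two
minutes); `alpha` is the through-origin slope of cell speed against cell
radius, with a seeded nonparametric bootstrap over cells for the 95%
interval (2000 resamples; the per-cell median of speed/radius is also
reported). The radius coordinate defaults to the distance at the window
start. The time-averaged distance is also computed, but pairing it with
the window-averaged speed is internally inconsistent: in linearized
dynamics it overestimates `alpha` by `1/(1 - alpha t_mean)` (~18% at
these rates), whereas the window-start radius makes the estimator exact
in linearized mode and biased low by a known bounded factor (about
`1 - alpha T / 2`, within [0.85, 1.0] for `alpha T = 0.3`) under true
exponential decay — the bounded-bias direction the analysis expects and
tests. The interval is a bootstrap because the upstream "credible
region" procedure is not reproducible from the main text; the report
labels it accordingly.

## Advection–diffusion solver

The default scheme ("comoving") exploits the exact co-moving transform:
conservative finite-volume diffusion (centered fluxes, no-flux walls,
explicit steps under `dt <= cfl * h^2 / 4D`) in the fixed co-moving grid,
with the contraction carried analytically in the grid geometry (the
output field's spacing and origin shrink by `exp(-alpha t)`). Advection
therefore contributes *zero* discretization error, mass is conserved to
roundoff, and positivity is inherited from the heat stencil. Fixed-grid
schemes ("muscl": van Leer flux-limited; "upwind": first order) are also
implemented and serve as cross-checks; they are not defaults because at
the relevant resolutions upwind's numerical diffusion (`|v| h / 2`, about
2e-2 um^2/s at h = 0.25 um) exceeds the physical `D` being fitted by an
order of magnitude, and even the limited scheme smears the bleach edge by
more than the physical diffusion length. Note that for this affine flow
a "full radial" and a "locally linearized" velocity field are
algebraically identical, so no separate option exists. Default spatial
resolution 0.25 um on a 75-um (three-pitch) domain.

The model initial condition for area prediction is the central square
*plus its lattice neighbors* (plateau 1, bleached background 0, fully
bleached by default, partial bleach configurable): the bleached lines
refill from both sides in the data, which a lone square in an infinite
dark surround cannot reproduce. The predicted field is blurred with the
imaging PSF and measured with the same anchored-threshold contour
operator as the data, normalized at t = 0. Because the flow is affine,
the predicted trajectory is independent of where the cell sits in the
network.

## Fitting the effective diffusion constant

`fit_diffusion_constant` sweeps `D` over a log grid (default 15 points on
[1e-4, 6e-3] um^2/s, covering the published family of model curves),
accumulates the sum of squared errors between predicted and observed
normalized-area trajectories at the observed timepoints in the window,
and refines the arg-min by parabolic interpolation in log10(D); an
arg-min on the sweep boundary is flagged "range-limited" and left
unrefined.

Deterministic model curves are adequate for clean data, but thresholded
areas of noisy movies carry speckle-induced biases that a noiseless model
cannot share. The pipeline therefore forward-models the measurement when
the movie's filament density is known (synthetic movies record it in
their metadata): each model realization draws filaments as a Poisson
point process from the full bleached block at the movie's areal density,
propagates them with the exact OU transition for the candidate `D`,
renders every frame through the same camera chain, measures *every*
window with the anchored-threshold contour operator, and summarizes cells
with the same statistic (median or quartile) as the data. Realizations
are complete correlated movies, so frame-to-frame speckle correlation and
edge-window geometry (outer windows of the block lack outer neighbors)
enter the model exactly as they enter the data — both were measurable
biases when omitted. Across the candidate-D sweep the dynamics stream
uses common random numbers (shared standard normals scaled by each D's
step width; camera noise on a separate stream), so SSE differences
reflect `D` rather than realization noise. Four block realizations per
movie replicate are the default.

Observed quartile statistics pool unit cells across replicate movies
before the sweep (as experimental quartiles pool cells across
replicates); the standard recovery study uses four replicate movies of
2e5 filaments each. Ground-truth validation at injected
`D = 1.0e-3 um^2/s`: single-movie recoveries have a ~25% spread with
negligible central bias; pooled four-replicate recoveries landed within
5–25% of truth across disjoint seed groups.

## Condition-level analyses

`fit_michaelis_menten` fits `alpha([ATP]) = a [ATP] / (Km + [ATP])` by
nonlinear least squares with relative weighting (`sigma` proportional to
the rate, covariance scaled by the residuals), the consistent estimator
when measurement scatter is multiplicative; standard deviations come from
the fit covariance, and the uncertainty band pairs amplitude + sd with
Km - sd (and vice versa), which brackets the fitted curve. ADP
competition is not modeled (the assays use an ATP-regeneration system).

`compute_peclet` returns `Pe = alpha L^2 / D`, the ratio of the diffusive
timescale `L^2/D` to the advective timescale `L/(alpha L)`; the default
`L = 1.5 um` (median filament length) probes the local competition.
`fit_peclet_slope` regresses `alpha L^2` on the chosen `D` column
(median, q1 or q3) through the origin, with the regression sd and an
optional inverse-variance weighting (default unweighted — no replicate
weights are published); because it is not known which variable carries
the error, the reciprocal regression is also reported. Synthetic
condition generators (rates on a Michaelis–Menten curve; condition sets
on a Peclet proportionality line, both with 10% multiplicative Gaussian
noise) support seeded recovery studies.

## Degenerate inputs and tie-breaks

Singular linearized maps (`alpha t >= 1`), all-zero frames, boundary mass
above 1e-6 of the total, all-equal `D` columns, and sub-3-point designs
raise `ValueError`. An empty fluorescent set renders an all-noise movie
with a warning. Tracks truncate (never interpolate) on gate failures and
contested regions. The bootstrap interval is clamped to contain the point
estimate. Thresholding falls back to Otsu when the class modes are
degenerate.

## Problem sizes used by the test suite and acceptance script

Movies use the 5x5 central window block (25 unit cells) on a 100-um
network: 8e5 filaments for contraction-rate recovery (SNR near 10), 2e5
per replicate (4 replicates pooled) for diffusion recovery; the
condition-level studies use 100 seeded replicates of 6 ATP concentrations
or 8 conditions. These sizes give the estimators' Monte-Carlo error a
comfortable margin relative to the tolerances they are tested against.

## Known limitations

- The transport model is linear-flow plus isotropic diffusion; no
  viscoelastic stress, polarity, or orientation-dependent terms, so late
  reorganization beyond the grid's lifetime is out of scope.
- The anchored-threshold area is a measurement-defined quantity: its D=0
  trajectory sits slightly above `A0 exp(-2 alpha t)` because compression
  raises the plateau over the fixed level. Comparisons are meaningful
  because model and data use the identical operator, not because the
  functional equals the material area.
- `alpha` recovery assumes the bleach happens at a known time and the
  network center is stationary; drift is not corrected.
- The forward-measured model requires the filament density and camera
  parameters; for movies without that metadata the deterministic model
  curves are used and `D` estimates inherit the speckle bias of the
  data-side measurement.
- Quartile (`q1`/`q3`) diffusion fits reuse the same machinery but were
  validated less extensively than the median fit.
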
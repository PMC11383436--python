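# frapgrid

Analysis of motor-driven contraction and active diffusion in filament
networks from grid-photobleached fluorescence movies.

When multimerized kinesin motors crosslink a microtubule network, the
network contracts globally while the filaments in its bulk also spread
locally in a diffusive-like, motor-driven way. Photobleaching a grid
pattern onto the labeled network turns it into a transient coordinate
system: the surviving fluorescent squares ("unit cells") advect toward the
network center as the network contracts, while the dark bleached lines
between them blur away as filaments redistribute. `frapgrid` quantifies
both effects and ties them together across experimental conditions. It is
written for active-matter / cytoskeleton labs doing FRAP-style photobleach
experiments on contracting in-vitro networks, and for anyone who wants a
fully synthetic, ground-truth-controlled testbed for such analyses.

## The model

The network contracts with a radially linear velocity field

    v(r) = -alpha * r

where `alpha` (1/s) is the global contraction rate. Tubulin concentration
`c(r, t)` then obeys the advection–diffusion equation

    dc/dt = D laplacian(c) + div(alpha * r * c)

with `D` (um^2/s) the effective diffusion constant of filaments in the
bulk. This is the Fokker–Planck equation of an Ornstein–Uhlenbeck process,
which supplies closed-form oracles (a point source has mean
`x0 exp(-alpha t)` and per-axis variance `(D/alpha)(1 - exp(-2 alpha t))`)
and an exact particle dual used throughout for validation.

Two material laws follow for tracked unit cells: a pair of points at
distance `d0` under pure linearized contraction closes to
`d0 (1 - alpha t)`, so a purely contracting cell has area
`A(t) = A0 (1 - alpha t)^2` — the *pure contraction bound*. Measured areas
above this bound are the signature of active diffusion; sweeping `D` in
the advection–diffusion model against the measured normalized-area
trajectories yields the effective diffusion constant `D_eff`.

Across conditions (motor species, ATP concentration), the contraction rate
follows a Michaelis–Menten dependence on ATP,
`alpha([ATP]) = a_max [ATP] / (Km + [ATP])`, and `alpha * L^2` is
proportional to `D_eff`; the through-origin slope is the Peclet number
`Pe = alpha L^2 / D` at the characteristic length `L` (default 1.5 um, a
typical filament length).

## What is in the package

- `frapgrid.simulate` — synthetic data: point filaments on a disk under
  OU (exact transitions) or linearized-Lagrangian dynamics, grid
  photobleach masks, and a camera model (PSF, pixel binning, shot and read
  noise) rendering 16-bit TIFF movies.
- `frapgrid.segmentation` / `frapgrid.tracking` — unit-cell detection
  (smooth, bimodal-midpoint threshold anchored at the first post-bleach
  frame, sub-pixel contour areas), nearest-neighbor linking with a
  displacement gate, and median/quartile normalized-area statistics.
- `frapgrid.contraction` — per-cell distance-vs-time line fits and the
  through-origin speed-vs-radius fit for `alpha`, with a bootstrap CI.
- `frapgrid.advdiff` — the advection–diffusion solver (exact co-moving
  advection + conservative finite-volume diffusion; flux-limited and
  upwind fixed-grid schemes as cross-checks), OU Green's-function oracles,
  predicted area trajectories, and the `D`-sweep least-squares fit,
  optionally forward-modeling the full measurement chain.
- `frapgrid.conditions` — Michaelis–Menten fits of `alpha` vs [ATP] and
  Peclet-number slope fits across conditions.
- `frapgrid.pipeline` — end-to-end recovery workflows; `frapgrid.cli` — a
  `frapgrid` command with `simulate`, `track`, `fit-contraction`,
  `fit-diffusion` and `analyze-conditions` subcommands.

## Worked example

Recover both transport coefficients from purely synthetic movies with
known ground truth (injected `alpha = 2.0e-3` 1/s, `D = 1.0e-3` um^2/s):

```python
from frapgrid import simulate_grid_movie
from frapgrid.pipeline import (recover_contraction_rate,
                               recover_diffusion_constant_pooled)

# contraction rate from one grid-photobleached movie (linearized mode)
movie = simulate_grid_movie(alpha=2.0e-3, d=0.0,
                            mode="linearized_lagrangian", seed=8,
                            n_filaments=800_000)
rate, tracks, speeds = recover_contraction_rate(movie.stack, seed=8)
print(f"alpha = {rate.alpha:.3e} 1/s "
      f"(95% CI {rate.ci95[0]:.3e} .. {rate.ci95[1]:.3e}, "
      f"{rate.n_cells} unit cells)")

# effective diffusion constant from replicate stochastic movies (OU mode)
stacks = []
for seed in (81, 82, 83, 84):
    mv = simulate_grid_movie(alpha=2.0e-3, d=1.0e-3, mode="eulerian_ou",
                             seed=seed, n_filaments=200_000)
    stacks.append(mv.stack)
fit, observed = recover_diffusion_constant_pooled(stacks, rate.alpha,
                                                  grid=mv.grid,
                                                  noise_seed=8)
print(f"D_eff = {fit.d_best:.2e} um^2/s (sweep over "
      f"{fit.d_grid[0]:.0e} .. {fit.d_grid[-1]:.0e}, flags={fit.flags})")
```

This prints:

```
alpha = 2.000e-03 1/s (95% CI 1.998e-03 .. 2.001e-03, 25 unit cells)
D_eff = 9.70e-04 um^2/s (sweep over 1e-04 .. 6e-03, flags=[])
```

`alpha` comes back at the injected 2.0e-3 1/s (the 25 unit cells of the
5x5 bleached grid all sit on the v = -alpha r line), and the D-sweep lands
within a few percent of the injected 1.0e-3 um^2/s; an empty `flags` list
means the optimum was interior to the sweep range. With `Pe =
alpha * (1.5 um)^2 / D_eff` these values give a Peclet number of about
4.6 at the filament scale: advection outpaces diffusion, but only by a
factor of a few.

The same workflow is available from the shell (`frapgrid simulate`,
`frapgrid track`, `frapgrid fit-contraction`, `frapgrid fit-diffusion`,
`frapgrid analyze-conditions`); see `frapgrid --help`.

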
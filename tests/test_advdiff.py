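"""Tests of the advection-diffusion solver, oracles and the D-sweep fit."""

import math

import numpy as np
import pytest

from frapgrid import (GridBleachSpec, fit_diffusion_constant,
                      make_gaussian_field, make_square_field,
                      ou_green_function, predict_area_trajectory,
                      simulate_filaments, solve_advdiff)
from frapgrid.advdiff import ConcentrationField
from frapgrid.config import SimulationConfig
from frapgrid.segmentation import measure_central_area
from frapgrid.tracking import AreaTrajectory

ALPHA = 2e-3
D = 1e-3


class TestGreenFunction:
    def test_initial_condition(self):
        mean, var = ou_green_function((3.0, -4.0), 0.0, ALPHA, D)
        assert mean == (3.0, -4.0) and var == 0.0

    def test_brownian_limit(self):
        _, var = ou_green_function((0.0, 0.0), 100.0, 0.0, D)
        assert var == pytest.approx(0.2)

    def test_pure_advection_mean_decay(self):
        mean, var = ou_green_function((10.0, 0.0), 150.0, ALPHA, 0.0)
        assert mean[0] == pytest.approx(10.0 * math.exp(-0.3))
        assert var == 0.0

    def test_variance_saturates_at_d_over_alpha(self):
        _, var = ou_green_function((0.0, 0.0), 1e7, ALPHA, D)
        assert var == pytest.approx(D / ALPHA)

    def test_negative_arguments_rejected(self):
        with pytest.raises(ValueError):
            ou_green_function((0.0, 0.0), -1.0, ALPHA, D)


class TestSolver:
    def test_heat_kernel_alpha_zero(self):
        # pure diffusion of a Gaussian stays Gaussian with
        # sigma^2 = sigma0^2 + 2 D t
        c0 = make_gaussian_field(3.0, spacing=0.25, domain=50.0,
                                 center=(0.0, 0.0))
        f = solve_advdiff(c0, 0.0, D, [100.0])[0]
        x, y = f.cell_centers()
        xx, yy = np.meshgrid(x, y)
        s2 = 9.0 + 2 * D * 100.0
        ref = np.exp(-(xx**2 + yy**2) / (2 * s2)) / (2 * np.pi * s2)
        err = np.linalg.norm(f.values - ref) / np.linalg.norm(ref)
        assert err < 1e-2

    @pytest.mark.parametrize("scheme", ["comoving", "muscl", "upwind"])
    def test_mass_conserved_and_nonnegative(self, scheme):
        c0 = make_gaussian_field(3.0, spacing=0.5, domain=60.0,
                                 center=(10.0, 0.0))
        fields = solve_advdiff(c0, ALPHA, D, [50.0, 150.0], scheme=scheme)
        for f in fields:
            assert abs(f.mass() - c0.mass()) / c0.mass() < 1e-6
            assert f.values.min() >= 0.0

    def test_matches_ou_oracle_moments_exactly(self):
        # mean and variance of the solution vs the OU Green's function;
        # the conservative Laplacian preserves second-moment growth
        # exactly (summation by parts), so moments match to roundoff
        c0 = make_gaussian_field(3.0, spacing=0.5, domain=60.0,
                                 center=(10.0, 0.0))
        f = solve_advdiff(c0, ALPHA, D, [150.0])[0]
        (mx, my), (vx, vy) = f.moments()
        mean, var = ou_green_function((10.0, 0.0), 150.0, ALPHA, D)
        v_ref = 9.0 * math.exp(-2 * ALPHA * 150.0) + var
        assert mx == pytest.approx(mean[0], abs=1e-9)
        assert my == pytest.approx(0.0, abs=1e-9)
        assert vx == pytest.approx(v_ref, rel=1e-9)

    def test_field_converges_second_order_to_analytic_solution(self):
        # L2 error of the whole field against the closed-form Gaussian
        # solution drops by about the formal order under grid refinement
        errs = []
        mean, var = ou_green_function((10.0, 0.0), 150.0, ALPHA, D)
        v_ref = 9.0 * math.exp(-2 * ALPHA * 150.0) + var
        for spacing in (2.0, 1.0):
            c0 = make_gaussian_field(3.0, spacing=spacing, domain=60.0,
                                     center=(10.0, 0.0))
            f = solve_advdiff(c0, ALPHA, D, [150.0], cfl=0.2)[0]
            x, y = f.cell_centers()
            xx, yy = np.meshgrid(x, y)
            ref = np.exp(-((xx - mean[0]) ** 2 + yy**2) / (2 * v_ref)) \
                / (2 * np.pi * v_ref)
            errs.append(np.linalg.norm(f.values - ref)
                        / np.linalg.norm(ref))
        assert errs[1] < errs[0] / 3.0

    def test_fixed_grid_schemes_agree_with_comoving(self):
        c0 = make_gaussian_field(3.0, spacing=0.5, domain=60.0,
                                 center=(10.0, 0.0))
        ref = solve_advdiff(c0, ALPHA, D, [150.0])[0]
        (mx0, _), (vx0, vy0) = ref.moments()
        # upwind's looser variance band is its first-order numerical
        # diffusion, the reason it is not the default scheme
        for scheme, tol_m, tol_v in (("muscl", 0.1, 0.02),
                                     ("upwind", 0.1, 0.25)):
            f = solve_advdiff(c0, ALPHA, D, [150.0], scheme=scheme)[0]
            (mx, _), (vx, vy) = f.moments()
            assert abs(mx - mx0) < tol_m
            assert abs(vx - vx0) < tol_v * vx0

    @pytest.mark.parametrize("scheme", ["comoving", "muscl"])
    def test_radial_symmetry_preserved(self, scheme):
        c0 = make_gaussian_field(4.0, spacing=0.5, domain=64.0,
                                 center=(0.0, 0.0))
        f = solve_advdiff(c0, ALPHA, D, [100.0], scheme=scheme)[0]
        np.testing.assert_allclose(f.values, np.rot90(f.values),
                                   rtol=0, atol=1e-12 * f.values.max())

    @pytest.mark.parametrize("scheme", ["comoving", "muscl"])
    def test_pure_advection_area_law(self, scheme):
        # D = 0: the thresholded square area contracts as A0 e^(-2 alpha t)
        c0 = make_square_field(12.0, spacing=0.25, domain=75.0,
                               center=(40.0, 0.0))
        f = solve_advdiff(c0, ALPHA, 0.0, [150.0], scheme=scheme)[0]
        if scheme == "comoving":
            center_px = None
        else:
            xc = 40.0 * math.exp(-0.3)
            center_px = ((0.0 - f.origin[1]) / f.spacing - 0.5,
                         (xc - f.origin[0]) / f.spacing - 0.5)
        a = measure_central_area(f.values, f.spacing, smooth_sigma_um=0.5,
                                 center_px=center_px)
        band = 4 * 12.0 * 0.25  # one grid-cell ring around the square
        assert abs(a - 144.0 * math.exp(-0.6)) < band

    def test_exponential_contraction_linearizes_to_pure_bound(self):
        # e^(-2 alpha t) agrees with the linearized (1 - alpha t)^2 to
        # first order in alpha t
        at = np.linspace(0.0, 0.3, 13)
        gap = np.exp(-2 * at) - (1 - at) ** 2
        assert np.all(gap >= 0)
        assert np.all(gap <= 2 * at**2 + 1e-12)

    def test_boundary_mass_precondition(self):
        vals = np.ones((40, 40))
        c0 = ConcentrationField(values=vals, spacing=1.0,
                                origin=(-20.0, -20.0))
        with pytest.raises(ValueError):
            solve_advdiff(c0, ALPHA, D, [10.0])

    def test_particle_histogram_converges_to_pde(self):
        # the OU particle ensemble is the stochastic dual of the PDE:
        # histogram L1 distance to the solved field drops with filament count
        edges = np.arange(-108.0, 109.0, 6.0)
        l1 = []
        for n in (20_000, 200_000):
            cfg = SimulationConfig(n_filaments=n, alpha=ALPHA, d=D,
                                   t_total=150.0, dt=10.0, seed=2)
            ens = simulate_filaments(cfg)
            # PDE initial condition = the empirical particle density, so the
            # comparison isolates dynamics rather than initial sampling
            h0, _, _ = np.histogram2d(ens.positions[0][:, 1],
                                      ens.positions[0][:, 0],
                                      bins=[edges, edges])
            c0 = ConcentrationField(values=h0 / (n * 36.0), spacing=6.0,
                                    origin=(-108.0, -108.0))
            ref = solve_advdiff(c0, ALPHA, D, [150.0],
                                boundary_mass_tol=1e-3)[0]
            hist, _, _ = np.histogram2d(ens.positions[-1][:, 1],
                                        ens.positions[-1][:, 0],
                                        bins=[edges, edges])
            # exact area-weighted resampling of the contracted PDE grid
            # onto the histogram bins
            def overlap(cell_lo):
                lo = cell_lo[:, None]
                hi = lo + ref.spacing
                cut_lo = np.maximum(lo, edges[None, :-1])
                cut_hi = np.minimum(hi, edges[None, 1:])
                return np.clip(cut_hi - cut_lo, 0.0, None) / ref.spacing

            ncell = ref.values.shape[0]
            wx = overlap(ref.origin[0] + np.arange(ncell) * ref.spacing)
            wy = overlap(ref.origin[1] + np.arange(ncell) * ref.spacing)
            pde_mass = wy.T @ (ref.values * ref.spacing**2) @ wx
            l1.append(np.abs(hist / n - pde_mass).sum())
        assert l1[1] < l1[0] / 1.8


class TestPredictedAreaTrajectory:
    grid = GridBleachSpec()
    times = np.arange(0.0, 151.0, 10.0)

    def test_pure_advection_trajectory(self):
        # monotone shrinkage bounded below by the Lagrangian law: with the
        # threshold anchored at t = 0, compression raises the plateau above
        # the fixed level, so the measured contour rides slightly outside
        # the material square and the trajectory sits on or above e^(-2at)
        tr = predict_area_trajectory(self.grid, ALPHA, 0.0, self.times)
        law = np.exp(-2 * ALPHA * self.times)
        assert tr.normalized_area[0] == 1.0
        assert np.all(np.diff(tr.normalized_area) < 0)
        assert np.all(tr.normalized_area >= law - 1e-3)
        assert np.all(tr.normalized_area <= law + 0.12)

    def test_no_advection_trajectory_stays_near_unity(self):
        tr = predict_area_trajectory(self.grid, 0.0, 2e-3, self.times)
        assert np.all(np.abs(tr.normalized_area - 1.0) < 0.02)

    def test_family_monotone_in_d(self):
        trajs = np.array([
            predict_area_trajectory(self.grid, ALPHA, d,
                                    self.times).normalized_area
            for d in (0.0, 3e-4, 1e-3, 3e-3, 6e-3)])
        assert np.all(np.diff(trajs, axis=0) > -1.5e-3)

    def test_times_must_start_at_zero(self):
        with pytest.raises(ValueError):
            predict_area_trajectory(self.grid, ALPHA, D, [10.0, 20.0])


class TestDiffusionFit:
    grid = GridBleachSpec()
    times = np.arange(0.0, 151.0, 15.0)

    def _observed(self, d):
        tr = predict_area_trajectory(self.grid, ALPHA, d, self.times)
        return AreaTrajectory(self.times, tr.normalized_area, "median")

    def test_self_consistency_on_grid_values(self):
        d_grid = np.geomspace(1e-4, 6e-3, 9)
        for d_true in (d_grid[3], d_grid[5]):
            fit = fit_diffusion_constant(self._observed(d_true), ALPHA,
                                         d_grid=d_grid, grid=self.grid)
            assert fit.sse[np.argmin(np.abs(d_grid - d_true))] \
                == fit.sse.min()
            assert abs(fit.d_best - d_true) / d_true < 0.25
            assert not fit.flags

    def test_sse_unimodal_in_log_d(self):
        fit = fit_diffusion_constant(self._observed(1e-3), ALPHA,
                                     d_grid=np.geomspace(1e-4, 6e-3, 11),
                                     grid=self.grid)
        sign_changes = np.sum(np.abs(np.diff(np.sign(np.diff(fit.sse)))) > 0)
        assert sign_changes <= 1

    def test_pure_contraction_hits_lower_boundary(self):
        obs = AreaTrajectory(self.times,
                             np.exp(-2 * ALPHA * self.times), "median")
        fit = fit_diffusion_constant(obs, ALPHA,
                                     d_grid=np.geomspace(5e-4, 6e-3, 6),
                                     grid=self.grid)
        assert "range-limited" in fit.flags
        assert fit.d_best == fit.d_grid[0]

    def test_needs_enough_timepoints(self):
        obs = AreaTrajectory([0.0, 10.0], [1.0, 0.9], "median")
        with pytest.raises(ValueError):
            fit_diffusion_constant(obs, ALPHA, grid=self.grid)
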
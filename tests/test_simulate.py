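"""Tests of the synthetic filament/movie generator."""

import numpy as np
import pytest

from frapgrid import (FilamentEnsemble, GridBleachSpec, ImagingConfig,
                      SimulationConfig, apply_bleach_mask, render_movie,
                      simulate_filaments)


def _cfg(**kw):
    base = dict(n_filaments=200, network_radius=50.0, alpha=2e-3, d=1e-3,
                advection_mode="eulerian_ou", t_total=100.0, dt=10.0, seed=1)
    base.update(kw)
    return SimulationConfig(**base)


class TestSimulateFilaments:
    def test_no_dynamics_positions_constant(self):
        for mode in ("eulerian_ou", "linearized_lagrangian"):
            ens = simulate_filaments(_cfg(alpha=0.0, d=0.0,
                                          advection_mode=mode))
            assert np.array_equal(ens.positions, np.broadcast_to(
                ens.positions[0], ens.positions.shape))

    def test_linearized_map_matches_closed_form(self):
        # x(t) = x0 (1 - alpha t): a filament starting 10 um out sits at
        # 8 um after 100 s at alpha = 2e-3 1/s
        ens = simulate_filaments(_cfg(advection_mode="linearized_lagrangian",
                                      d=0.0))
        shrink = 1.0 - 2e-3 * ens.times
        expected = ens.positions[0][None] * shrink[:, None, None]
        np.testing.assert_allclose(ens.positions, expected, rtol=1e-12)
        np.testing.assert_allclose(ens.positions[-1],
                                   ens.positions[0] * 0.8, rtol=1e-12)

    def test_ou_brownian_displacement_variance(self):
        # alpha = 0: per-axis displacement variance is 2 D t
        ens = simulate_filaments(_cfg(n_filaments=100_000, alpha=0.0))
        disp = ens.positions[-1] - ens.positions[0]
        var = disp.var(axis=0)
        np.testing.assert_allclose(var, 2 * 1e-3 * 100.0, rtol=0.05)

    def test_ou_no_diffusion_exponential_decay(self):
        # D = 0 in the OU mode: every radius decays as r0 exp(-alpha t)
        ens = simulate_filaments(_cfg(d=0.0, dt=5.0))
        r = np.hypot(ens.positions[..., 0], ens.positions[..., 1])
        expected = r[0][None] * np.exp(-2e-3 * ens.times)[:, None]
        np.testing.assert_allclose(r, expected, rtol=1e-10)

    def test_initial_positions_inside_disk(self):
        ens = simulate_filaments(_cfg())
        r0 = np.hypot(*ens.positions[0].T)
        assert r0.max() <= 50.0

    def test_seed_determinism(self):
        a = simulate_filaments(_cfg(seed=42))
        b = simulate_filaments(_cfg(seed=42))
        c = simulate_filaments(_cfg(seed=43))
        assert np.array_equal(a.positions, b.positions)
        assert not np.array_equal(a.positions, c.positions)

    def test_linearized_singular_map_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(alpha=2e-2, t_total=100.0, dt=1.0,
                             advection_mode="linearized_lagrangian")

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_filaments=0)
        with pytest.raises(ValueError):
            SimulationConfig(alpha=float("nan"))
        with pytest.raises(ValueError):
            SimulationConfig(dt=0.0)


class TestBleachMask:
    def _ensemble(self, points):
        pos = np.asarray(points, dtype=float)[None]
        return FilamentEnsemble(times=[0.0], positions=pos,
                                fluorescent=np.ones(len(points), bool))

    def test_window_membership(self):
        grid = GridBleachSpec()  # 12 um squares on a 25 um pitch
        ens = self._ensemble([
            (0.0, 0.0),     # square center -> fluorescent
            (12.5, 0.0),    # midpoint of the bleached line -> dark
            (25.0, 25.0),   # neighboring square center -> fluorescent
            (5.9, 5.9),     # just inside the corner
            (6.1, 0.0),     # just outside the edge
        ])
        out = apply_bleach_mask(ens, grid)
        assert out.fluorescent.tolist() == [True, False, True, True, False]
        # positions untouched, filament count conserved
        assert np.array_equal(out.positions, ens.positions)
        assert out.n_filaments == ens.n_filaments

    def test_extent_limits_lattice(self):
        grid = GridBleachSpec(extent=1)
        ens = self._ensemble([(0.0, 0.0), (25.0, 0.0)])
        out = apply_bleach_mask(ens, grid)
        assert out.fluorescent.tolist() == [True, False]

    def test_mask_uses_positions_at_bleach_time(self):
        pos = np.stack([np.array([[0.0, 0.0]]), np.array([[12.5, 0.0]])])
        ens = FilamentEnsemble(times=[0.0, 10.0], positions=pos,
                               fluorescent=np.ones(1, bool))
        assert apply_bleach_mask(ens, GridBleachSpec(bleach_time=0.0)) \
            .fluorescent[0]
        assert not apply_bleach_mask(ens, GridBleachSpec(bleach_time=10.0)) \
            .fluorescent[0]

    def test_bleach_time_outside_range_rejected(self):
        ens = self._ensemble([(0.0, 0.0)])
        with pytest.raises(ValueError):
            apply_bleach_mask(ens, GridBleachSpec(bleach_time=50.0))

    def test_surviving_fraction_is_window_area_fraction(self):
        # Monte-Carlo estimate of the fluorescent fraction of a uniform
        # field: (side / pitch)^2 = (12/25)^2 = 0.2304
        cfg = _cfg(n_filaments=200_000, network_radius=200.0, alpha=0.0,
                   d=0.0, seed=9)
        out = apply_bleach_mask(simulate_filaments(cfg), GridBleachSpec())
        frac = out.fluorescent.mean()
        assert abs(frac - (12 / 25) ** 2) < 5e-3


class TestRenderMovie:
    def test_single_filament_centroid(self):
        # one filament on a pixel center renders to a symmetric spot whose
        # intensity-weighted centroid reproduces the position to < 0.1 px
        imaging = ImagingConfig(field_size=(64, 64),
                                photons_per_filament=1000.0)
        x = (40 + 0.5 - 32) * imaging.pixel_size
        y = (20 + 0.5 - 32) * imaging.pixel_size
        ens = FilamentEnsemble(times=[0.0], positions=[[(x, y)]],
                               fluorescent=[True])
        stack = render_movie(ens, imaging, noise=False)
        frame = stack.data[0]
        rows = np.arange(64)[:, None]
        cols = np.arange(64)[None, :]
        rc = (frame * rows).sum() / frame.sum()
        cc = (frame * cols).sum() / frame.sum()
        assert abs(rc - 20) < 0.1 and abs(cc - 40) < 0.1

    def test_zero_photons_read_noise_only(self):
        imaging = ImagingConfig(field_size=(64, 64),
                                photons_per_filament=0.0, read_noise_sd=2.0)
        ens = FilamentEnsemble(times=[0.0], positions=[[(0.0, 0.0)]],
                               fluorescent=[True])
        frame = render_movie(ens, imaging, seed=4).data[0]
        assert abs(frame.mean()) < 0.2
        assert abs(frame.std() - 2.0) < 0.3

    def test_all_bleached_warns_but_renders(self):
        ens = FilamentEnsemble(times=[0.0], positions=[[(0.0, 0.0)]],
                               fluorescent=[False])
        with pytest.warns(RuntimeWarning):
            stack = render_movie(ens, ImagingConfig(field_size=(32, 32)))
        assert stack.data.shape == (1, 32, 32)

    def test_plateau_contrast_and_uniformity(self):
        # noiseless bleached uniform-density network (filaments on a regular
        # lattice, so no sampling speckle): squares are much brighter than
        # the bleached lines, and plateau brightness is uniform across cells
        from frapgrid import GridBleachSpec, apply_bleach_mask
        coords = np.arange(-80.0, 80.0, 0.4) + 0.13
        gx, gy = np.meshgrid(coords, coords)
        pts = np.column_stack([gx.ravel(), gy.ravel()])
        pts = pts[np.hypot(pts[:, 0], pts[:, 1]) <= 80.0]
        ens = FilamentEnsemble(times=[0.0], positions=pts[None],
                               fluorescent=np.ones(len(pts), bool))
        ens = apply_bleach_mask(ens, GridBleachSpec(extent=5))
        stack = render_movie(ens, ImagingConfig(field_size=(360, 360)),
                             noise=False)
        frame = stack.data[0]
        h, w = frame.shape
        px = stack.pixel_size
        cols = (np.arange(w) + 0.5 - w / 2) * px
        rows = (np.arange(h) + 0.5 - h / 2) * px
        xx, yy = np.meshgrid(cols, rows)
        plateau_means = []
        for cx in (-50, -25, 0, 25, 50):
            for cy in (-50, -25, 0, 25, 50):
                sel = (np.abs(xx - cx) < 4) & (np.abs(yy - cy) < 4)
                plateau_means.append(frame[sel].mean())
        line_sel = (np.abs(xx - 12.5) < 2) & (np.abs(yy) < 40)
        plateau = np.mean(plateau_means)
        assert plateau / max(frame[line_sel].mean(), 1e-9) > 20
        assert np.max(np.abs(plateau_means - plateau)) / plateau < 0.05

    def test_render_seed_determinism(self, ou_movie):
        a = render_movie(ou_movie.ensemble, ou_movie.imaging, seed=6)
        b = render_movie(ou_movie.ensemble, ou_movie.imaging, seed=6)
        assert np.array_equal(a.data, b.data)

    def test_frame_interval_must_match_samples(self):
        ens = simulate_filaments(_cfg(dt=7.0, t_total=70.0))
        with pytest.raises(ValueError):
            render_movie(ens, ImagingConfig(frame_interval=10.0,
                                            field_size=(32, 32)))
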
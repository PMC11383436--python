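"""Synthetic contracting-network movies with a photobleached grid.

Generates ground-truth point-filament trajectories under linear inward
advection plus diffusion, applies a grid photobleach, and renders noisy
fluorescence image stacks, so the downstream measurement pipeline can be
validated against known parameters.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .config import GridBleachSpec, ImagingConfig, SimulationConfig

log = logging.getLogger(__name__)

__all__ = [
    "FilamentEnsemble",
    "ImageStack",
    "simulate_filaments",
    "apply_bleach_mask",
    "render_movie",
]


@dataclass
class FilamentEnsemble:
    """Trajectories of point filaments in network-centered coordinates.

    Attributes
    ----------
    times : (T,) array of sample times in seconds.
    positions : (T, N, 2) array of (x, y) positions in micrometres.
    fluorescent : (N,) boolean array; False marks photobleached filaments.
    """

    times: np.ndarray
    positions: np.ndarray
    fluorescent: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        self.fluorescent = np.asarray(self.fluorescent, dtype=bool)
        if self.positions.ndim != 3 or self.positions.shape[2] != 2:
            raise ValueError("positions must have shape (T, N, 2)")
        if self.positions.shape[0] != self.times.shape[0]:
            raise ValueError("times and positions disagree on frame count")
        if self.fluorescent.shape[0] != self.positions.shape[1]:
            raise ValueError("fluorescent length must equal filament count")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions must be finite")

    @property
    def n_filaments(self) -> int:
        return self.positions.shape[1]

    def index_at_time(self, t: float, atol: float = 1e-6) -> int:
        """Index of the sample closest to ``t``; raise if outside the range."""
        i = int(np.argmin(np.abs(self.times - t)))
        if t < self.times[0] - atol or t > self.times[-1] + atol:
            raise ValueError(f"time {t} outside simulated range")
        return i


@dataclass
class ImageStack:
    """A T x H x W intensity movie with physical calibration.

    ``data`` holds photon counts as floats (negative values can occur from
    read noise). Pixel (row, col) is centered at
    x = (col + 0.5 - W/2) * pixel_size, y = (row + 0.5 - H/2) * pixel_size
    in network-centered micrometre coordinates.
    """

    data: np.ndarray
    pixel_size: float
    times: np.ndarray
    bleach_time: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must have shape (T, H, W)")
        if self.data.shape[0] != self.times.shape[0]:
            raise ValueError("times and data disagree on frame count")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    def pixel_to_um(self, rows, cols):
        """Convert (fractional) pixel indices to network-frame micrometres."""
        h, w = self.data.shape[1:]
        x = (np.asarray(cols, dtype=float) + 0.5 - w / 2.0) * self.pixel_size
        y = (np.asarray(rows, dtype=float) + 0.5 - h / 2.0) * self.pixel_size
        return x, y

    def first_post_bleach_index(self, atol: float = 1e-6) -> int:
        idx = np.nonzero(self.times >= self.bleach_time - atol)[0]
        if idx.size == 0:
            raise ValueError("no frames at or after the bleach time")
        return int(idx[0])


def _initial_positions(cfg: SimulationConfig,
                       rng: np.random.Generator) -> np.ndarray:
    r = cfg.network_radius * np.sqrt(rng.uniform(size=cfg.n_filaments))
    theta = rng.uniform(0.0, 2.0 * np.pi, size=cfg.n_filaments)
    return np.column_stack([r * np.cos(theta), r * np.sin(theta)])


def simulate_filaments(cfg: SimulationConfig) -> FilamentEnsemble:
    """Simulate filament trajectories under contraction plus diffusion.

    Initial positions are uniform on the disk of ``cfg.network_radius``;
    trajectories are sampled at multiples of ``cfg.dt`` from 0 to
    ``cfg.t_total``. In ``eulerian_ou`` mode the exact Ornstein-Uhlenbeck
    transition (mean scaled by exp(-alpha dt), exact conditional variance) is
    used at every step, so the sampled trajectory is exact in distribution
    for any step size. In ``linearized_lagrangian`` mode positions follow
    x(t) = (x0 + B(t)) (1 - alpha t) with B a Brownian motion in the
    co-moving frame.

    Identical configs (including seed) give bit-identical output.
    """
    rng = np.random.default_rng(cfg.seed)
    n_steps = int(round(cfg.t_total / cfg.dt))
    times = np.arange(n_steps + 1) * cfg.dt
    x0 = _initial_positions(cfg, rng)
    n = cfg.n_filaments

    positions = np.empty((n_steps + 1, n, 2))
    positions[0] = x0

    if cfg.advection_mode == "eulerian_ou":
        decay = math.exp(-cfg.alpha * cfg.dt)
        if cfg.alpha > 0:
            step_var = (cfg.d / cfg.alpha) * (1.0 - decay**2)
        else:
            step_var = 2.0 * cfg.d * cfg.dt
        sd = math.sqrt(step_var)
        x = x0.copy()
        for k in range(1, n_steps + 1):
            x = x * decay
            if sd > 0:
                x = x + rng.normal(scale=sd, size=(n, 2))
            positions[k] = x
    else:  # linearized_lagrangian
        shrink = 1.0 - cfg.alpha * times
        if shrink[-1] <= 0:
            raise ValueError("linearized map is singular: alpha * t >= 1")
        if cfg.d > 0:
            inc = rng.normal(scale=math.sqrt(2.0 * cfg.d * cfg.dt),
                             size=(n_steps, n, 2))
            b = np.concatenate([np.zeros((1, n, 2)), np.cumsum(inc, axis=0)])
            positions[:] = (x0[None] + b) * shrink[:, None, None]
        else:
            positions[:] = x0[None] * shrink[:, None, None]

    fluorescent = np.ones(n, dtype=bool)
    return FilamentEnsemble(times=times, positions=positions,
                            fluorescent=fluorescent)


def apply_bleach_mask(ensemble: FilamentEnsemble,
                      grid: GridBleachSpec) -> FilamentEnsemble:
    """Photobleach the grid: keep fluorescence only inside the square windows.

    A filament stays fluorescent iff its position at ``grid.bleach_time``
    lies inside one of the axis-aligned square windows whose centers sit on
    the pitch lattice anchored at ``grid.grid_origin``. Positions are left
    untouched; only the fluorescence flags change.
    """
    k = ensemble.index_at_time(grid.bleach_time)
    pos = ensemble.positions[k]
    rel = pos - np.asarray(grid.grid_origin, dtype=float)
    # signed offset from the nearest lattice center, in (-pitch/2, pitch/2]
    frac = np.mod(rel + grid.pitch / 2.0, grid.pitch) - grid.pitch / 2.0
    inside = np.all(np.abs(frac) <= grid.square_side / 2.0, axis=1)
    if grid.extent is not None:
        index = np.round(rel / grid.pitch)
        half = (grid.extent - 1) / 2.0
        inside &= np.all(np.abs(index) <= half + 1e-9, axis=1)
    return FilamentEnsemble(times=ensemble.times,
                            positions=ensemble.positions,
                            fluorescent=inside)


def window_centers(grid: GridBleachSpec, radius: float) -> np.ndarray:
    """Centers (x, y) of all bleach windows within ``radius`` of the origin."""
    kmax = int(math.ceil(radius / grid.pitch)) + 1
    ks = np.arange(-kmax, kmax + 1)
    gx, gy = np.meshgrid(ks, ks, indexing="ij")
    centers = np.column_stack([
        grid.grid_origin[0] + gx.ravel() * grid.pitch,
        grid.grid_origin[1] + gy.ravel() * grid.pitch,
    ])
    if grid.extent is not None:
        half = (grid.extent - 1) / 2.0
        keep = (np.abs(gx.ravel()) <= half + 1e-9) & \
               (np.abs(gy.ravel()) <= half + 1e-9)
        centers = centers[keep]
    r = np.hypot(centers[:, 0], centers[:, 1])
    return centers[r <= radius]


def render_movie(ensemble: FilamentEnsemble,
                 imaging: ImagingConfig,
                 seed: int = 0,
                 noise: bool = True,
                 bleach_time: float = 0.0) -> ImageStack:
    """Render the fluorescent filaments into a noisy image stack.

    Frames are taken at multiples of ``imaging.frame_interval``, which must
    coincide (to within 1e-6 s) with sample times of the ensemble. Each frame
    bins fluorescent filament positions to pixels, blurs with a Gaussian PSF
    of ``imaging.psf_sigma``, scales to ``imaging.photons_per_filament``,
    then applies Poisson shot noise and Gaussian read noise (skipped when
    ``noise`` is False). Filaments outside the field of view are clipped
    silently. Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    h, w = imaging.field_size
    px = imaging.pixel_size
    t_end = ensemble.times[-1]
    n_frames = int(math.floor(t_end / imaging.frame_interval + 1e-9)) + 1
    frame_times = np.arange(n_frames) * imaging.frame_interval

    idx = []
    for t in frame_times:
        i = int(np.argmin(np.abs(ensemble.times - t)))
        if abs(ensemble.times[i] - t) > 1e-6:
            raise ValueError(
                "frame_interval must be an integer multiple of the "
                "simulation step dt")
        idx.append(i)

    keep = ensemble.fluorescent
    if not np.any(keep):
        warnings.warn("no fluorescent filaments: rendering an all-noise "
                      "movie", RuntimeWarning, stacklevel=2)

    x_edges = (np.arange(w + 1) - w / 2.0) * px
    y_edges = (np.arange(h + 1) - h / 2.0) * px
    sigma_px = imaging.psf_sigma / px

    data = np.empty((n_frames, h, w))
    for f, i in enumerate(idx):
        pos = ensemble.positions[i][keep]
        counts, _, _ = np.histogram2d(pos[:, 1], pos[:, 0],
                                      bins=[y_edges, x_edges])
        if sigma_px > 0:
            counts = gaussian_filter(counts, sigma_px)
        frame = counts * imaging.photons_per_filament
        if noise:
            frame = rng.poisson(np.clip(frame, 0, None)).astype(float)
            if imaging.read_noise_sd > 0:
                frame += rng.normal(scale=imaging.read_noise_sd,
                                    size=frame.shape)
        data[f] = frame

    meta = {
        "pixel_size_um": px,
        "frame_interval_s": imaging.frame_interval,
        "psf_sigma_um": imaging.psf_sigma,
        "photons_per_filament": imaging.photons_per_filament,
        "read_noise_sd": imaging.read_noise_sd,
        "seed": seed,
        "noise": noise,
    }
    return ImageStack(data=data, pixel_size=px, times=frame_times,
                      bleach_time=bleach_time, meta=meta)
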
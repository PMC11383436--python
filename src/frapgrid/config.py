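"""Configuration types for the synthetic grid-photobleach experiment.

All lengths are in micrometres, all times in seconds. Coordinates are
network-centered: the origin is the center of contraction of the filament
network, and the rendered image field is centered on it by default.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass
from typing import Optional

ADVECTION_MODES = ("eulerian_ou", "linearized_lagrangian")


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValueError(msg)


def _finite(*vals: float) -> bool:
    return all(math.isfinite(float(v)) for v in vals)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the point-filament network simulation.

    The network is a disk of radius ``network_radius`` filled uniformly with
    ``n_filaments`` point filaments. Filaments are advected by the radially
    linear inward field v(r) = -alpha * r and diffuse isotropically with
    diffusion constant ``d``.

    Two advection modes are provided:

    ``eulerian_ou``
        Each filament follows the Ornstein-Uhlenbeck SDE
        dX = -alpha X dt + sqrt(2 d) dW, i.e. the particle dual of the
        advection-diffusion equation for the tubulin concentration. Material
        points decay exponentially, r(t) = r0 exp(-alpha t).
    ``linearized_lagrangian``
        The short-time linearization of the same flow: the deterministic map
        x(t) = x0 (1 - alpha t) plus Brownian motion in the co-moving frame.
        Only valid while alpha * t < 1.
    """

    n_filaments: int = 200_000
    network_radius: float = 100.0
    alpha: float = 2.0e-3
    d: float = 1.0e-3
    advection_mode: str = "eulerian_ou"
    t_total: float = 150.0
    dt: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.n_filaments >= 1, "n_filaments must be >= 1")
        _require(_finite(self.network_radius, self.alpha, self.d,
                         self.t_total, self.dt),
                 "simulation parameters must be finite")
        _require(self.network_radius > 0, "network_radius must be > 0")
        _require(self.alpha >= 0, "alpha must be >= 0")
        _require(self.d >= 0, "d must be >= 0")
        _require(0 < self.dt <= self.t_total, "need 0 < dt <= t_total")
        _require(self.advection_mode in ADVECTION_MODES,
                 f"advection_mode must be one of {ADVECTION_MODES}")
        if self.advection_mode == "linearized_lagrangian":
            _require(self.alpha * self.t_total < 1.0,
                     "linearized map is singular for alpha * t_total >= 1")


@dataclass(frozen=True)
class GridBleachSpec:
    """Geometry of the photobleached grid.

    The bleach leaves square fluorescent windows of side ``square_side`` whose
    centers sit on a square lattice of pitch ``pitch`` anchored at
    ``grid_origin``; everything outside the windows is bleached dark. With
    ``extent`` set to an integer n, only the central n x n windows survive
    (windows further out are bleached too); with ``extent`` None the lattice
    is unbounded.
    """

    square_side: float = 12.0
    pitch: float = 25.0
    grid_origin: tuple[float, float] = (0.0, 0.0)
    bleach_time: float = 0.0
    extent: Optional[int] = None

    def __post_init__(self) -> None:
        _require(0 < self.square_side < self.pitch,
                 "need 0 < square_side < pitch")
        if self.extent is not None:
            _require(self.extent >= 1, "extent must be >= 1 or None")


@dataclass(frozen=True)
class ImagingConfig:
    """Microscope rendering model.

    Each fluorescent filament contributes a Gaussian point-spread function of
    width ``psf_sigma`` carrying ``photons_per_filament`` expected photons;
    frames are binned to ``pixel_size`` pixels, subjected to Poisson shot
    noise and additive Gaussian read noise.
    """

    pixel_size: float = 0.5
    frame_interval: float = 10.0
    psf_sigma: float = 0.5
    photons_per_filament: float = 80.0
    read_noise_sd: float = 2.0
    field_size: tuple[int, int] = (512, 512)

    def __post_init__(self) -> None:
        _require(self.pixel_size > 0, "pixel_size must be > 0")
        _require(self.frame_interval > 0, "frame_interval must be > 0")
        _require(self.psf_sigma >= 0, "psf_sigma must be >= 0")
        _require(self.photons_per_filament >= 0,
                 "photons_per_filament must be >= 0")
        _require(self.read_noise_sd >= 0, "read_noise_sd must be >= 0")


def config_to_dict(cfg) -> dict:
    """Serialize any of the config dataclasses to a plain dict."""
    d = asdict(cfg)
    for k, v in d.items():
        if isinstance(v, tuple):
            d[k] = list(v)
    return d
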
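"""Segmentation of fluorescent unit cells in grid-photobleached frames.

The same operator (Gaussian smooth, bimodal-midpoint threshold, connected
components) measures areas both on rendered microscope frames and on
concentration fields produced by the advection-diffusion solver, so model
and measurement are compared through one consistent definition of "area".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import find_contours
from skimage.measure import label as cc_label
from skimage.measure import regionprops

__all__ = [
    "Region",
    "bimodal_midpoint_threshold",
    "segment_unit_cells",
    "measure_central_area",
]


@dataclass(frozen=True)
class Region:
    """A segmented fluorescent unit cell in one frame."""

    label: int
    centroid_um: tuple[float, float]  # (x, y), image-centered frame
    area_um2: float
    centroid_px: tuple[float, float]  # (row, col)


def _class_mode(values: np.ndarray, bins: int = 64) -> float:
    hist, edges = np.histogram(values, bins=bins)
    i = int(np.argmax(hist))
    return 0.5 * (edges[i] + edges[i + 1])


def bimodal_midpoint_threshold(img: np.ndarray) -> float:
    """Threshold halfway between the two intensity modes of a grid image.

    The histogram of a photobleached grid frame is bimodal: a dark mode from
    the bleached lines (and any unilluminated surround) and a bright mode
    from the fluorescent plateaus. The threshold is the midpoint of the two
    modal intensities; Otsu's threshold splits the classes and serves as the
    fallback when the modes are degenerate.
    """
    flat = np.asarray(img, dtype=float).ravel()
    if flat.max() <= flat.min():
        return flat.max()
    t = threshold_otsu(flat)
    lo = flat[flat < t]
    hi = flat[flat >= t]
    if lo.size == 0 or hi.size == 0:
        return t
    lo_mode = _class_mode(lo)
    hi_mode = _class_mode(hi)
    if not hi_mode > lo_mode:
        return t
    return 0.5 * (lo_mode + hi_mode)


def _binary_grid_mask(frame: np.ndarray, smooth_sigma_px: float,
                      threshold: float | None = None):
    smoothed = ndimage.gaussian_filter(np.asarray(frame, dtype=float),
                                       smooth_sigma_px) \
        if smooth_sigma_px > 0 else np.asarray(frame, dtype=float)
    thr = bimodal_midpoint_threshold(smoothed) if threshold is None \
        else threshold
    mask = smoothed > thr
    mask = ndimage.binary_fill_holes(mask)
    return mask, smoothed


def segment_unit_cells(frame: np.ndarray,
                       pixel_size: float,
                       smooth_sigma_px: float = 1.0,
                       area_range: tuple[float, float] = (25.0, 400.0),
                       exclude_border: bool = True,
                       threshold: float | None = None,
                       subpixel_areas: bool = False) -> list[Region]:
    """Detect fluorescent unit cells in a single post-bleach frame.

    Pipeline: Gaussian smooth (``smooth_sigma_px``), threshold at the
    midpoint between the modal bleached-line and plateau intensities,
    fill holes, 8-connected components; keep regions whose area falls in
    ``area_range`` (um^2) and, with ``exclude_border``, whose bounding box
    does not touch the frame edge. Centroids are intensity-weighted on the
    smoothed frame and reported in image-centered micrometres.

    When tracking a movie, pass the ``threshold`` measured on the first
    post-bleach frame so the intensity level that defines "fluorescent"
    stays anchored there: as the network compresses (plateau rising) and
    the bleached lines refill by diffusion, a per-frame adaptive threshold
    would slide up with the plateau and hide the diffusive spread that this
    measurement exists to capture.

    With ``subpixel_areas`` the reported area of each kept region is
    re-measured by tracing the threshold-level contour around its centroid
    (marching squares), which is free of the one-pixel quantization and the
    connectivity/hole-filling asymmetries of plain pixel counting; detection
    and filtering still operate on the pixel mask.

    An empty result is valid (e.g. a pre-bleach or all-noise frame).
    """
    frame = np.asarray(frame, dtype=float)
    h, w = frame.shape
    mask, smoothed = _binary_grid_mask(frame, smooth_sigma_px, threshold)
    thr_used = bimodal_midpoint_threshold(smoothed) if threshold is None \
        else threshold
    labels = cc_label(mask, connectivity=2)
    regions: list[Region] = []
    for rp in regionprops(labels, intensity_image=smoothed):
        area = rp.area * pixel_size**2
        if not (area_range[0] <= area <= area_range[1]):
            continue
        r0, c0, r1, c1 = rp.bbox
        if exclude_border and (r0 == 0 or c0 == 0 or r1 == h or c1 == w):
            continue
        row, col = rp.centroid_weighted
        if subpixel_areas:
            m = 4
            rr0, cc0 = max(r0 - m, 0), max(c0 - m, 0)
            crop = smoothed[rr0:min(r1 + m, h), cc0:min(c1 + m, w)]
            a_sub = measure_central_area(
                crop, pixel_size, smooth_sigma_um=0.0,
                center_px=(row - rr0, col - cc0), threshold=thr_used,
                subpixel=True)
            if a_sub > 0:
                area = a_sub
        x = (col + 0.5 - w / 2.0) * pixel_size
        y = (row + 0.5 - h / 2.0) * pixel_size
        regions.append(Region(label=rp.label, centroid_um=(x, y),
                              area_um2=area, centroid_px=(row, col)))
    return regions


def _point_in_polygon(poly: np.ndarray, point: tuple[float, float]) -> bool:
    """Even-odd ray-casting test; ``poly`` is (N, 2) of (row, col)."""
    r, c = point
    rs = poly[:, 0]
    cs = poly[:, 1]
    rs2 = np.roll(rs, -1)
    cs2 = np.roll(cs, -1)
    crosses = (rs > r) != (rs2 > r)
    with np.errstate(divide="ignore", invalid="ignore"):
        c_int = cs + (r - rs) / (rs2 - rs) * (cs2 - cs)
    return bool(np.sum(crosses & (c_int > c)) % 2)


def _shoelace(poly: np.ndarray) -> float:
    r = poly[:, 0]
    c = poly[:, 1]
    return 0.5 * abs(float(np.dot(r, np.roll(c, -1)) -
                           np.dot(c, np.roll(r, -1))))


def threshold_contour_areas(smoothed: np.ndarray, threshold: float,
                            points: np.ndarray, spacing: float
                            ) -> np.ndarray:
    """Areas (um^2) of the threshold-level contours enclosing each point.

    Traces the marching-squares contours once and, for every (row, col)
    point, returns the area of the innermost closed contour containing it
    (0.0 where the point lies outside all closed contours). Vectorized
    companion to :func:`measure_central_area` for measuring many unit
    cells on one frame.
    """
    polys = []
    for contour in find_contours(smoothed, threshold):
        if not np.allclose(contour[0], contour[-1]):
            continue
        lo = contour.min(axis=0)
        hi = contour.max(axis=0)
        polys.append((lo, hi, contour, _shoelace(contour)))
    out = np.zeros(len(points))
    for i, pt in enumerate(points):
        best = None
        for lo, hi, poly, area in polys:
            if not (lo[0] <= pt[0] <= hi[0] and lo[1] <= pt[1] <= hi[1]):
                continue
            if (best is None or area < best) and _point_in_polygon(poly, pt):
                best = area
        if best is not None:
            out[i] = best * spacing**2
    return out


def measure_central_area(values: np.ndarray,
                         spacing: float,
                         smooth_sigma_um: float = 0.5,
                         center_px: tuple[float, float] | None = None,
                         threshold: float | None = None,
                         subpixel: bool = False) -> float:
    """Area (um^2) of the connected bright component containing a point.

    Applies the unit-cell segmentation operator (smooth at
    ``smooth_sigma_um`` physical width, bimodal-midpoint threshold unless a
    fixed ``threshold`` is given, 8-connected components) and returns the
    area of the component covering ``center_px`` (row, col; defaults to the
    array center). Returns 0.0 if that point is below threshold.

    With ``subpixel`` the boundary is traced by marching squares at the
    threshold level and the polygon area returned; this removes the
    one-pixel-ring quantization of plain pixel counting (pixel counting is
    unbiased against it, just stepped) and is used when deterministic model
    fields are measured.
    """
    values = np.asarray(values, dtype=float)
    if center_px is None:
        center_px = ((values.shape[0] - 1) / 2.0, (values.shape[1] - 1) / 2.0)
    sigma_px = smooth_sigma_um / spacing
    if subpixel:
        smoothed = ndimage.gaussian_filter(values, sigma_px) \
            if sigma_px > 0 else values
        thr = bimodal_midpoint_threshold(smoothed) if threshold is None \
            else threshold
        best = None
        for contour in find_contours(smoothed, thr):
            if not np.allclose(contour[0], contour[-1]):
                continue  # open contour touching the border
            if not _point_in_polygon(contour, center_px):
                continue
            a = _shoelace(contour)
            if best is None or a < best:
                best = a  # innermost enclosing contour
        return float(best) * spacing**2 if best is not None else 0.0
    mask, _ = _binary_grid_mask(values, sigma_px, threshold)
    labels = cc_label(mask, connectivity=2)
    r = int(round(center_px[0]))
    c = int(round(center_px[1]))
    r = min(max(r, 0), values.shape[0] - 1)
    c = min(max(c, 0), values.shape[1] - 1)
    lab = labels[r, c]
    if lab == 0:
        return 0.0
    return float(np.count_nonzero(labels == lab)) * spacing**2
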
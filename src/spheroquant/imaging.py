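"""Per-frame spheroid quantification.

A :class:`Frame` carries a phase-contrast-like channel and a propidium-iodide
(PI) fluorescence channel at a known pixel size (default 1 µm/pixel).  The
operations here reproduce the standard spheroid-assay measurements: classical
segmentation of the spheroid body, the mean of 36 diameters through the
centre of mass (one every 5°), mean PI intensity, and angle-averaged radial
PI line profiles.

Coordinate convention: arrays are indexed (row, col) with the origin at the
top-left; angles are measured counter-clockwise from the +col axis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import filters, morphology

__all__ = [
    "Frame",
    "SpheroidMask",
    "ShapeMetrics",
    "RadialProfile",
    "SegmentationConfig",
    "NoSpheroidError",
    "segment_spheroid",
    "measure_diameters",
    "mean_fluorescence",
    "radial_profile",
    "quantify_frame",
    "metrics_to_dataframe",
]

N_DIAMETERS = 36  # every 5° over 180°; each line yields one full diameter


class NoSpheroidError(ValueError):
    """Raised when no foreground object is found in a frame."""


@dataclass
class Frame:
    """One two-channel microscopy frame."""

    phase: np.ndarray
    pi: np.ndarray
    pixel_size: float = 1.0  # µm / pixel
    time_post_treatment: float = 0.0  # hours
    frame_id: str = ""

    def __post_init__(self):
        self.phase = np.asarray(self.phase, dtype=float)
        self.pi = np.asarray(self.pi, dtype=float)
        if self.phase.shape != self.pi.shape:
            raise ValueError("phase and PI channels must share a shape")
        if self.phase.ndim != 2:
            raise ValueError("channels must be 2-D")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")


@dataclass
class SpheroidMask:
    """Binary mask of the main spheroid body (single connected component)."""

    mask: np.ndarray
    n_components_raw: int = 1  # components before the largest-only rule

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        if not self.mask.any():
            raise NoSpheroidError("mask is empty")

    @property
    def fragmented(self) -> bool:
        """True when the thresholded frame contained several bodies."""
        return self.n_components_raw > 1


@dataclass
class ShapeMetrics:
    """Centroid, diameters and area of one segmented spheroid."""

    centroid: tuple[float, float]  # (row, col), pixels
    diameters: np.ndarray  # 36 values, µm
    mean_diameter: float  # µm
    area: float  # µm²
    fragmented: bool = False

    def __post_init__(self):
        self.diameters = np.asarray(self.diameters, dtype=float)
        if self.diameters.shape != (N_DIAMETERS,):
            raise ValueError(f"expected {N_DIAMETERS} diameters")


@dataclass
class RadialProfile:
    """Angle-averaged PI intensity versus radius from the centre of mass."""

    radius: np.ndarray  # pixels, 0, 1, 2, ...
    intensity: np.ndarray

    def __post_init__(self):
        self.radius = np.asarray(self.radius, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.radius.shape != self.intensity.shape:
            raise ValueError("radius and intensity must have equal length")


@dataclass
class SegmentationConfig:
    """Classical segmentation settings.

    The pipeline is: Gaussian smooth -> Otsu threshold -> morphological
    closing -> hole fill -> largest connected component.  ``min_area_px``
    removes speckle before the component rule; ``include_corona`` dilates
    the mask and re-merges nearby debris, for studying the shed-cell corona
    together with the main body.
    """

    smooth_sigma: float = 2.0
    closing_radius: int = 2
    min_area_px: int = 16
    include_corona: bool = False
    corona_dilation_px: int = 10


def segment_spheroid(
    frame: Frame, config: SegmentationConfig | None = None
) -> SpheroidMask:
    """Segment the main spheroid body from the phase channel.

    Deterministic classical pipeline (see :class:`SegmentationConfig`).
    Shed-cell debris around the body is excluded by the largest-component
    rule unless ``config.include_corona`` is set.

    Raises :class:`NoSpheroidError` when no foreground is found.
    """
    config = config or SegmentationConfig()
    img = frame.phase
    smoothed = ndimage.gaussian_filter(img, config.smooth_sigma)
    if np.ptp(smoothed) == 0:
        raise NoSpheroidError("no spheroid detected: constant image")
    thr = filters.threshold_otsu(smoothed)
    fg = smoothed > thr
    if config.closing_radius > 0:
        fg = morphology.closing(fg, morphology.disk(config.closing_radius))
    fg = ndimage.binary_fill_holes(fg)
    labels, n = ndimage.label(fg)
    if n == 0:
        raise NoSpheroidError("no spheroid detected")
    sizes = np.bincount(labels.ravel())[1:]
    small = np.nonzero(sizes < config.min_area_px)[0] + 1
    if small.size:
        fg[np.isin(labels, small)] = False
        labels, n = ndimage.label(fg)
        if n == 0:
            raise NoSpheroidError("no spheroid detected")
        sizes = np.bincount(labels.ravel())[1:]
    main = labels == (int(np.argmax(sizes)) + 1)
    if config.include_corona:
        grown = morphology.dilation(
            main, morphology.disk(config.corona_dilation_px)
        )
        keep = np.unique(labels[grown & fg])
        main = np.isin(labels, keep[keep > 0])
        main = ndimage.binary_fill_holes(main)
    return SpheroidMask(mask=main, n_components_raw=int(n))


def _outermost_crossing(
    mask_f: np.ndarray, centroid: tuple[float, float], angle: float,
    coarse_step: float = 0.5,
) -> float:
    """Distance (px) from centroid to the outermost mask boundary along a ray.

    The mask is sampled with bilinear interpolation; the outermost sample at
    or above 0.5 is refined by bisection against its first outside neighbour,
    giving sub-pixel localisation.  Returns 0 when the ray never meets the
    mask (centroid outside a ring limb, say).
    """
    r0, c0 = centroid
    dr, dc = -np.sin(angle), np.cos(angle)
    nrow, ncol = mask_f.shape
    # max in-bounds travel along the ray
    tmax = np.hypot(nrow, ncol)
    ts = np.arange(0.0, tmax + coarse_step, coarse_step)
    rows = r0 + ts * dr
    cols = c0 + ts * dc
    inside = (rows >= 0) & (rows <= nrow - 1) & (cols >= 0) & (cols <= ncol - 1)
    if not inside.any():
        return 0.0
    ts = ts[inside]
    vals = ndimage.map_coordinates(
        mask_f, np.vstack([rows[inside], cols[inside]]), order=1, mode="constant"
    )
    hits = np.nonzero(vals >= 0.5)[0]
    if hits.size == 0:
        return 0.0
    i = hits[-1]
    lo = ts[i]
    if i + 1 >= len(ts):
        return float(lo)
    hi = ts[i + 1]

    def val(t: float) -> float:
        return float(ndimage.map_coordinates(
            mask_f, [[r0 + t * dr], [c0 + t * dc]], order=1, mode="constant"
        )[0])

    for _ in range(25):
        mid = 0.5 * (lo + hi)
        if val(mid) >= 0.5:
            lo = mid
        else:
            hi = mid
    return float(0.5 * (lo + hi))


def measure_diameters(mask: SpheroidMask, pixel_size: float = 1.0) -> ShapeMetrics:
    """36 diameters through the centre of mass, every 5° over 180°.

    Each diameter is measured outermost-crossing to outermost-crossing of
    the mask along the line through the centroid, which makes the measure
    robust to interior holes.  A centroid falling outside the mask (ring
    shapes) is flagged with a warning but still measured.
    """
    m = mask.mask
    centroid = ndimage.center_of_mass(m)
    ri, ci = int(round(centroid[0])), int(round(centroid[1]))
    inside = (
        0 <= ri < m.shape[0] and 0 <= ci < m.shape[1] and m[ri, ci]
    )
    if not inside:
        warnings.warn(
            "centroid lies outside the mask; diameters measured regardless",
            stacklevel=2,
        )
    mask_f = m.astype(float)
    diameters = np.empty(N_DIAMETERS)
    for k in range(N_DIAMETERS):
        theta = np.deg2rad(5.0 * k)
        t_plus = _outermost_crossing(mask_f, centroid, theta)
        t_minus = _outermost_crossing(mask_f, centroid, theta + np.pi)
        diameters[k] = (t_plus + t_minus) * pixel_size
    area = float(m.sum()) * pixel_size**2
    return ShapeMetrics(
        centroid=(float(centroid[0]), float(centroid[1])),
        diameters=diameters,
        mean_diameter=float(diameters.mean()),
        area=area,
        fragmented=mask.fragmented,
    )


def mean_fluorescence(
    frame: Frame, region: SpheroidMask | None = None
) -> float:
    """Mean PI intensity, over the whole image or restricted to a mask.

    Whole-image is the default; note that whole-image means depend on the
    field of view and are therefore only comparable between acquisitions
    with identical imaging geometry.
    """
    if region is None:
        return float(frame.pi.mean())
    sel = frame.pi[region.mask]
    if sel.size == 0:
        raise ValueError("empty region")
    return float(sel.mean())


def radial_profile(
    frame: Frame,
    centroid: tuple[float, float],
    gaussian_sigma: float = 2.0,
    n_angles: int = 72,
) -> RadialProfile:
    """Average radial PI line profile through a point.

    The PI channel is Gaussian filtered, then a line profile is read from
    the centroid to the image edge every 360/n_angles degrees at unit-pixel
    steps (bilinear interpolation).  Profiles are aligned at radius 0 and
    averaged point-wise up to the shortest profile length.
    """
    r0, c0 = centroid
    nrow, ncol = frame.pi.shape
    if not (0 <= r0 <= nrow - 1 and 0 <= c0 <= ncol - 1):
        raise ValueError("centroid outside image")
    img = (
        ndimage.gaussian_filter(frame.pi, gaussian_sigma)
        if gaussian_sigma > 0
        else frame.pi
    )
    angles = 2 * np.pi * np.arange(n_angles) / n_angles
    lengths = []
    for theta in angles:
        dr, dc = -np.sin(theta), np.cos(theta)
        limits = []
        if dr > 0:
            limits.append((nrow - 1 - r0) / dr)
        elif dr < 0:
            limits.append(-r0 / dr)
        if dc > 0:
            limits.append((ncol - 1 - c0) / dc)
        elif dc < 0:
            limits.append(-c0 / dc)
        lengths.append(min(limits) if limits else 0.0)
    r_max = int(np.floor(min(lengths)))
    radius = np.arange(r_max + 1, dtype=float)
    acc = np.zeros_like(radius)
    for theta in angles:
        dr, dc = -np.sin(theta), np.cos(theta)
        rows = r0 + radius * dr
        cols = c0 + radius * dc
        acc += ndimage.map_coordinates(img, np.vstack([rows, cols]), order=1)
    return RadialProfile(radius=radius, intensity=acc / n_angles)


# ---------------------------------------------------------------------------
# frame-level convenience and tabular output


def quantify_frame(
    frame: Frame, config: SegmentationConfig | None = None
) -> tuple[ShapeMetrics, float, SpheroidMask]:
    """Segment one frame and return (shape metrics, mean PI, mask)."""
    mask = segment_spheroid(frame, config)
    metrics = measure_diameters(mask, frame.pixel_size)
    pi_mean = mean_fluorescence(frame)
    return metrics, pi_mean, mask


def metrics_to_dataframe(rows: list[dict]) -> pd.DataFrame:
    """Assemble per-frame metric dicts into the canonical CSV layout.

    Columns: frame_id, time_h, centroid_row, centroid_col, mean_diameter_um,
    area_um2, mean_pi, fragmented, d000 ... d175.
    """
    cols = [
        "frame_id", "time_h", "centroid_row", "centroid_col",
        "mean_diameter_um", "area_um2", "mean_pi", "fragmented",
    ] + [f"d{5 * k:03d}" for k in range(N_DIAMETERS)]
    return pd.DataFrame(rows, columns=cols)


def frame_metrics_row(
    frame: Frame, metrics: ShapeMetrics, pi_mean: float
) -> dict:
    row = {
        "frame_id": frame.frame_id,
        "time_h": frame.time_post_treatment,
        "centroid_row": metrics.centroid[0],
        "centroid_col": metrics.centroid[1],
        "mean_diameter_um": metrics.mean_diameter,
        "area_um2": metrics.area,
        "mean_pi": pi_mean,
        "fragmented": metrics.fragmented,
    }
    for k in range(N_DIAMETERS):
        row[f"d{5 * k:03d}"] = metrics.diameters[k]
    return row
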
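"""Foveal center location strategies.

The foveal center is the point of minimum total retinal thickness.  Four
strategies of increasing robustness are implemented:

``none``
    trust fixation and take the scan center (0, 0);
``min``
    raw A-scan of minimum TRT within the central 0.85 mm *radius* region;
``interp_min``
    resample the central 0.85 x 0.85 mm square to a 0.02 mm grid with
    cubic interpolation and take the minimum grid node;
``smooth_min``
    as ``interp_min`` but smooth the resampled window with a 0.05 mm
    radius circular-support mean filter before taking the minimum.

Note the asymmetry, which follows each method's original definition: the
raw-minimum method searches a circular region while the resampling methods
use a square window of the same nominal size.

All minima use deterministic tie-breaking: smallest TRT, then smallest
distance to the scan center, then smallest (B-scan, A-scan) or row-major
grid index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .oct_io import TRTPointCloud

CENTER_METHODS = ("none", "min", "interp_min", "smooth_min")

REGION_RADIUS_MM = 0.85
WINDOW_MM = 0.85
WINDOW_SPACING_MM = 0.02
KERNEL_RADIUS_MM = 0.05

#: thickness differences below this are treated as ties (far below the
#: scanner's 3.87 µm axial resolution; absorbs interpolation round-off)
TIE_TOL_UM = 1e-9


@dataclass(frozen=True)
class FoveaCenter:
    """A located foveal center with the strategy that produced it."""

    x_mm: float
    y_mm: float
    method: str = "none"

    def __post_init__(self) -> None:
        if self.method not in CENTER_METHODS:
            raise ValueError(
                f"unknown center method {self.method!r}; expected one of {CENTER_METHODS}"
            )


def locate_none(cloud: TRTPointCloud) -> FoveaCenter:
    """Assume perfect fixation: the scan center is the foveal center."""
    return FoveaCenter(0.0, 0.0, "none")


def locate_min(cloud: TRTPointCloud, region_radius_mm: float = REGION_RADIUS_MM) -> FoveaCenter:
    """Raw A-scan of minimum TRT inside the central circular region."""
    r2 = cloud.x_mm**2 + cloud.y_mm**2
    inside = np.flatnonzero(r2 <= region_radius_mm**2)
    if inside.size == 0:
        raise ValueError(
            f"no A-scans within {region_radius_mm} mm of the scan center"
        )
    vals = cloud.trt_um[inside]
    winners = inside[vals <= vals.min() + TIE_TOL_UM]
    if winners.size > 1:
        d2 = r2[winners]
        winners = winners[d2 == d2.min()]
        if winners.size > 1 and cloud.bscan_index is not None:
            order = np.lexsort((cloud.ascan_index[winners], cloud.bscan_index[winners]))
            winners = winners[order[:1]]
    k = int(winners[0])
    return FoveaCenter(float(cloud.x_mm[k]), float(cloud.y_mm[k]), "min")


def _central_window(
    cloud: TRTPointCloud, window_mm: float, spacing_mm: float
) -> tuple[np.ndarray, np.ndarray]:
    """Resample the central square window by cubic interpolation.

    Returns (axis, values) with values indexed [iy, ix].  The axis covers
    the largest symmetric span not exceeding *window_mm*.
    """
    n = int(np.floor(window_mm / spacing_mm + 1e-9)) + 1
    axis = (np.arange(n) - (n - 1) / 2) * spacing_mm
    xx, yy = np.meshgrid(axis, axis)
    values = cloud.interpolator()(xx, yy)
    if not np.all(np.isfinite(values)):
        raise ValueError(
            f"central {window_mm} mm window is not fully covered by the scan data"
        )
    return axis, values


def _grid_argmin(axis: np.ndarray, values: np.ndarray) -> tuple[float, float]:
    """Minimum grid node with distance-to-origin then row-major tie-breaks."""
    flat = values.ravel()
    winners = np.flatnonzero(flat <= flat.min() + TIE_TOL_UM)
    if winners.size > 1:
        iy, ix = np.unravel_index(winners, values.shape)
        d2 = axis[ix] ** 2 + axis[iy] ** 2
        winners = winners[d2 == d2.min()]
    iy, ix = np.unravel_index(int(winners[0]), values.shape)
    return float(axis[ix]), float(axis[iy])


def locate_interp_min(
    cloud: TRTPointCloud,
    window_mm: float = WINDOW_MM,
    spacing_mm: float = WINDOW_SPACING_MM,
) -> FoveaCenter:
    """Minimum of the cubically resampled central window."""
    axis, values = _central_window(cloud, window_mm, spacing_mm)
    x, y = _grid_argmin(axis, values)
    return FoveaCenter(x, y, "interp_min")


def circular_kernel(kernel_radius_mm: float, spacing_mm: float) -> np.ndarray:
    """Binary mask of lattice offsets within the given Euclidean radius.

    With the defaults (0.05 mm radius on a 0.02 mm lattice, i.e. 2.5
    pixels) the mask contains 21 pixels.
    """
    r_px = kernel_radius_mm / spacing_mm
    half = int(np.floor(r_px))
    offs = np.arange(-half, half + 1)
    ox, oy = np.meshgrid(offs, offs)
    return (ox**2 + oy**2) <= r_px**2 + 1e-12


def _circular_mean_filter(values: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Mean over the circular neighbourhood, renormalized at the borders.

    Truncating the kernel at the window edge and dividing by the in-window
    count avoids the downward bias zero-padding would introduce.
    """
    from scipy.ndimage import correlate

    kernel = mask.astype(float)
    num = correlate(values, kernel, mode="constant", cval=0.0)
    den = correlate(np.ones_like(values), kernel, mode="constant", cval=0.0)
    return num / den


def locate_smooth_min(
    cloud: TRTPointCloud,
    window_mm: float = WINDOW_MM,
    spacing_mm: float = WINDOW_SPACING_MM,
    kernel_radius_mm: float = KERNEL_RADIUS_MM,
) -> FoveaCenter:
    """Minimum of the resampled central window after circular mean filtering."""
    axis, values = _central_window(cloud, window_mm, spacing_mm)
    mask = circular_kernel(kernel_radius_mm, spacing_mm)
    smoothed = _circular_mean_filter(values, mask)
    x, y = _grid_argmin(axis, smoothed)
    return FoveaCenter(x, y, "smooth_min")


def locate_center(cloud: TRTPointCloud, method: str, **params) -> FoveaCenter:
    """Dispatch to one of the four strategies by name."""
    dispatch = {
        "none": locate_none,
        "min": locate_min,
        "interp_min": locate_interp_min,
        "smooth_min": locate_smooth_min,
    }
    if method not in dispatch:
        raise ValueError(f"unknown center method {method!r}; expected one of {CENTER_METHODS}")
    return dispatch[method](cloud, **params)
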
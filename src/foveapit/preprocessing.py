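"""TRT map construction and resampling.

Total retinal thickness (TRT) is the ILM-to-BM height difference at each
A-scan.  Downstream analyses consume either an N x N map on a uniform
0.02 mm lattice (alignment comparisons) or a set of 24 radial profiles of
2 mm radius (morphometry and model fitting).  Both are produced from the
scattered per-A-scan samples with triangulation-based C1 piecewise-cubic
(Clough-Tocher) interpolation; cells outside the convex hull of the data
stay undefined (NaN) rather than being extrapolated.

Angular convention: direction 0 points along +x (nasal after orientation
standardization) and angles increase counter-clockwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .oct_io import OCTScan, ScanValidationError, TRTPointCloud
from .center_location import FoveaCenter

GRID_EXTENT_MM = 3.0
GRID_SPACING_MM = 0.02
RADIAL_RADIUS_MM = 2.0
RADIAL_N_DIRECTIONS = 24
RADIAL_STEP_MM = 0.02

#: fraction of radial samples allowed to fall outside the data hull
MAX_UNDEFINED_FRACTION = 0.05


@dataclass
class RegularGrid:
    """TRT map on a uniform square lattice centered at the origin."""

    x_axis: np.ndarray
    y_axis: np.ndarray
    values_um: np.ndarray
    spacing_mm: float

    def __post_init__(self) -> None:
        self.x_axis = np.asarray(self.x_axis, dtype=float)
        self.y_axis = np.asarray(self.y_axis, dtype=float)
        self.values_um = np.asarray(self.values_um, dtype=float)
        for name, ax in (("x_axis", self.x_axis), ("y_axis", self.y_axis)):
            d = np.diff(ax)
            if np.any(d <= 0) or np.any(np.abs(d - self.spacing_mm) > 1e-12):
                raise ValueError(f"{name} must increase uniformly by spacing_mm")
        if self.values_um.shape != (self.y_axis.size, self.x_axis.size):
            raise ValueError(
                f"values_um shape {self.values_um.shape} != "
                f"(len(y_axis), len(x_axis)) = {(self.y_axis.size, self.x_axis.size)}"
            )

    @property
    def N(self) -> int:
        if self.x_axis.size != self.y_axis.size:
            raise ValueError("grid is not square")
        return self.x_axis.size

    @property
    def defined_mask(self) -> np.ndarray:
        return np.isfinite(self.values_um)

    def to_frame(self):
        """Long-format table (x_mm, y_mm, trt_um) for inspection/serialization."""
        import pandas as pd

        xx, yy = np.meshgrid(self.x_axis, self.y_axis)
        return pd.DataFrame(
            {"x_mm": xx.ravel(), "y_mm": yy.ravel(), "trt_um": self.values_um.ravel()}
        )


@dataclass
class RadialProfileSet:
    """TRT along uniformly spaced angular directions from the foveal center.

    ``values_um[k, i]`` is the thickness in direction ``angles_rad[k]`` at
    radius ``radii_mm[i]``; row 0 of every direction is the shared center
    sample.  Undefined (out-of-hull) samples are NaN.
    """

    angles_rad: np.ndarray
    radii_mm: np.ndarray
    values_um: np.ndarray
    center: FoveaCenter

    def __post_init__(self) -> None:
        self.angles_rad = np.asarray(self.angles_rad, dtype=float)
        self.radii_mm = np.asarray(self.radii_mm, dtype=float)
        self.values_um = np.asarray(self.values_um, dtype=float)
        if self.values_um.shape != (self.angles_rad.size, self.radii_mm.size):
            raise ValueError("values_um must be (n_directions, n_radii)")
        if self.radii_mm[0] != 0.0:
            raise ValueError("radii must start at exactly 0")
        center_col = self.values_um[:, 0]
        finite = center_col[np.isfinite(center_col)]
        if finite.size and not np.all(finite == finite[0]):
            raise ValueError("all directions must share the center sample")

    @property
    def n_directions(self) -> int:
        return self.angles_rad.size

    @property
    def step_mm(self) -> float:
        return float(self.radii_mm[1] - self.radii_mm[0])

    def is_complete(self) -> bool:
        return bool(np.all(np.isfinite(self.values_um)))

    def to_frame(self):
        """Long-format table (direction, angle_rad, radius_mm, trt_um)."""
        import pandas as pd

        k, i = np.meshgrid(
            np.arange(self.n_directions), np.arange(self.radii_mm.size), indexing="ij"
        )
        return pd.DataFrame(
            {
                "direction": k.ravel(),
                "angle_rad": self.angles_rad[k.ravel()],
                "radius_mm": self.radii_mm[i.ravel()],
                "trt_um": self.values_um.ravel(),
            }
        )


def compute_trt(scan: OCTScan) -> TRTPointCloud:
    """TRT = ILM - BM per A-scan.

    A non-positive thickness anywhere signals a layer-segmentation failure
    and raises :class:`ScanValidationError` listing the offending A-scans.
    """
    trt = scan.ilm_um - scan.bm_um
    bad = np.argwhere(trt <= 0)
    if bad.size:
        listing = ", ".join(f"(bscan={b}, ascan={a})" for b, a in bad[:10])
        more = "" if len(bad) <= 10 else f" and {len(bad) - 10} more"
        raise ScanValidationError(
            f"non-positive TRT at {len(bad)} A-scan(s): {listing}{more}"
        )
    nb, na = scan.meta.n_bscans, scan.meta.n_ascans
    bidx, aidx = np.meshgrid(np.arange(nb), np.arange(na), indexing="ij")
    return TRTPointCloud(
        scan.x_mm.ravel(), scan.y_mm.ravel(), trt.ravel(),
        bidx.ravel(), aidx.ravel(),
    )


def standardize_orientation(cloud: TRTPointCloud, eye: str) -> TRTPointCloud:
    """Flip left eyes (OS) so every cloud shares the right-eye convention.

    OD clouds are returned unchanged (a copy); OS clouds have x negated,
    mapping temporal/nasal sides onto the OD layout.  Applying the OS flip
    twice is the identity.
    """
    if eye not in ("OD", "OS"):
        raise ValueError(f"unknown eye code {eye!r}; expected 'OD' or 'OS'")
    x = -cloud.x_mm if eye == "OS" else cloud.x_mm.copy()
    return TRTPointCloud(
        x, cloud.y_mm.copy(), cloud.trt_um.copy(),
        None if cloud.bscan_index is None else cloud.bscan_index.copy(),
        None if cloud.ascan_index is None else cloud.ascan_index.copy(),
    )


def recenter(cloud: TRTPointCloud, center: FoveaCenter) -> TRTPointCloud:
    """Translate the cloud so the located foveal center moves to (0, 0)."""
    if not (np.isfinite(center.x_mm) and np.isfinite(center.y_mm)):
        raise ValueError("center coordinates must be finite")
    return cloud.translated(-center.x_mm, -center.y_mm)


def _square_axis(extent_mm: float, spacing_mm: float) -> np.ndarray:
    n = int(np.floor(extent_mm / spacing_mm + 1e-9)) + 1
    return (np.arange(n) - (n - 1) / 2) * spacing_mm


def resample_regular(
    cloud: TRTPointCloud,
    extent_mm: float = GRID_EXTENT_MM,
    spacing_mm: float = GRID_SPACING_MM,
    *,
    center: FoveaCenter | None = None,
) -> RegularGrid:
    """Interpolate the cloud onto a square grid centered at the origin.

    ``extent_mm`` is the total side length, so the default 3 mm grid spans
    x, y in [-1.5, 1.5] mm with 151 samples per axis.  If *center* is given
    the grid is evaluated about that point in the cloud's frame — exactly
    equivalent to ``resample_regular(recenter(cloud, center))`` but reusing
    the cloud's cached triangulation.
    """
    if len(cloud) < 3:
        raise ValueError("need at least 3 points to interpolate")
    axis = _square_axis(extent_mm, spacing_mm)
    cx, cy = (center.x_mm, center.y_mm) if center is not None else (0.0, 0.0)
    xx, yy = np.meshgrid(axis + cx, axis + cy)
    try:
        interp = cloud.interpolator()
    except Exception as exc:
        raise ValueError(f"degenerate point geometry: {exc}") from exc
    values = interp(xx, yy)
    return RegularGrid(x_axis=axis, y_axis=axis, values_um=values, spacing_mm=spacing_mm)


def resample_radial(
    cloud: TRTPointCloud,
    radius_mm: float = RADIAL_RADIUS_MM,
    n_directions: int = RADIAL_N_DIRECTIONS,
    step_mm: float = RADIAL_STEP_MM,
    *,
    center: FoveaCenter | None = None,
) -> RadialProfileSet:
    """Sample TRT along radial spokes from the foveal center.

    The cloud is assumed recentered (foveal center at the origin) unless
    *center* is provided, in which case spokes emanate from that point.
    Samples outside the data hull are NaN; if more than 5% of samples are
    undefined the scan is considered too decentered and an error is raised.
    """
    if len(cloud) < 3:
        raise ValueError("need at least 3 points to interpolate")
    cx, cy = (center.x_mm, center.y_mm) if center is not None else (0.0, 0.0)
    angles = 2 * np.pi * np.arange(n_directions) / n_directions
    n_r = int(np.floor(radius_mm / step_mm + 1e-9)) + 1
    radii = np.arange(n_r) * step_mm
    radii[-1] = radius_mm  # exact endpoint
    interp = cloud.interpolator()

    xx = cx + radii[None, :] * np.cos(angles)[:, None]
    yy = cy + radii[None, :] * np.sin(angles)[:, None]
    values = interp(xx, yy)
    # one evaluation of the origin shared by every direction
    center_val = float(interp(cx, cy))
    values[:, 0] = center_val

    undefined = ~np.isfinite(values)
    frac = undefined.mean()
    if frac > MAX_UNDEFINED_FRACTION:
        raise ValueError(
            f"{frac:.1%} of radial samples fall outside the data hull "
            f"(limit {MAX_UNDEFINED_FRACTION:.0%}); scan too decentered"
        )
    fc = FoveaCenter(cx, cy, center.method if center is not None else "none")
    return RadialProfileSet(angles_rad=angles, radii_mm=radii, values_um=values, center=fc)
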
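"""Shared fixtures-as-functions for the test suite."""

from __future__ import annotations

import numpy as np

from foveapit.center_location import FoveaCenter
from foveapit.oct_io import TRTPointCloud
from foveapit.preprocessing import RadialProfileSet

ANGLES_24 = 2 * np.pi * np.arange(24) / 24
RADII_101 = np.round(np.arange(101) * 0.02, 10)


def profile_set(values: np.ndarray) -> RadialProfileSet:
    """Wrap a 24x101 value matrix as a radial profile set at the origin."""
    return RadialProfileSet(ANGLES_24, RADII_101, values, FoveaCenter(0.0, 0.0, "none"))


def profiles_from_radial(f) -> RadialProfileSet:
    """Profile set from a radially symmetric thickness function f(r)."""
    return profile_set(np.tile(f(RADII_101), (24, 1)))


def profiles_from_diametric(f) -> RadialProfileSet:
    """Profile set whose 12 diametric lines all equal f(x), x in [-2, 2]."""
    v = np.empty((24, 101))
    for k in range(12):
        v[k] = f(RADII_101)
        v[k + 12] = f(-RADII_101)
    return profile_set(v)


def dense_pit_cloud(
    thickness,  # callable T(x, y)
    half_extent_mm: float = 2.5,
    n_per_axis: int = 101,
) -> TRTPointCloud:
    """Scattered cloud sampling an analytic surface on a fine square lattice."""
    ax = np.linspace(-half_extent_mm, half_extent_mm, n_per_axis)
    xx, yy = np.meshgrid(ax, ax)
    bidx, aidx = np.meshgrid(np.arange(n_per_axis), np.arange(n_per_axis), indexing="ij")
    return TRTPointCloud(
        xx.ravel(), yy.ravel(), thickness(xx, yy).ravel(),
        bidx.ravel(), aidx.ravel(),
    )


def gaussian_pit(cx: float = 0.0, cy: float = 0.0, depth: float = 100.0,
                 width2: float = 0.18, base: float = 330.0):
    """Smooth radially symmetric pit T(x, y) with its minimum at (cx, cy)."""

    def T(x, y):
        r2 = (np.asarray(x) - cx) ** 2 + (np.asarray(y) - cy) ** 2
        return base - depth * np.exp(-r2 / width2)

    return T
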
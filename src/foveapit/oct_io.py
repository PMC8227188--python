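"""OCT scan data model and a plain-text interchange format.

Scanner exports (e.g. Spectralis ``.vol``) are proprietary; this module
defines the open format the rest of the pipeline consumes: a TSV table of
per-A-scan records plus a JSON sidecar with acquisition metadata.

Interchange layout
------------------
``<name>.tsv`` — header row and columns ``bscan_index`` (0-based int),
``ascan_index`` (0-based int), ``x_mm``, ``y_mm``, ``ilm_um``, ``bm_um``
and optionally ``trt_um``.  Coordinates are millimetres in the scanner's
lateral plane with origin at the scan center; heights are micrometres from
a flat reference with Bruch's membrane (BM) below the inner limiting
membrane (ILM).  ``<name>.json`` — ``{pattern, eye, n_bscans, n_ascans,
axial_resolution_um, scan_id, subject_id}``.

Values are serialized with 6 significant digits; at the scanner's 3.87 µm
axial resolution finer digits carry no information.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

REQUIRED_COLUMNS = ("bscan_index", "ascan_index", "x_mm", "y_mm", "ilm_um", "bm_um")

#: default acquisition geometries (B-scans x A-scans per B-scan)
PATTERN_DEFAULTS = {"raster": (25, 512), "star": (12, 768)}

AXIAL_RESOLUTION_UM = 3.87


class InterchangeFormatError(ValueError):
    """A file does not conform to the TSV + JSON-sidecar interchange format."""


class ScanValidationError(ValueError):
    """Scan data violates a structural invariant (geometry, finiteness, ILM >= BM)."""


@dataclass
class ScanMeta:
    """Acquisition metadata for one OCT volume scan."""

    pattern: str = "raster"
    eye: str = "OD"
    n_bscans: int | None = None
    n_ascans: int | None = None
    axial_resolution_um: float = AXIAL_RESOLUTION_UM
    scan_id: str = ""
    subject_id: str = ""

    def __post_init__(self) -> None:
        if self.pattern not in PATTERN_DEFAULTS:
            raise ScanValidationError(
                f"unknown pattern {self.pattern!r}; expected one of {sorted(PATTERN_DEFAULTS)}"
            )
        if self.eye not in ("OD", "OS"):
            raise ScanValidationError(f"unknown eye code {self.eye!r}; expected 'OD' or 'OS'")
        nb, na = PATTERN_DEFAULTS[self.pattern]
        if self.n_bscans is None:
            self.n_bscans = nb
        if self.n_ascans is None:
            self.n_ascans = na
        if self.n_bscans <= 0 or self.n_ascans <= 0:
            raise ScanValidationError("n_bscans and n_ascans must be positive")
        if not (self.axial_resolution_um > 0):
            raise ScanValidationError("axial_resolution_um must be positive")

    def to_dict(self) -> dict:
        return {
            "pattern": self.pattern,
            "eye": self.eye,
            "n_bscans": int(self.n_bscans),
            "n_ascans": int(self.n_ascans),
            "axial_resolution_um": float(self.axial_resolution_um),
            "scan_id": self.scan_id,
            "subject_id": self.subject_id,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScanMeta":
        return cls(**{k: d[k] for k in cls.__dataclass_fields__ if k in d})


@dataclass
class OCTScan:
    """Per-A-scan layer heights with lateral coordinates.

    Arrays are shaped ``(n_bscans, n_ascans)`` which enforces that every
    B-scan carries the same number of A-scan samples.  After orientation
    standardization x runs temporal to nasal and y inferior to superior.
    """

    meta: ScanMeta
    x_mm: np.ndarray
    y_mm: np.ndarray
    ilm_um: np.ndarray
    bm_um: np.ndarray

    def __post_init__(self) -> None:
        shape = (self.meta.n_bscans, self.meta.n_ascans)
        for name in ("x_mm", "y_mm", "ilm_um", "bm_um"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != shape:
                raise ScanValidationError(
                    f"{name} has shape {arr.shape}, expected {shape} from metadata"
                )
            if not np.all(np.isfinite(arr)):
                bad = np.argwhere(~np.isfinite(arr))[0]
                raise ScanValidationError(
                    f"{name} contains a non-finite value at (bscan={bad[0]}, ascan={bad[1]})"
                )
            setattr(self, name, arr)
        below = self.ilm_um < self.bm_um
        if np.any(below):
            bad = np.argwhere(below)[0]
            raise ScanValidationError(
                f"ilm_um < bm_um at (bscan={bad[0]}, ascan={bad[1]}): "
                f"{self.ilm_um[tuple(bad)]:.6g} < {self.bm_um[tuple(bad)]:.6g}"
            )

    @property
    def n_points(self) -> int:
        return self.meta.n_bscans * self.meta.n_ascans

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, OCTScan):
            return NotImplemented
        return self.meta == other.meta and all(
            np.array_equal(getattr(self, n), getattr(other, n))
            for n in ("x_mm", "y_mm", "ilm_um", "bm_um")
        )


@dataclass
class TRTPointCloud:
    """Scattered total-retinal-thickness samples, one triple per A-scan.

    ``bscan_index``/``ascan_index`` track provenance for deterministic
    tie-breaking in center location; they are optional for clouds built
    outside a scan context.
    """

    x_mm: np.ndarray
    y_mm: np.ndarray
    trt_um: np.ndarray
    bscan_index: np.ndarray | None = None
    ascan_index: np.ndarray | None = None
    _interp_cache: object = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.x_mm = np.asarray(self.x_mm, dtype=float).ravel()
        self.y_mm = np.asarray(self.y_mm, dtype=float).ravel()
        self.trt_um = np.asarray(self.trt_um, dtype=float).ravel()
        n = self.x_mm.size
        if self.y_mm.size != n or self.trt_um.size != n:
            raise ScanValidationError("x_mm, y_mm, trt_um must have equal length")
        for name in ("x_mm", "y_mm", "trt_um"):
            arr = getattr(self, name)
            if not np.all(np.isfinite(arr)):
                raise ScanValidationError(f"{name} contains non-finite values")
        if np.any(self.trt_um <= 0):
            idx = np.flatnonzero(self.trt_um <= 0)
            raise ScanValidationError(
                f"non-positive TRT at {idx.size} point(s), first at index {idx[0]}"
            )
        for name in ("bscan_index", "ascan_index"):
            arr = getattr(self, name)
            if arr is not None:
                arr = np.asarray(arr, dtype=int).ravel()
                if arr.size != n:
                    raise ScanValidationError(f"{name} length mismatch")
                setattr(self, name, arr)

    def __len__(self) -> int:
        return self.x_mm.size

    def interpolator(self):
        """Triangulation-based C1 cubic interpolant of the cloud (cached).

        NaN is returned outside the convex hull of the samples.
        """
        if self._interp_cache is None:
            from scipy.interpolate import CloughTocher2DInterpolator

            pts = np.column_stack([self.x_mm, self.y_mm])
            self._interp_cache = CloughTocher2DInterpolator(pts, self.trt_um)
        return self._interp_cache

    def translated(self, dx: float, dy: float) -> "TRTPointCloud":
        return TRTPointCloud(
            self.x_mm + dx, self.y_mm + dy, self.trt_um.copy(),
            None if self.bscan_index is None else self.bscan_index.copy(),
            None if self.ascan_index is None else self.ascan_index.copy(),
        )


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_scan(scan: OCTScan, path: str | Path) -> Path:
    """Serialize *scan* to the interchange TSV (+ JSON sidecar).

    Returns the TSV path.  Numeric cells carry 6 significant digits.
    """
    path = Path(path)
    nb, na = scan.meta.n_bscans, scan.meta.n_ascans
    bidx, aidx = np.meshgrid(np.arange(nb), np.arange(na), indexing="ij")
    df = pd.DataFrame(
        {
            "bscan_index": bidx.ravel(),
            "ascan_index": aidx.ravel(),
            "x_mm": scan.x_mm.ravel(),
            "y_mm": scan.y_mm.ravel(),
            "ilm_um": scan.ilm_um.ravel(),
            "bm_um": scan.bm_um.ravel(),
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
    _sidecar_path(path).write_text(json.dumps(scan.meta.to_dict(), indent=1))
    return path


def read_scan(path: str | Path) -> OCTScan:
    """Parse an interchange-format scan, validating structure and invariants.

    Raises
    ------
    InterchangeFormatError
        Missing files/columns, non-numeric cells, duplicated or missing
        (bscan, ascan) records, inconsistent B-scan lengths.  Messages name
        the offending column or record.
    ScanValidationError
        Structurally well-formed data violating a scan invariant
        (e.g. ``ilm_um < bm_um``), citing the offending row.
    """
    path = Path(path)
    if not path.exists():
        raise InterchangeFormatError(f"no such file: {path}")
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise InterchangeFormatError(f"missing JSON sidecar: {sidecar}")
    try:
        meta = ScanMeta.from_dict(json.loads(sidecar.read_text()))
    except (json.JSONDecodeError, TypeError) as exc:
        raise InterchangeFormatError(f"unreadable sidecar {sidecar}: {exc}") from exc

    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise InterchangeFormatError(f"unreadable TSV {path}: {exc}") from exc
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise InterchangeFormatError(f"{path}: missing column(s) {missing}")
    for col in REQUIRED_COLUMNS:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & df[col].notna()
        if bad.any() or df[col].isna().any():
            row = int(np.flatnonzero(vals.isna())[0])
            raise InterchangeFormatError(
                f"{path}: non-numeric or empty cell in column {col!r} at data row {row}"
            )
        df[col] = vals

    nb, na = meta.n_bscans, meta.n_ascans
    if len(df) != nb * na:
        raise InterchangeFormatError(
            f"{path}: {len(df)} data rows, expected n_bscans*n_ascans = {nb * na}"
        )
    counts = df.groupby("bscan_index").size()
    if not (counts == na).all():
        bad_b = int(counts.index[counts != na][0])
        raise InterchangeFormatError(
            f"{path}: B-scan {bad_b} has {int(counts.loc[bad_b])} A-scans, expected {na}"
        )

    order = np.lexsort((df["ascan_index"].to_numpy(), df["bscan_index"].to_numpy()))
    df = df.iloc[order]
    bidx = df["bscan_index"].to_numpy(dtype=int)
    aidx = df["ascan_index"].to_numpy(dtype=int)
    expect_b, expect_a = np.meshgrid(np.arange(nb), np.arange(na), indexing="ij")
    if not (np.array_equal(bidx, expect_b.ravel()) and np.array_equal(aidx, expect_a.ravel())):
        raise InterchangeFormatError(
            f"{path}: (bscan_index, ascan_index) pairs are not exactly "
            f"{{0..{nb - 1}}} x {{0..{na - 1}}} (duplicate or missing record)"
        )

    def grid(col: str) -> np.ndarray:
        return df[col].to_numpy(dtype=float).reshape(nb, na)

    return OCTScan(
        meta=meta,
        x_mm=grid("x_mm"),
        y_mm=grid("y_mm"),
        ilm_um=grid("ilm_um"),
        bm_um=grid("bm_um"),
    )
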
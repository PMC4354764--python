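"""Core containers and file I/O for dynamic series, ROIs, masks, maps and tables.

Conventions used throughout the package:

* arrays are 0-based ``(row, col)``, row-major; the time axis comes first,
  so a dynamic series is ``(T, H, W)`` with index 0 the pre-contrast phase;
* a pixel's center sits at its integer coordinate (the pixel spans
  ``row - 0.5 .. row + 0.5``);
* NIfTI files store the series with time as the last axis (the NIfTI dim
  order), and acquisition times live in a sidecar JSON ``{"times": [...]}``
  in seconds.  When the sidecar is absent the protocol default of one phase
  every 80 s is assumed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import EmptyRoiError, FormatError

DEFAULT_PHASE_SPACING_S = 80.0

#: canonical column order for cohort tables
COHORT_COLUMNS = (
    "case_id",
    "label",
    "pathway",
    "si_slope",
    "msi",
    "e_initial",
    "e_peak",
    "eser",
    "sep",
    "tic_type",
)


@dataclass
class DceSeries:
    """A single-slice dynamic contrast-enhanced series.

    Parameters
    ----------
    data
        ``(T, H, W)`` signal intensities in arbitrary scanner units;
        ``data[0]`` is the pre-contrast acquisition.
    times
        Acquisition times in seconds, strictly increasing, ``times[0] == 0``.
    case_id
        Free-text case label.
    """

    data: np.ndarray
    times: np.ndarray
    case_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.data.ndim != 3:
            raise FormatError(f"series must be (T, H, W); got shape {self.data.shape}")
        t, h, w = self.data.shape
        if t < 4:
            raise FormatError(f"T < 4: need at least 1 pre + 3 post phases, got T={t}")
        if h < 8 or w < 8:
            raise FormatError(f"image too small: {h}x{w} (need at least 8x8)")
        if self.times.shape != (t,):
            raise FormatError(
                f"times length {self.times.shape} does not match T={t}"
            )
        if not np.all(np.diff(self.times) > 0):
            raise FormatError("times must be strictly increasing")
        if self.times[0] != 0:
            raise FormatError("times[0] must be 0 (pre-contrast)")
        if not np.all(np.isfinite(self.data)):
            raise FormatError("series contains non-finite intensities")

    @property
    def n_phases(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        """Spatial shape ``(H, W)``."""
        return self.data.shape[1:]


@dataclass
class RoiPolygon:
    """User-drawn ROI as an ordered polygon in pixel coordinates (row, col)."""

    vertices: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2:
            raise FormatError("ROI vertices must be an (n, 2) array of (row, col)")
        if len(self.vertices) < 3:
            raise FormatError("ROI polygon needs at least 3 vertices")
        if not np.all(np.isfinite(self.vertices)):
            raise FormatError("ROI vertices must be finite")


@dataclass
class MaskImage:
    """A binary H×W image; ``kind`` distinguishes the user ROI from the lesion."""

    data: np.ndarray
    kind: str = "roi"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 2:
            raise FormatError("mask must be 2-D")
        if self.kind not in ("roi", "lesion"):
            raise FormatError(f"mask kind must be 'roi' or 'lesion', got {self.kind!r}")

    @property
    def n_pixels(self) -> int:
        return int(self.data.sum())


# ---------------------------------------------------------------------------
# ROI rasterization
# ---------------------------------------------------------------------------

def rasterize_roi(poly: RoiPolygon, shape: tuple[int, int]) -> MaskImage:
    """Rasterize a polygon onto an image grid.

    A pixel is included iff its center (at the integer coordinate) lies
    inside the polygon by the even-odd rule; points exactly on the boundary
    count as inside.
    """
    h, w = shape
    verts = poly.vertices
    rows, cols = np.mgrid[0:h, 0:w]
    pr = rows.ravel().astype(float)
    pc = cols.ravel().astype(float)
    inside = np.zeros(pr.shape, dtype=bool)
    boundary = np.zeros(pr.shape, dtype=bool)
    eps = 1e-9
    n = len(verts)
    for i in range(n):
        r1, c1 = verts[i]
        r2, c2 = verts[(i + 1) % n]
        # even-odd ray cast along +col
        crosses = (r1 > pr) != (r2 > pr)
        with np.errstate(divide="ignore", invalid="ignore"):
            c_at = (c2 - c1) * (pr - r1) / (r2 - r1) + c1
        inside ^= crosses & (pc < c_at)
        # on-segment test (collinear within the edge's bounding box)
        cross = (r2 - r1) * (pc - c1) - (c2 - c1) * (pr - r1)
        scale = max(abs(r2 - r1), abs(c2 - c1), 1.0)
        on = (
            (np.abs(cross) <= eps * scale)
            & (pr >= min(r1, r2) - eps)
            & (pr <= max(r1, r2) + eps)
            & (pc >= min(c1, c2) - eps)
            & (pc <= max(c1, c2) + eps)
        )
        boundary |= on
    mask = (inside | boundary).reshape(h, w)
    if not mask.any():
        raise EmptyRoiError("ROI polygon covers no pixel centers")
    return MaskImage(mask, kind="roi")


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".json")
    return path.with_suffix(".json")


def read_series(
    path: str | Path,
    fmt: str | None = None,
    times: np.ndarray | None = None,
    slice_index: int | None = None,
) -> DceSeries:
    """Read a dynamic series from NIfTI (with optional JSON sidecar) or ``.npz``.

    Parameters
    ----------
    path
        ``.nii``/``.nii.gz`` (time last axis) or ``.npz`` with arrays
        ``data`` (T, H, W) and optionally ``times``.
    fmt
        ``"nifti"`` or ``"npz"``; inferred from the extension when omitted.
    times
        Overrides any sidecar/embedded times.
    slice_index
        Required to pick a slice when the NIfTI is a 4-D volume (H, W, Z, T).
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    if fmt is None:
        fmt = "npz" if path.suffix == ".npz" else "nifti"
    if fmt == "npz":
        with np.load(path) as npz:
            if "data" not in npz:
                raise FormatError(f"{path}: npz fixture must contain a 'data' array")
            data = np.asarray(npz["data"], dtype=float)
            if times is None and "times" in npz:
                times = np.asarray(npz["times"], dtype=float)
    elif fmt == "nifti":
        img = nib.load(str(path))
        arr = np.asarray(img.dataobj, dtype=float)
        if arr.ndim == 4:
            if slice_index is None:
                raise FormatError(
                    f"{path}: 4-D volume; pass slice_index to select the analysed slice"
                )
            arr = arr[:, :, slice_index, :]
        if arr.ndim != 3:
            raise FormatError(f"{path}: expected 3-D (H, W, T) data, got {arr.shape}")
        data = np.moveaxis(arr, -1, 0)
        if times is None:
            sidecar = _sidecar_path(path)
            if sidecar.exists():
                meta = json.loads(sidecar.read_text())
                if "times" in meta:
                    times = np.asarray(meta["times"], dtype=float)
    else:
        raise FormatError(f"unknown series format {fmt!r}")
    if times is None:
        times = DEFAULT_PHASE_SPACING_S * np.arange(data.shape[0])
    case_id = path.name.split(".")[0]
    return DceSeries(data=data, times=np.asarray(times, float), case_id=case_id)


def read_roi(path: str | Path) -> RoiPolygon:
    """Read a ROI polygon from JSON ``{"vertices": [[row, col], ...]}``."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    doc = json.loads(path.read_text())
    if "vertices" not in doc:
        raise FormatError(f"{path}: ROI JSON must contain 'vertices'")
    return RoiPolygon(np.asarray(doc["vertices"], dtype=float))


def read_mask(path: str | Path, kind: str = "lesion") -> MaskImage:
    img = nib.load(str(Path(path)))
    arr = np.asarray(img.dataobj)
    return MaskImage(arr > 0, kind=kind)


def read_map(path: str | Path) -> np.ndarray:
    img = nib.load(str(Path(path)))
    return np.asarray(img.dataobj, dtype=float)


def read_cohort(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"case_id", "label", "pathway"} - set(df.columns)
    if missing:
        raise FormatError(f"cohort table missing columns: {sorted(missing)}")
    if df["label"].isna().any():
        raise FormatError("cohort table has missing truth labels")
    dup = df.duplicated(subset=["case_id", "pathway"])
    if dup.any():
        raise FormatError("cohort table has duplicate (case_id, pathway) rows")
    return df


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def write_series(series: DceSeries, path: str | Path) -> None:
    path = Path(path)
    img = nib.Nifti1Image(np.moveaxis(series.data, 0, -1), affine=np.eye(4))
    nib.save(img, str(path))
    _sidecar_path(path).write_text(
        json.dumps({"times": list(series.times)}) + "\n"
    )


def write_mask(mask: MaskImage, path: str | Path) -> None:
    img = nib.Nifti1Image(mask.data.astype(np.uint8), affine=np.eye(4))
    nib.save(img, str(Path(path)))


def write_map(values: np.ndarray, path: str | Path) -> None:
    """Write a parameter map as float64 NIfTI; NaN marks undefined pixels."""
    img = nib.Nifti1Image(np.asarray(values, dtype=np.float64), affine=np.eye(4))
    nib.save(img, str(Path(path)))


def write_roi(poly: RoiPolygon, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps({"vertices": [[float(r), float(c)] for r, c in poly.vertices]})
        + "\n"
    )


def write_cohort(df: pd.DataFrame, path: str | Path) -> None:
    """Write a cohort table as CSV (kinetic parameters at 2 decimals)."""
    out = df.copy()
    for col in out.columns:
        if out[col].dtype.kind == "f":
            out[col] = out[col].round(2)
    out.to_csv(path, index=False)


def write_roc(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False, float_format="%.6g")
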
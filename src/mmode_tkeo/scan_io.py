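"""Reading, calibration and cropping of M-mode ultrasound scans.

An M-mode scan is a depth-versus-time intensity image: each pixel row is a
thin tissue layer at a fixed depth beneath the skin, each pixel column is one
acquisition instant.  All downstream processing relies on the conventions
fixed here:

* rows and columns are 0-based;
* row ``r`` sits at depth ``depth_offset_mm + r * mm_per_row`` (row 0 nearest
  the skin);
* column ``c`` is recorded at time ``c / columns_per_second`` seconds;
* intensities are floats normalised to ``[0, 1]``.

The default calibration matches a portable body-composition scanner operated
in scan mode: 0.042 mm per pixel row and roughly 100 columns per second.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np

__all__ = [
    "ScanCalibration",
    "MModeScan",
    "ScanReadError",
    "read_scan",
    "write_scan",
    "load_calibration",
    "save_calibration",
    "crop_depth",
    "time_axis",
]

#: Rec. 601 luma weights used to collapse RGB scans to one channel.
_LUMA = np.array([0.299, 0.587, 0.114])


class ScanReadError(ValueError):
    """Raised when a scan image cannot be read or fails validation."""


@dataclass(frozen=True)
class ScanCalibration:
    """Geometric and temporal calibration of an M-mode scan.

    Parameters
    ----------
    mm_per_row
        Depth extent of one pixel row, in millimetres.
    columns_per_second
        Temporal sampling rate, in pixel columns per second.
    depth_offset_mm
        Depth of row 0 beneath the skin, in millimetres.
    """

    mm_per_row: float = 0.042
    columns_per_second: float = 100.0
    depth_offset_mm: float = 0.0

    def __post_init__(self) -> None:
        if not self.mm_per_row > 0:
            raise ValueError(f"mm_per_row must be > 0, got {self.mm_per_row}")
        if not self.columns_per_second > 0:
            raise ValueError(
                f"columns_per_second must be > 0, got {self.columns_per_second}"
            )
        if self.depth_offset_mm < 0:
            raise ValueError(
                f"depth_offset_mm must be >= 0, got {self.depth_offset_mm}"
            )

    def to_dict(self) -> dict:
        return {
            "mm_per_row": self.mm_per_row,
            "columns_per_second": self.columns_per_second,
            "depth_offset_mm": self.depth_offset_mm,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScanCalibration":
        return cls(
            mm_per_row=float(d["mm_per_row"]),
            columns_per_second=float(d["columns_per_second"]),
            depth_offset_mm=float(d.get("depth_offset_mm", 0.0)),
        )


@dataclass(frozen=True)
class MModeScan:
    """A calibrated M-mode scan: 2-D intensity array plus its calibration.

    ``pixels[r, c]`` is the echo intensity of the tissue layer at depth
    ``depth_offset_mm + r * mm_per_row`` recorded at time
    ``c / columns_per_second``.  Intensities are finite floats in ``[0, 1]``.
    """

    pixels: np.ndarray
    calibration: ScanCalibration

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2:
            raise ValueError(f"pixels must be 2-D, got shape {px.shape}")
        if px.shape[1] < 3:
            raise ValueError(
                "scan must have at least 3 columns for energy-operator "
                f"analysis, got {px.shape[1]}"
            )
        if not np.all(np.isfinite(px)):
            raise ValueError("scan intensities must be finite")
        if px.min() < 0 or px.max() > 1:
            raise ValueError("scan intensities must lie in [0, 1]")
        object.__setattr__(self, "pixels", px)

    @property
    def n_rows(self) -> int:
        return self.pixels.shape[0]

    @property
    def n_columns(self) -> int:
        return self.pixels.shape[1]

    @property
    def duration_s(self) -> float:
        """Time span covered by the scan, in seconds."""
        return self.n_columns / self.calibration.columns_per_second

    def depth_axis(self) -> np.ndarray:
        """Depth of each pixel row beneath the skin, in millimetres."""
        c = self.calibration
        return c.depth_offset_mm + np.arange(self.n_rows) * c.mm_per_row


def _to_unit_gray(raw: np.ndarray, path: Path) -> np.ndarray:
    """Collapse to one channel and rescale to [0, 1] by the bit-depth max."""
    arr = np.asarray(raw)
    if arr.ndim == 3:
        if arr.shape[2] not in (3, 4):
            raise ScanReadError(f"{path}: unsupported channel count {arr.shape[2]}")
        arr = arr[:, :, :3] @ _LUMA  # Rec. 601 luma
        # luma of integer channels stays on the integer scale
        if np.issubdtype(np.asarray(raw).dtype, np.integer):
            scale = float(np.iinfo(np.asarray(raw).dtype).max)
        else:
            scale = 1.0
        return np.clip(arr / scale, 0.0, 1.0)
    if arr.ndim != 2:
        raise ScanReadError(f"{path}: expected a 2-D image, got shape {arr.shape}")
    if np.issubdtype(arr.dtype, np.integer):
        return arr.astype(float) / float(np.iinfo(arr.dtype).max)
    return np.clip(arr.astype(float), 0.0, 1.0)


def read_scan(path: str | Path, calibration: ScanCalibration) -> MModeScan:
    """Read a TIFF/PNG M-mode scan image and attach its calibration.

    RGB images are collapsed to one channel with Rec. 601 luma weights
    (0.299, 0.587, 0.114); integer images are rescaled to ``[0, 1]`` by the
    maximum of their bit depth.

    Raises
    ------
    ScanReadError
        If the file is missing, unreadable, empty, or narrower than the
        3 columns the Teager-Kaiser operator needs.
    """
    path = Path(path)
    if not path.exists():
        raise ScanReadError(f"{path}: no such file")
    try:
        raw = iio.imread(path)
    except Exception as exc:  # noqa: BLE001 - wrap any decoder failure
        raise ScanReadError(f"{path}: cannot be read as an image ({exc})") from exc
    if raw.size == 0:
        raise ScanReadError(f"{path}: image is empty")
    gray = _to_unit_gray(raw, path)
    if gray.shape[1] < 3:
        raise ScanReadError(
            f"{path}: scan has {gray.shape[1]} columns; at least 3 are required"
        )
    return MModeScan(pixels=gray, calibration=calibration)


def write_scan(
    scan: MModeScan,
    path: str | Path,
    *,
    bit_depth: int = 16,
    sidecar: bool = True,
) -> Path:
    """Write a scan as a 16-bit (or 8-bit) grayscale image.

    When ``sidecar`` is true, the calibration is written next to the image as
    ``<path>.calib.json`` with keys ``mm_per_row``, ``columns_per_second`` and
    ``depth_offset_mm``.
    """
    path = Path(path)
    if bit_depth == 16:
        data = np.round(scan.pixels * 65535).astype(np.uint16)
    elif bit_depth == 8:
        data = np.round(scan.pixels * 255).astype(np.uint8)
    else:
        raise ValueError(f"bit_depth must be 8 or 16, got {bit_depth}")
    iio.imwrite(path, data)
    if sidecar:
        save_calibration(scan.calibration, sidecar_path(path))
    return path


def sidecar_path(image_path: str | Path) -> Path:
    return Path(str(image_path) + ".calib.json")


def save_calibration(calibration: ScanCalibration, path: str | Path) -> None:
    Path(path).write_text(json.dumps(calibration.to_dict(), indent=2))


def load_calibration(path: str | Path) -> ScanCalibration:
    return ScanCalibration.from_dict(json.loads(Path(path).read_text()))


def crop_depth(scan: MModeScan, z_min: float, z_max: float) -> MModeScan:
    """Keep the rows covering depths ``[z_min, z_max)`` millimetres.

    A row at depth ``z = depth_offset_mm + r * mm_per_row`` is kept when
    ``z_min <= z < z_max`` (half-open interval), and the calibration offset is
    updated to the depth of the first retained row.
    """
    if not (0 <= z_min < z_max):
        raise ValueError(f"need 0 <= z_min < z_max, got ({z_min}, {z_max})")
    c = scan.calibration
    # first row with offset + r*mm >= z_min; last row with offset + r*mm < z_max
    r_first = max(0, math.ceil((z_min - c.depth_offset_mm) / c.mm_per_row - 1e-12))
    r_last = math.floor(
        (z_max - c.depth_offset_mm) / c.mm_per_row - 1e-12
    )  # inclusive
    r_last = min(r_last, scan.n_rows - 1)
    if r_first > r_last:
        raise ValueError(
            f"crop window [{z_min}, {z_max}) mm contains no rows of a scan "
            f"spanning [{c.depth_offset_mm}, "
            f"{c.depth_offset_mm + scan.n_rows * c.mm_per_row}) mm"
        )
    new_calib = replace(
        c, depth_offset_mm=c.depth_offset_mm + r_first * c.mm_per_row
    )
    return MModeScan(pixels=scan.pixels[r_first : r_last + 1], calibration=new_calib)


def time_axis(scan: MModeScan) -> np.ndarray:
    """Acquisition time of each column in seconds: ``t(c) = c / rate``."""
    return np.arange(scan.n_columns) / scan.calibration.columns_per_second
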
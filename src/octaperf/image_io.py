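"""Reading, writing and quality-gating of en-face OCTA angiograms.

An en-face angiogram is a square 8-bit grayscale projection of the OCTA
flow volume over one retinal slab (full thickness, superficial plexus or
deep plexus), acquired on a 6x6 mm or 3x3 mm macular field at a nominal
304x304 px sampling. Physical scale is carried as ``mm_per_px`` derived
from the field size; pixel coordinates are 0-based, row-major, origin at
the top-left.

The quality gate mirrors the acquisition rules of longitudinal OCTA
studies: scans with a device signal-strength index (SSI) below 5 are
rejected, and gross blink/motion artifacts are approximated by blank-band
and duplicated-row heuristics (full visual inspection cannot be
automated).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import tifffile
from PIL import Image

VALID_SLABS = ("full", "scp", "dcp")
VALID_PROTOCOLS = ("6x6", "3x3")
VALID_TIMEPOINTS = ("pre", "post")

#: field of view in mm implied by each scan protocol
PROTOCOL_FIELD_MM = {"6x6": 6.0, "3x3": 3.0}


class AngiogramError(ValueError):
    """Raised for malformed angiogram inputs (shape, dtype, metadata)."""


@dataclass
class EnFaceAngiogram:
    """One grayscale slab image with physical scale and scan metadata.

    Parameters
    ----------
    pixels : ndarray of uint8, shape (n, n)
        Grayscale en-face projection, 0-255.
    field_mm : float
        Physical side length of the imaged square field (6.0 or 3.0 mm).
    slab : {'full', 'scp', 'dcp'}
    protocol : {'6x6', '3x3'}
    ssi : float
        Device-reported signal strength index (treated as supplied
        metadata; the device's definition is proprietary).
    eye_id : str
    timepoint : {'pre', 'post'}
    """

    pixels: np.ndarray
    field_mm: float
    slab: str = "full"
    protocol: str = "6x6"
    ssi: float = 10.0
    eye_id: str = ""
    timepoint: str = "pre"

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise AngiogramError(f"expected 2-D grayscale image, got ndim={px.ndim}")
        if px.shape[0] != px.shape[1]:
            raise AngiogramError(f"angiogram must be square, got {px.shape}")
        if px.dtype != np.uint8:
            px = _to_uint8(px)
        self.pixels = px
        if self.field_mm not in (6.0, 3.0):
            raise AngiogramError(f"field_mm must be 6.0 or 3.0, got {self.field_mm}")
        if self.slab not in VALID_SLABS:
            raise AngiogramError(f"slab must be one of {VALID_SLABS}, got {self.slab!r}")
        if self.protocol not in VALID_PROTOCOLS:
            raise AngiogramError(
                f"protocol must be one of {VALID_PROTOCOLS}, got {self.protocol!r}"
            )
        if self.timepoint not in VALID_TIMEPOINTS:
            raise AngiogramError(
                f"timepoint must be one of {VALID_TIMEPOINTS}, got {self.timepoint!r}"
            )

    @property
    def side_px(self) -> int:
        return self.pixels.shape[0]

    @property
    def mm_per_px(self) -> float:
        """Physical pixel pitch, field_mm / side_px."""
        return self.field_mm / self.side_px

    def with_pixels(self, pixels: np.ndarray) -> "EnFaceAngiogram":
        """Copy of this scan with the pixel array replaced."""
        return replace(self, pixels=pixels)


@dataclass
class QualityReport:
    """Outcome of the scan-quality gate; passed iff no rule fired."""

    passed: bool
    reasons: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.passed != (len(self.reasons) == 0):
            raise ValueError("passed must be equivalent to an empty reasons list")


def _to_uint8(px: np.ndarray) -> np.ndarray:
    """Linearly rescale higher-bit-depth or float input to 8-bit."""
    px = np.asarray(px)
    if px.dtype == np.uint8:
        return px
    if px.dtype == np.uint16:
        return (px.astype(np.float64) / 257.0).round().astype(np.uint8)
    px = px.astype(np.float64)
    lo, hi = float(px.min()), float(px.max())
    if hi <= lo:
        return np.zeros(px.shape, dtype=np.uint8)
    return ((px - lo) / (hi - lo) * 255.0).round().astype(np.uint8)


def load_angiogram(
    path: str | Path,
    *,
    protocol: str,
    slab: str = "full",
    ssi: float = 10.0,
    eye_id: str = "",
    timepoint: str = "pre",
) -> EnFaceAngiogram:
    """Load a TIFF/PNG angiogram and attach scan metadata.

    RGB inputs are collapsed to grayscale by channel averaging; 16-bit
    inputs are rescaled to 8-bit. Non-square images are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        px = tifffile.imread(path)
    else:
        px = np.asarray(Image.open(path))
    if px.ndim == 3:
        px = px.mean(axis=2).round().astype(px.dtype)
    if protocol not in PROTOCOL_FIELD_MM:
        raise AngiogramError(f"unknown protocol {protocol!r}")
    return EnFaceAngiogram(
        pixels=px,
        field_mm=PROTOCOL_FIELD_MM[protocol],
        slab=slab,
        protocol=protocol,
        ssi=ssi,
        eye_id=eye_id,
        timepoint=timepoint,
    )


def save_angiogram(scan: EnFaceAngiogram, path: str | Path) -> Path:
    """Write the pixel array as 8-bit TIFF or PNG (by extension)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, scan.pixels)
    else:
        Image.fromarray(scan.pixels).save(path)
    return path


def quality_gate(
    scan: EnFaceAngiogram,
    *,
    ssi_min: float = 5.0,
    max_blank_row_fraction: float = 0.05,
    max_duplicate_row_fraction: float = 0.25,
    blank_level: int = 0,
) -> QualityReport:
    """Apply the study's scan-quality rules.

    Rules (each contributes a reason identifier on failure):

    - ``low_ssi``: signal strength index below ``ssi_min`` (default 5,
      the exclusion threshold used clinically).
    - ``blank_band``: fraction of rows at or below ``blank_level``
      exceeding ``max_blank_row_fraction`` — a proxy for blink artifacts
      and localized signal loss.
    - ``duplicate_rows``: fraction of consecutive identical non-blank
      rows exceeding ``max_duplicate_row_fraction`` — a proxy for motion
      or doubling artifacts.

    Deterministic, and monotone in ``ssi_min``: raising the threshold
    never converts a failure into a pass.
    """
    reasons: list[str] = []
    if scan.ssi < ssi_min:
        reasons.append("low_ssi")

    px = scan.pixels
    blank_rows = np.all(px <= blank_level, axis=1)
    if blank_rows.mean() > max_blank_row_fraction:
        reasons.append("blank_band")

    non_blank = ~blank_rows
    if non_blank.sum() >= 2:
        same = np.all(px[1:] == px[:-1], axis=1) & non_blank[1:] & non_blank[:-1]
        if same.mean() > max_duplicate_row_fraction:
            reasons.append("duplicate_rows")

    return QualityReport(passed=not reasons, reasons=reasons)


def read_metadata_csv(path: str | Path) -> list[dict]:
    """Read a metadata sidecar CSV (eye_id, timepoint, slab, protocol, ssi)."""
    with open(path, newline="") as fh:
        rows = list(csv.DictReader(fh))
    for row in rows:
        row["ssi"] = float(row["ssi"])
    return rows


def write_metadata_csv(rows: list[dict], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fields = ["eye_id", "timepoint", "slab", "protocol", "ssi"]
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=fields, extrasaction="ignore")
        writer.writeheader()
        writer.writerows(rows)
    return path
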
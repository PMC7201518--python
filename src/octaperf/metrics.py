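"""Perfusion metrics: vascular density, skeleton density, box-counting
fractal dimension, FAZ area, and percent change.

Vascular density (VD) is the percentage of the analysis region occupied
by binarized vessel signal; skeleton VD is the same ratio computed on
the 1-px centerline map and is proportional to vessel *length* density,
making it the more sensitive marker of capillary loss. The fractal
dimension (FD) summarizes the branching complexity of the skeletonized
network via box counting. The foveal avascular zone (FAZ) area is the
mean shoelace area of up to three manual polygon traces, converted to
mm^2 through the image scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from shapely.geometry import Polygon

from .segmentation import BinaryVesselMap, SkeletonMap


@dataclass
class PerfusionMetrics:
    """The per-image row unit of a longitudinal perfusion analysis."""

    eye_id: str = ""
    timepoint: str = "pre"
    slab: str = "full"
    protocol: str = "6x6"
    vd_percent: float = np.nan
    skeleton_vd_percent: float = np.nan
    fd: float = np.nan
    faz_area_mm2: float = np.nan  # full-thickness slab only

    def __post_init__(self) -> None:
        for name in ("vd_percent", "skeleton_vd_percent"):
            v = getattr(self, name)
            if np.isfinite(v) and not 0.0 <= v <= 100.0:
                raise ValueError(f"{name} must be in [0, 100], got {v}")
        if np.isfinite(self.fd) and not 0.0 <= self.fd <= 2.0:
            raise ValueError(f"fd must be in [0, 2], got {self.fd}")
        if np.isfinite(self.faz_area_mm2) and self.faz_area_mm2 < 0:
            raise ValueError("faz_area_mm2 must be >= 0")


@dataclass
class FazTrace:
    """One manual FAZ outline: a simple polygon in pixel coordinates."""

    vertices_px: np.ndarray  # (n, 2) array of (x=col, y=row)
    mm_per_px: float
    replicate: int = 1

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices_px, dtype=np.float64)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
            raise ValueError("a trace needs >= 3 (x, y) vertices")
        self.vertices_px = v
        if self.mm_per_px <= 0:
            raise ValueError("mm_per_px must be positive")
        poly = Polygon(v)
        if not poly.is_valid or poly.area == 0.0:
            raise ValueError("trace polygon must be simple (non-self-intersecting)")

    @property
    def area_mm2(self) -> float:
        return Polygon(self.vertices_px).area * self.mm_per_px**2


def _mask_of(obj) -> np.ndarray:
    if isinstance(obj, (BinaryVesselMap, SkeletonMap)):
        return obj.mask
    return np.asarray(obj, dtype=bool)


def vascular_density(vessel_map, roi=None) -> float:
    """Percent of the region of interest occupied by vessel foreground:
    100 * |foreground AND roi| / |roi|. ``roi=None`` uses the full frame
    (the unpaired case); paired analyses pass the common-area mask."""
    mask = _mask_of(vessel_map)
    if roi is None:
        roi = np.ones_like(mask, dtype=bool)
    roi = np.asarray(roi, dtype=bool)
    if roi.shape != mask.shape:
        raise ValueError("roi shape must match the vessel map")
    denom = int(roi.sum())
    if denom == 0:
        raise ValueError("empty region of interest")
    return 100.0 * int((mask & roi).sum()) / denom


def skeleton_density(skeleton_map, roi=None) -> float:
    """Vascular density of the 1-px skeleton (length density, percent)."""
    return vascular_density(skeleton_map, roi)


def default_box_sizes(side_px: int) -> list:
    """Powers of 2 from 2 px up to side/4."""
    sizes = []
    s = 2
    while s <= side_px // 4:
        sizes.append(s)
        s *= 2
    return sizes


def box_counting_fd(
    skeleton_map,
    box_sizes=None,
    n_grid_offsets: int = 8,
    seed: int = 0,
) -> float:
    """Box-counting fractal dimension of a (skeleton) point set.

    For each box size ``eps`` the number of occupied grid boxes
    ``N(eps)`` is minimized over ``n_grid_offsets`` grid origins — the
    aligned origin (0, 0) plus random offsets in [0, eps)^2 — and the
    dimension is the negative slope of the least-squares fit of
    ``log N(eps)`` against ``log eps``. Default sizes are powers of 2
    from 2 px to a quarter of the image side (at least 4 sizes are
    required; ~1.5 decades of scale is recommended).

    Raises ``ValueError`` on an empty skeleton: the dimension of the
    empty set is undefined, not zero.
    """
    mask = _mask_of(skeleton_map)
    pts = np.argwhere(mask)
    if pts.shape[0] == 0:
        raise ValueError("fractal dimension is undefined for an empty skeleton")
    side = min(mask.shape)
    sizes = list(box_sizes) if box_sizes is not None else default_box_sizes(side)
    if len(sizes) < 4:
        raise ValueError(f"need >= 4 box sizes, got {sizes}")
    rng = np.random.default_rng(seed)
    counts = []
    for eps in sizes:
        offsets = [(0.0, 0.0)] + [tuple(rng.uniform(0, eps, 2)) for _ in range(max(n_grid_offsets - 1, 0))]
        best = None
        for orow, ocol in offsets:
            boxes = np.empty_like(pts)
            boxes[:, 0] = (pts[:, 0] + orow) // eps
            boxes[:, 1] = (pts[:, 1] + ocol) // eps
            n = len(np.unique(boxes, axis=0))
            best = n if best is None else min(best, n)
        counts.append(best)
    slope = np.polyfit(np.log(np.asarray(sizes, float)), np.log(np.asarray(counts, float)), 1)[0]
    return float(-slope)


def faz_area(traces) -> float:
    """Mean FAZ area over 1-3 replicate manual traces, in mm^2.

    Each trace's shoelace polygon area (px^2) is scaled by mm_per_px^2;
    replicates are averaged, following the convention of repeating the
    manual measurement three times.
    """
    traces = list(traces)
    if not 1 <= len(traces) <= 3:
        raise ValueError("expected 1-3 replicate traces")
    return float(np.mean([t.area_mm2 for t in traces]))


def faz_trace_sd(traces) -> float:
    """Replicate SD of the traced areas (mm^2), retained for QC."""
    return float(np.std([t.area_mm2 for t in traces], ddof=0))


def percent_change(pre_value: float, post_value: float) -> float:
    """Relative change of a metric between visits:
    100 * (post - pre) / pre. Undefined (error) at zero baseline."""
    if pre_value == 0:
        raise ZeroDivisionError("percent change undefined for zero baseline")
    return 100.0 * (post_value - pre_value) / pre_value
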
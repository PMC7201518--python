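"""End-to-end analysis: paired scans -> registered, masked perfusion
metrics -> cohort table.

This is thin glue over the alignment, segmentation and metrics modules,
mirroring the longitudinal workflow: register the follow-up scan to
baseline, segment both resampled grayscale images, and compute all
densities within the common-area mask so the two visits are compared
over identical retina.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alignment import RegistrationResult, intersection_mask, register_pair
from .image_io import EnFaceAngiogram
from .metrics import PerfusionMetrics, box_counting_fd, skeleton_density, vascular_density
from .segmentation import SegmentationParams, binarize_angiogram, skeletonize


@dataclass
class PairAnalysis:
    pre_metrics: PerfusionMetrics
    post_metrics: PerfusionMetrics
    registration: RegistrationResult
    roi: np.ndarray


def _segment_metrics(
    scan: EnFaceAngiogram,
    pixels: np.ndarray,
    roi: np.ndarray,
    params: SegmentationParams,
    fd_seed: int,
) -> PerfusionMetrics:
    vessel_map, _ = binarize_angiogram(pixels, params)
    masked = vessel_map.mask & roi
    skel = skeletonize(masked)
    vd = vascular_density(masked, roi)
    svd = skeleton_density(skel, roi)
    fd = box_counting_fd(skel, seed=fd_seed) if skel.mask.any() else float("nan")
    return PerfusionMetrics(
        eye_id=scan.eye_id,
        timepoint=scan.timepoint,
        slab=scan.slab,
        protocol=scan.protocol,
        vd_percent=vd,
        skeleton_vd_percent=svd,
        fd=fd,
    )


def analyze_pair(
    pre: EnFaceAngiogram,
    post: EnFaceAngiogram,
    params: SegmentationParams | None = None,
    *,
    fd_seed: int = 0,
) -> PairAnalysis:
    """Register, mask, segment and measure one pre/post pair.

    The post image is resampled into pre coordinates before
    binarization (segmentation always runs on resampled grayscale,
    never on resampled binary masks), and both timepoints' densities
    use the common-area mask as denominator.
    """
    params = params or SegmentationParams()
    reg = register_pair(pre, post)
    roi = intersection_mask(pre, reg.transform)
    aligned_u8 = np.clip(np.rint(reg.aligned), 0, 255).astype(np.uint8)
    pre_m = _segment_metrics(pre, pre.pixels, roi, params, fd_seed)
    post_m = _segment_metrics(post, aligned_u8, roi, params, fd_seed)
    post_m.eye_id = post.eye_id
    post_m.timepoint = post.timepoint
    return PairAnalysis(pre_m, post_m, reg, roi)


def synthetic_noise_circles(config, n_circles: int = 3, jitter_px: int = 3):
    """Noise-sampling circles sized to fit the generated FAZ disk.

    Returns ((row, col) centers, radius_px): circles clustered at the
    known synthetic FAZ center, with the radius chosen so each circle
    (including jitter) stays inside the avascular disk.
    """
    faz_r_px = config.faz_radius_mm / config.mm_per_px
    radius = max(int(faz_r_px) - jitter_px - 1, 3)
    c = (config.image_px - 1) // 2
    offsets = [(0, 0), (-jitter_px, jitter_px), (jitter_px, -jitter_px)][:n_circles]
    centers = [(c + dr, c + dc) for dr, dc in offsets]
    return centers, radius


def analyze_cohort(cohort, params: SegmentationParams | None = None, *, sim_config=None):
    """Run :func:`analyze_pair` over a simulated cohort and return the
    per-scan metrics as a :class:`~octaperf.stats.CohortTable`.

    ``sim_config`` (the cohort's SimulationConfig) lets the pipeline
    place noise-sampling circles inside the known synthetic FAZ; without
    it, dark-circle auto-proposal is used.
    """
    from .stats import CohortTable

    if params is None:
        params = SegmentationParams()
    if sim_config is not None:
        centers, radius = synthetic_noise_circles(sim_config)
        params = SegmentationParams(
            **{**vars(params), "faz_circles": centers, "circle_radius_px": radius}
        )
    rows = []
    for eye in cohort:
        res = analyze_pair(eye.pre, eye.post, params)
        rows.append(res.pre_metrics)
        rows.append(res.post_metrics)
    return CohortTable.from_metrics(rows)
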
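"""Rigid registration of paired en-face angiograms.

Longitudinal OCTA compares a follow-up scan against a baseline scan of
the same eye; fixation differences between visits leave a small rigid
offset (a few pixels of translation, a degree or two of rotation)
between the pair. This module recovers that motion, resamples the
follow-up image into baseline coordinates, and produces the
common-area mask so that densities are computed only over retina seen
by both scans (the denominator domain of every paired metric).

The transform family is a similarity (translation + rotation about the
image center, with an optional isotropic scale locked to 1 by default).
The objective is normalized cross-correlation (NCC) on modestly blurred
images — robust to speckle — maximized by a coarse rotation/translation
search (phase cross-correlation per candidate angle) followed by
Nelder-Mead refinement of the full parameter vector.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.optimize import minimize
from skimage.filters import gaussian
from skimage.registration import phase_cross_correlation
from skimage.transform import AffineTransform, warp


class RegistrationError(RuntimeError):
    """Raised when the optimizer cannot find a credible alignment."""


@dataclass(frozen=True)
class RigidTransform:
    """Motion of image content: rotation ``theta_deg`` about the image
    center followed by translation ``(dx_px, dy_px)``, with optional
    isotropic ``scale``.

    Coordinates are (x=column, y=row); positive dx moves content right,
    positive dy moves it down, positive theta rotates clockwise on
    screen (y axis points down).
    """

    dx_px: float = 0.0
    dy_px: float = 0.0
    theta_deg: float = 0.0
    scale: float = 1.0

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError("scale must be positive")

    def matrix(self, side_px: int) -> np.ndarray:
        """Forward 3x3 homogeneous matrix mapping input (x, y, 1) to
        output coordinates, rotating about the image center."""
        c = (side_px - 1) / 2.0
        th = math.radians(self.theta_deg)
        s, co = math.sin(th), math.cos(th)
        rot = self.scale * np.array([[co, -s], [s, co]])
        m = np.eye(3)
        m[:2, :2] = rot
        m[:2, 2] = np.array([c + self.dx_px, c + self.dy_px]) - rot @ np.array([c, c])
        return m

    def inverse(self) -> "RigidTransform":
        th = math.radians(self.theta_deg)
        s, co = math.sin(th), math.cos(th)
        rot_inv = np.array([[co, s], [-s, co]]) / self.scale
        d = -rot_inv @ np.array([self.dx_px, self.dy_px])
        return RigidTransform(float(d[0]), float(d[1]), -self.theta_deg, 1.0 / self.scale)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Transform equivalent to applying ``other`` first, then self."""
        th = math.radians(self.theta_deg)
        s, co = math.sin(th), math.cos(th)
        rot = self.scale * np.array([[co, -s], [s, co]])
        d = rot @ np.array([other.dx_px, other.dy_px]) + np.array(
            [self.dx_px, self.dy_px]
        )
        return RigidTransform(
            float(d[0]),
            float(d[1]),
            self.theta_deg + other.theta_deg,
            self.scale * other.scale,
        )

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(
            json.dumps(
                {
                    "dx_px": self.dx_px,
                    "dy_px": self.dy_px,
                    "theta_deg": self.theta_deg,
                    "scale": self.scale,
                }
            )
        )
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "RigidTransform":
        return cls(**json.loads(Path(path).read_text()))


def apply_transform(
    image: np.ndarray,
    transform: RigidTransform,
    *,
    order: int = 1,
    cval: float = 0.0,
) -> np.ndarray:
    """Resample ``image`` so its content undergoes ``transform``.

    Bilinear interpolation by default; out-of-bounds samples filled
    with ``cval``. Returns a float array of the same shape.
    """
    n = image.shape[0]
    inv = AffineTransform(matrix=transform.inverse().matrix(n))
    return warp(
        image.astype(np.float64), inv, order=order, cval=cval, preserve_range=True
    )


def valid_region_mask(shape: tuple, transform: RigidTransform) -> np.ndarray:
    """Pixels of the reference frame whose samples in the moving image
    (i.e. forward-mapped coordinates) land fully in-bounds."""
    n = shape[0]
    m = transform.matrix(n)
    cols, rows = np.meshgrid(np.arange(shape[1]), np.arange(shape[0]))
    x = m[0, 0] * cols + m[0, 1] * rows + m[0, 2]
    y = m[1, 0] * cols + m[1, 1] * rows + m[1, 2]
    eps = 1e-9
    return (
        (x >= -eps) & (x <= shape[1] - 1 + eps) & (y >= -eps) & (y <= shape[0] - 1 + eps)
    )


def _ncc(a: np.ndarray, b: np.ndarray, mask: np.ndarray) -> float:
    if mask.sum() < 16:
        return -1.0
    av = a[mask]
    bv = b[mask]
    av = av - av.mean()
    bv = bv - bv.mean()
    denom = math.sqrt(float(av @ av) * float(bv @ bv))
    if denom == 0.0:
        return 0.0
    return float(av @ bv) / denom


@dataclass
class RegistrationResult:
    transform: RigidTransform  # motion of post relative to pre
    aligned: np.ndarray  # post resampled into pre coordinates (float)
    score: float  # NCC of the aligned pair over the common area


def _pixels(image) -> np.ndarray:
    return np.asarray(getattr(image, "pixels", image), dtype=np.float64)


def register_pair(
    pre,
    post,
    *,
    theta_range_deg: float = 6.0,
    theta_step_deg: float = 1.0,
    blur_sigma: float = 1.5,
    similarity_floor: float = 0.2,
    estimate_scale: bool = False,
) -> RegistrationResult:
    """Estimate the rigid motion of ``post`` relative to ``pre``.

    Accepts :class:`~octaperf.image_io.EnFaceAngiogram` objects or bare
    2-D arrays; angiogram pairs must share slab and protocol. Returns
    the recovered transform, the post image resampled into pre
    coordinates, and the final NCC score. A score below
    ``similarity_floor`` raises :class:`RegistrationError` — such pairs
    are excluded from analysis, mirroring clinical quality exclusions.
    """
    for attr in ("slab", "protocol"):
        a, b = getattr(pre, attr, None), getattr(post, attr, None)
        if a is not None and b is not None and a != b:
            raise ValueError(f"pre/post {attr} mismatch: {a!r} vs {b!r}")
    pre_px = _pixels(pre)
    post_px = _pixels(post)
    if pre_px.shape != post_px.shape:
        raise ValueError("pre and post images must share shape")

    pre_b = gaussian(pre_px, sigma=blur_sigma, preserve_range=True)
    post_b = gaussian(post_px, sigma=blur_sigma, preserve_range=True)

    # coarse search: candidate rotations, translation by phase correlation
    best: tuple[float, RigidTransform] | None = None
    n_steps = int(round(theta_range_deg / theta_step_deg))
    for k in range(-n_steps, n_steps + 1):
        theta = k * theta_step_deg
        derot = apply_transform(post_b, RigidTransform(theta_deg=-theta))
        shift, _, _ = phase_cross_correlation(
            pre_b, derot, upsample_factor=10, normalization=None
        )
        # derot must move by (dy, dx) = shift to match pre, so the
        # derotated post content sits at pre position - shift; the
        # forward motion re-rotates that offset
        off = np.array([-shift[1], -shift[0]])  # (x, y)
        th = math.radians(theta)
        rot = np.array([[math.cos(th), -math.sin(th)], [math.sin(th), math.cos(th)]])
        d = rot @ off
        cand = RigidTransform(float(d[0]), float(d[1]), theta)
        score = _score_transform(pre_b, post_b, cand)
        if best is None or score > best[0]:
            best = (score, cand)

    assert best is not None
    t0 = best[1]

    # local refinement of the full parameter vector
    if estimate_scale:
        x0 = [t0.dx_px, t0.dy_px, t0.theta_deg, 1.0]

        def unpack(x):
            return RigidTransform(x[0], x[1], x[2], max(x[3], 1e-3))

    else:
        x0 = [t0.dx_px, t0.dy_px, t0.theta_deg]

        def unpack(x):
            return RigidTransform(x[0], x[1], x[2])

    def objective(x):
        return -_score_transform(pre_b, post_b, unpack(x))

    res = minimize(
        objective,
        x0,
        method="Nelder-Mead",
        options={"xatol": 5e-3, "fatol": 1e-7, "maxiter": 400},
    )
    transform = unpack(res.x)
    score = -float(res.fun)
    if score < similarity_floor:
        raise RegistrationError(
            f"registration similarity {score:.3f} below floor {similarity_floor}"
        )
    # cubic resampling for the returned image: downstream binarization is
    # sensitive to interpolation blur on 1-2 px capillaries
    aligned = apply_transform(post_px, transform.inverse(), order=3)
    return RegistrationResult(transform=transform, aligned=aligned, score=score)


def _score_transform(
    pre_b: np.ndarray, post_b: np.ndarray, t: RigidTransform
) -> float:
    aligned = apply_transform(post_b, t.inverse())
    mask = valid_region_mask(pre_b.shape, t)
    return _ncc(pre_b, aligned, mask)


def intersection_mask(pre, transform: RigidTransform) -> np.ndarray:
    """Common-area mask in the pre (reference) frame: pixels carrying
    valid image content in both scans of an aligned pair.

    All downstream density metrics use this mask as their denominator
    domain. Raises :class:`RegistrationError` on empty overlap.
    """
    shape = _pixels(pre).shape
    mask = valid_region_mask(shape, transform)
    if not mask.any():
        raise RegistrationError("registered pair has empty overlap")
    return mask


def save_mask_png(mask: np.ndarray, path: str | Path) -> Path:
    from PIL import Image

    path = Path(path)
    Image.fromarray((mask.astype(np.uint8)) * 255).save(path)
    return path
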
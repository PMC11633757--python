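"""Mosaic preprocessing: tile stitching, percentile normalization, retrospective
shading correction and mask-to-image coregistration.

Tiles are acquired with fractional overlap; stitching removes half the
overlap from each tile border (5% for the default 10% overlap) and places
the cropped tiles edge to edge, so pixel values are conserved without any
blending or interpolation.  Composite images are percentile normalized per
channel (lower 1.5%, upper 99%) to improve dynamic range and suppress
isolated bright pixels.  Uneven illumination (vignetting) is corrected by
a multiplicative flat-field model estimated retrospectively from the raw
tile stack.  Annotation masks are coregistered to the multimodal mosaic by
phase correlation (translation) or an exhaustive small-angle scan (rigid),
with nearest-neighbour resampling so label values are preserved exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.registration import phase_cross_correlation
from sklearn.base import BaseEstimator, TransformerMixin

from .images import AnnotationMask, MultimodalImage, TileStack

__all__ = [
    "stitch_tiles",
    "percentile_normalize",
    "PercentileNormalizer",
    "ShadingModel",
    "estimate_shading",
    "correct_shading",
    "ShadingCorrector",
    "RegistrationTransform",
    "RegistrationError",
    "register_mask",
    "register_from_landmarks",
]


# ---------------------------------------------------------------------------
# Stitching
# ---------------------------------------------------------------------------

def stitch_tiles(stack: TileStack, crop_frac: float = 0.05) -> MultimodalImage:
    """Stitch a tile stack into a mosaic by border cropping, without blending.

    ``crop_frac`` of the tile size is removed from each border; the cropped
    tiles must then abut exactly, which requires ``2 * crop_frac ==
    overlap_frac``.  The mosaic has size ``n_rows * (1 - 2 crop_frac) *
    tile_px`` per side.
    """
    spec = stack.spec
    if abs(2.0 * crop_frac - spec.overlap_frac) > 1e-9:
        raise ValueError(
            f"crop_frac {crop_frac} inconsistent with overlap {spec.overlap_frac}; "
            f"expected crop_frac = overlap/2 = {spec.overlap_frac / 2}"
        )
    t = spec.tile_px
    crop_px = int(round(crop_frac * t))
    core = t - 2 * crop_px
    if core != spec.step_px:
        raise ValueError(
            f"cropped tile core ({core} px) does not equal the stage step "
            f"({spec.step_px} px); choose tile_px so that crop_frac * tile_px "
            "is an integer (e.g. multiples of 20 for 10% overlap)"
        )
    n_rows, n_cols = spec.grid
    mosaic = np.empty((3, n_rows * core, n_cols * core), dtype=float)
    for r in range(n_rows):
        for c in range(n_cols):
            tile = stack.tile(r, c)
            mosaic[:, r * core : (r + 1) * core, c * core : (c + 1) * core] = tile[
                :, crop_px : t - crop_px, crop_px : t - crop_px
            ]
    return MultimodalImage(mosaic, pixel_size=stack.pixel_size)


# ---------------------------------------------------------------------------
# Percentile normalization
# ---------------------------------------------------------------------------

class PercentileNormalizer(BaseEstimator, TransformerMixin):
    """Per-channel linear rescaling mapping the ``p_lo`` percentile to 0 and
    ``p_hi`` to 1, followed by clipping to [0, 1].

    Percentiles are computed over the full mosaic (not per tile).  A
    constant channel (degenerate percentiles) is set to zero with a
    warning.
    """

    def __init__(self, p_lo: float = 1.5, p_hi: float = 99.0):
        self.p_lo = p_lo
        self.p_hi = p_hi

    def fit(self, image: MultimodalImage, y=None) -> "PercentileNormalizer":
        if image.data.size == 0:
            raise ValueError("empty image")
        self.lo_ = np.percentile(image.data, self.p_lo, axis=(1, 2))
        self.hi_ = np.percentile(image.data, self.p_hi, axis=(1, 2))
        return self

    def transform(self, image: MultimodalImage) -> MultimodalImage:
        out = np.empty_like(image.data)
        for ch in range(3):
            lo, hi = self.lo_[ch], self.hi_[ch]
            if hi <= lo:
                warnings.warn(
                    f"channel {ch}: degenerate percentiles (constant channel); set to 0",
                    stacklevel=2,
                )
                out[ch] = 0.0
            else:
                out[ch] = np.clip((image.data[ch] - lo) / (hi - lo), 0.0, 1.0)
        return MultimodalImage(out, pixel_size=image.pixel_size)


def percentile_normalize(
    image: MultimodalImage, p_lo: float = 1.5, p_hi: float = 99.0
) -> MultimodalImage:
    """Percentile-normalize an image (thin wrapper over PercentileNormalizer)."""
    return PercentileNormalizer(p_lo=p_lo, p_hi=p_hi).fit(image).transform(image)


# ---------------------------------------------------------------------------
# Shading (flat-field) model
# ---------------------------------------------------------------------------

@dataclass
class ShadingModel:
    """Multiplicative flat-field plus additive dark-field, tile-sized.

    ``flatfield`` is a strictly positive per-pixel gain raster with unit
    mean per channel; ``darkfield`` an additive offset (zero by default).
    A corrected tile is ``(tile - darkfield) / flatfield`` clipped at 0.
    """

    flatfield: np.ndarray
    darkfield: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.flatfield = np.asarray(self.flatfield, dtype=float)
        if np.any(self.flatfield <= 0):
            raise ValueError("flatfield must be strictly positive")
        means = self.flatfield.mean(axis=(-2, -1))
        if np.any(np.abs(means - 1.0) > 1e-6):
            raise ValueError("flatfield must have unit mean per channel")
        if self.darkfield is None:
            self.darkfield = np.zeros_like(self.flatfield)


def estimate_shading(stack: TileStack, smooth_frac: float = 1 / 16) -> ShadingModel:
    """Estimate a flat-field from a raw tile stack.

    Per-pixel median across the stack, Gaussian-smoothed with sigma =
    ``tile_px * smooth_frac``, normalized to unit mean per channel — a
    simplified retrospective stand-in for low-rank + smoothness flat-field
    models; a more elaborate backend can be plugged in behind the same
    interface.
    """
    if len(stack) == 0:
        raise ValueError("empty tile stack")
    if len(stack) < 9:
        warnings.warn(
            f"only {len(stack)} tiles; flat-field estimate may be unreliable "
            "(>= 9 tiles recommended)",
            stacklevel=2,
        )
    med = np.median(stack.tiles, axis=0)  # (3, t, t)
    sigma = stack.spec.tile_px * smooth_frac
    flat = np.stack([ndimage.gaussian_filter(med[ch], sigma, mode="reflect") for ch in range(3)])
    flat = np.clip(flat, 1e-6, None)
    flat /= flat.mean(axis=(-2, -1), keepdims=True)
    return ShadingModel(flatfield=flat)


def correct_shading(stack: TileStack, model: ShadingModel) -> TileStack:
    """Apply a shading model to every tile: (tile - dark) / flat, clipped at 0."""
    if model.flatfield.shape[-2:] != stack.tiles.shape[-2:]:
        raise ValueError(
            f"shading model shape {model.flatfield.shape[-2:]} does not match "
            f"tile size {stack.tiles.shape[-2:]}"
        )
    corrected = np.clip((stack.tiles - model.darkfield) / model.flatfield, 0.0, None)
    return TileStack(corrected, stack.spec, pixel_size=stack.pixel_size)


class ShadingCorrector(BaseEstimator, TransformerMixin):
    """Estimator wrapper: ``fit`` estimates the flat-field from a tile stack,
    ``transform`` corrects a stack with the fitted model (``model_``)."""

    def __init__(self, smooth_frac: float = 1 / 16):
        self.smooth_frac = smooth_frac

    def fit(self, stack: TileStack, y=None) -> "ShadingCorrector":
        self.model_ = estimate_shading(stack, smooth_frac=self.smooth_frac)
        return self

    def transform(self, stack: TileStack) -> TileStack:
        return correct_shading(stack, self.model_)


# ---------------------------------------------------------------------------
# Registration
# ---------------------------------------------------------------------------

class RegistrationError(RuntimeError):
    """Raised when no reliable correlation peak is found."""


@dataclass
class RegistrationTransform:
    """Detected motion of the moving raster relative to the fixed image.

    ``dx``/``dy`` are the column/row displacement in pixels and ``theta``
    the rotation in degrees (counter-clockwise); aligning the moving raster
    applies the inverse.  ``kind`` is ``"translation"`` (theta forced to 0)
    or ``"rigid"``.
    """

    dx: float
    dy: float
    theta: float = 0.0
    kind: str = "translation"

    def __post_init__(self) -> None:
        if not np.all(np.isfinite([self.dx, self.dy, self.theta])):
            raise ValueError("transform parameters must be finite")
        if self.kind == "translation" and self.theta != 0.0:
            raise ValueError("translation transform requires theta = 0")
        if self.kind not in ("translation", "rigid"):
            raise ValueError(f"unknown transform kind {self.kind!r}")


def _summary(raster) -> np.ndarray:
    if isinstance(raster, MultimodalImage):
        s = raster.data.mean(axis=0)
    elif isinstance(raster, AnnotationMask):
        s = raster.labels.astype(float)
    else:
        s = np.asarray(raster, dtype=float)
    s = s - s.mean()
    sd = s.std()
    return s / sd if sd > 0 else s


def _apply_inverse(labels: np.ndarray, tf: RegistrationTransform) -> np.ndarray:
    out = labels
    if tf.theta != 0.0:
        out = ndimage.rotate(out, -tf.theta, reshape=False, order=0, mode="nearest")
    out = ndimage.shift(out, (-tf.dy, -tf.dx), order=0, mode="nearest")
    return out


def register_mask(
    moving,
    fixed: MultimodalImage,
    kind: str = "translation",
    max_angle: float = 5.0,
    angle_step: float = 0.25,
    min_correlation: float = 0.1,
) -> tuple[RegistrationTransform, AnnotationMask]:
    """Coregister an annotation mask (or image) to a multimodal mosaic.

    Translation is recovered by phase correlation of intensity summaries;
    the rigid path adds an exhaustive rotation scan over ``+-max_angle``
    degrees in ``angle_step`` steps around the phase-correlation optimum.
    The mask is resampled with nearest-neighbour interpolation so the label
    set is preserved exactly.

    Raises :class:`RegistrationError` when the aligned correlation falls
    below ``min_correlation`` (no resampling is performed in that case).
    """
    fixed_sum = _summary(fixed)
    moving_sum = _summary(moving)
    if fixed_sum.shape != moving_sum.shape:
        raise ValueError("moving and fixed rasters must share a pixel grid")

    def _translation(mov: np.ndarray) -> tuple[float, float, float]:
        shift, error, _ = phase_cross_correlation(fixed_sum, mov, upsample_factor=10)
        # skimage returns the shift to apply to `mov`; the detected motion is its negation
        return -float(shift[0]), -float(shift[1]), float(error)

    if kind == "translation":
        dy, dx, _ = _translation(moving_sum)
        tf = RegistrationTransform(dx=dx, dy=dy, theta=0.0, kind="translation")
    elif kind == "rigid":
        best = None
        for theta in np.arange(-max_angle, max_angle + angle_step / 2, angle_step):
            rot = ndimage.rotate(moving_sum, -theta, reshape=False, order=1, mode="nearest")
            dy, dx, err = _translation(rot)
            if best is None or err < best[0]:
                best = (err, theta, dy, dx)
        _, theta, dy, dx = best
        tf = RegistrationTransform(dx=dx, dy=dy, theta=float(theta), kind="rigid")
    else:
        raise ValueError(f"unknown registration kind {kind!r}")

    aligned_sum = _apply_inverse(moving_sum, tf)
    denom = aligned_sum.std() * fixed_sum.std()
    corr = float((aligned_sum * fixed_sum).mean() / denom) if denom > 0 else 0.0
    if corr < min_correlation:
        raise RegistrationError(
            f"registration failed: aligned correlation {corr:.3f} < {min_correlation}"
        )

    if isinstance(moving, AnnotationMask):
        resampled = AnnotationMask(_apply_inverse(moving.labels, tf), level=moving.level)
    else:
        labels = np.asarray(moving)
        resampled = AnnotationMask(
            _apply_inverse(labels.astype(np.int64), tf), level=6
        )
    return tf, resampled


def register_from_landmarks(
    moving_points: np.ndarray, fixed_points: np.ndarray, kind: str = "rigid"
) -> RegistrationTransform:
    """Semi-automatic fallback: estimate the transform from user-picked
    point/line pairs (at least one pair for translation, two for rigid).

    Points are (row, col) coordinates; the returned transform records the
    motion of the moving raster relative to the fixed image, matching
    :func:`register_mask`.
    """
    mov = np.atleast_2d(np.asarray(moving_points, dtype=float))
    fix = np.atleast_2d(np.asarray(fixed_points, dtype=float))
    if mov.shape != fix.shape or mov.shape[0] < 1:
        raise ValueError("need matching non-empty landmark arrays")
    if kind == "translation" or mov.shape[0] == 1:
        d = (mov - fix).mean(axis=0)
        return RegistrationTransform(dx=float(d[1]), dy=float(d[0]), kind="translation")
    # rigid: 2-D Kabsch on centred coordinates
    mov_c = mov - mov.mean(axis=0)
    fix_c = fix - fix.mean(axis=0)
    h = fix_c.T @ mov_c
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(u @ vt))
    r = u @ np.diag([1.0, d]) @ vt
    # r aligns moving onto fixed; the recorded motion of moving relative
    # to fixed is its inverse rotation
    theta = float(-np.degrees(np.arctan2(r[1, 0], r[0, 0])))
    disp = mov.mean(axis=0) - fix.mean(axis=0)
    return RegistrationTransform(dx=float(disp[1]), dy=float(disp[0]), theta=theta, kind="rigid")
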
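"""Synthetic multimodal phantoms with the statistical structure of tile-scanned
CARS/TPEF/SHG endomicroscopy data.

Every downstream stage (stitching, shading correction, segmentation,
evaluation, ablation planning) is exercised on data from this module, so the
defaults encode the study conditions: ~10% tile overlap, multiplicative
vignetting toward tile edges, per-tissue-class channel signatures (high
SHG/TPEF in collagen-rich connective tissue, high CARS in dense muscle,
tumor TPEF above the surrounding stroma) and the six-class pixel prior
(background 56%, tumor 18%, other 10%, necrosis 7%, stroma 7%, healthy
epithelium 1%).  The ablation phantom emulates brain tissue containing
cholesterol crystals, whose crystalline structure gives a distinctive,
strong SHG signature on a moderate CARS/TPEF background.

Label maps are synthesised by thresholding smoothed Gaussian noise fields,
one per class, with per-class offsets adjusted iteratively until the
realized pixel fractions hit the target priors: simple, seedable, and
productive of contiguous histology-like regions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .images import CARS, SHG, TPEF, AcquisitionSpec, AnnotationMask, MultimodalImage, TileStack
from .taxonomy import SIX_CLASS_PRIORS, get_taxonomy

__all__ = [
    "ChannelSignature",
    "PhantomSpec",
    "default_signatures",
    "generate_label_map",
    "render_multimodal",
    "decompose_into_tiles",
    "vignette_profile",
    "generate_ablation_phantom",
]


@dataclass(frozen=True)
class ChannelSignature:
    """Per-class channel statistics used by the renderer.

    ``mean_intensity`` is the (CARS, TPEF, SHG) triple in [0, 1];
    ``texture_scale`` the spatial correlation length of the intensity
    texture in pixels (0 = white noise); ``noise_sd`` the additive Gaussian
    standard deviation.
    """

    class_id: str
    mean_intensity: tuple[float, float, float]
    texture_scale: float = 3.0
    noise_sd: float = 0.04

    def __post_init__(self) -> None:
        if not all(0.0 <= m <= 1.0 for m in self.mean_intensity):
            raise ValueError(f"mean_intensity must be in [0,1], got {self.mean_intensity}")
        if self.texture_scale < 0:
            raise ValueError("texture_scale must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def default_signatures(noise_sd: float = 0.04, texture_scale: float = 3.0) -> list[ChannelSignature]:
    """Default six-class signatures (CARS, TPEF, SHG).

    Qualitative contrast only — collagen-rich tissue high in SHG/TPEF,
    muscle high in CARS, tumor TPEF above tumor stroma; the magnitudes are
    package defaults, not claims about real tissue.
    """
    means = {
        "background": (0.03, 0.03, 0.02),
        "healthy epithelium": (0.18, 0.50, 0.10),
        "tumor stroma": (0.28, 0.30, 0.55),
        "other tissue": (0.65, 0.45, 0.50),
        "necrosis": (0.45, 0.20, 0.06),
        "tumor": (0.40, 0.65, 0.28),
    }
    return [
        ChannelSignature(name, m, texture_scale=texture_scale, noise_sd=noise_sd)
        for name, m in means.items()
    ]


@dataclass
class PhantomSpec:
    """Specification of a synthetic annotated phantom."""

    shape: tuple[int, int] = (2048, 2048)
    class_priors: dict[str, float] = field(default_factory=lambda: dict(SIX_CLASS_PRIORS))
    seed: int = 0
    pixel_size: float = 0.36
    level: int = 6
    blob_scale_px: float | None = None  # default: min(shape)/16

    def __post_init__(self) -> None:
        total = sum(self.class_priors.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"class priors must sum to 1 (got {total:.6f})")
        if any(p < 0 for p in self.class_priors.values()):
            raise ValueError("class priors must be >= 0")
        tax = get_taxonomy(self.level)
        unknown = set(self.class_priors) - set(tax.names)
        if unknown:
            raise ValueError(f"priors name unknown classes: {sorted(unknown)}")


def _unit_variance_field(rng: np.random.Generator, shape, scale: float) -> np.ndarray:
    """Smoothed standard-normal field rescaled to unit pointwise variance."""
    f = rng.standard_normal(shape)
    if scale > 0:
        f = ndimage.gaussian_filter(f, sigma=scale, mode="reflect")
        sd = f.std()
        if sd > 0:
            f /= sd
    return f


def generate_label_map(spec: PhantomSpec, frac_tol: float = 0.03, max_iter: int = 400) -> AnnotationMask:
    """Generate a spatially contiguous label raster matching the class priors.

    One smoothed Gaussian field per class is thresholded through an argmax
    with per-class offsets; the offsets are adjusted iteratively until each
    realized class fraction is within ``frac_tol`` (default +-3 percentage
    points) of its prior.  Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    tax = get_taxonomy(spec.level)
    names = [n for n in tax.names if spec.class_priors.get(n, 0.0) > 0.0]
    priors = np.array([spec.class_priors[n] for n in names])
    scale = spec.blob_scale_px if spec.blob_scale_px is not None else min(spec.shape) / 16

    if len(names) == 1:
        labels = np.full(spec.shape, tax.code(names[0]), dtype=np.int64)
        return AnnotationMask(labels, level=spec.level)

    fields = np.stack([_unit_variance_field(rng, spec.shape, scale) for _ in names])
    offsets = np.log(priors)  # crude initialization, refined below
    n_px = fields[0].size
    assign = None
    for it in range(max_iter):
        assign = np.argmax(fields + offsets[:, None, None], axis=0)
        frac = np.bincount(assign.ravel(), minlength=len(names)) / n_px
        err = priors - frac
        if np.max(np.abs(err)) < 0.25 * frac_tol:
            break
        offsets += (2.0 if it < 50 else 0.5) * err

    codes = np.array([tax.code(n) for n in names])
    labels = codes[assign].astype(np.int64)
    realized = np.bincount(assign.ravel(), minlength=len(names)) / n_px
    if np.max(np.abs(realized - priors)) > frac_tol:
        warnings.warn(
            "realized class fractions deviate from priors by more than "
            f"{frac_tol:.0%}; consider a larger raster or blob scale",
            stacklevel=2,
        )
    return AnnotationMask(labels, level=spec.level)


def render_multimodal(
    mask: AnnotationMask,
    signatures: list[ChannelSignature] | None = None,
    seed: int = 0,
    pixel_size: float = 0.36,
) -> MultimodalImage:
    """Render a 3-channel image from a label map and per-class signatures.

    Each pixel's channel mean follows its class signature; spatially
    correlated Gaussian texture with the class's ``texture_scale`` and
    ``noise_sd`` is added per channel.  Reproducible given ``seed``.
    """
    if signatures is None:
        signatures = default_signatures()
    rng = np.random.default_rng(seed)
    tax = get_taxonomy(mask.level)
    by_code: dict[int, ChannelSignature] = {}
    for sig in signatures:
        by_code[tax.code(sig.class_id)] = sig
    present = np.unique(mask.labels)
    missing = [tax.names[c] for c in present if c not in by_code]
    if missing:
        raise ValueError(f"no channel signature for class(es): {missing}")

    out = np.zeros((3,) + mask.shape, dtype=float)
    for code in present:
        sig = by_code[code]
        region = mask.labels == code
        for ch in range(3):
            out[ch][region] = sig.mean_intensity[ch]
            if sig.noise_sd > 0:
                noise = _unit_variance_field(rng, mask.shape, sig.texture_scale)
                out[ch][region] += sig.noise_sd * noise[region]
            elif sig.texture_scale > 0:
                pass  # texture without noise amplitude renders flat
    np.clip(out, 0.0, 1.0, out=out)
    return MultimodalImage(out, pixel_size=pixel_size)


def vignette_profile(tile_px: int, strength: float) -> np.ndarray:
    """Radial cosine falloff: 1 at the tile center, (1 - strength) at corners."""
    half = (tile_px - 1) / 2.0
    y, x = np.mgrid[0:tile_px, 0:tile_px]
    rho = np.sqrt(((y - half) / half) ** 2 + ((x - half) / half) ** 2) / np.sqrt(2.0)
    return 1.0 - strength * (1.0 - np.cos(np.pi * np.clip(rho, 0, 1))) / 2.0


def decompose_into_tiles(
    image: MultimodalImage, acq: AcquisitionSpec, seed: int = 0
) -> TileStack:
    """Cut a mosaic into raster-scan-ordered overlapping tiles.

    The stage step between tile origins is ``(1 - overlap_frac) * tile_px``.
    Each tile is multiplied by a smooth radial vignette of the stated
    strength; optional additive Gaussian noise (``acq.noise_sd``) emulates
    detection noise.
    """
    rng = np.random.default_rng(seed)
    n_rows, n_cols = acq.grid
    step, t = acq.step_px, acq.tile_px
    need = (step * (n_rows - 1) + t, step * (n_cols - 1) + t)
    if need[0] > image.shape[0] or need[1] > image.shape[1]:
        raise ValueError(
            f"grid {acq.grid} of {t}-px tiles at step {step} needs {need}, "
            f"image is {image.shape}"
        )
    vignette = vignette_profile(t, acq.vignette_strength)
    tiles = np.empty((n_rows * n_cols, 3, t, t), dtype=float)
    for r in range(n_rows):
        for c in range(n_cols):
            crop = image.data[:, r * step : r * step + t, c * step : c * step + t]
            tile = crop * vignette
            if acq.noise_sd > 0:
                tile = tile + rng.normal(0.0, acq.noise_sd, size=tile.shape)
            tiles[r * n_cols + c] = tile
    return TileStack(tiles, acq, pixel_size=image.pixel_size)


def generate_ablation_phantom(
    shape: tuple[int, int] = (500, 500),
    n_crystals: int = 5,
    crystal_size_px: int = 40,
    seed: int = 0,
    pixel_size: float = 1.3,
    max_attempts: int = 200,
) -> tuple[MultimodalImage, AnnotationMask]:
    """Brain-tissue phantom with SHG-bright cholesterol-crystal blobs.

    The background tissue has moderate CARS/TPEF and low SHG; each crystal
    is an elongated elliptical blob whose SHG intensity is several times the
    background SHG mean.  Returns the phantom and the ground-truth binary
    crystal mask (level-2 annotation: 0 = tissue, 1 = crystal).

    Crystals are placed without mutual contact so the truth mask has exactly
    ``n_crystals`` connected components; placement retries with new
    positions and raises after ``max_attempts`` failed proposals per
    crystal.
    """
    if n_crystals < 0:
        raise ValueError("n_crystals must be >= 0")
    rng = np.random.default_rng(seed)
    H, W = shape
    bg_mean = (0.45, 0.35, 0.07)  # CARS, TPEF, SHG
    img = np.empty((3, H, W))
    for ch in range(3):
        img[ch] = bg_mean[ch] + 0.03 * _unit_variance_field(rng, shape, 4.0)

    margin = crystal_size_px
    min_sep = 1.6 * crystal_size_px
    centers: list[tuple[float, float]] = []
    for _ in range(n_crystals):
        for attempt in range(max_attempts):
            cy = rng.uniform(margin, H - margin)
            cx = rng.uniform(margin, W - margin)
            if all((cy - y) ** 2 + (cx - x) ** 2 >= min_sep**2 for y, x in centers):
                centers.append((cy, cx))
                break
        else:
            raise RuntimeError(
                f"could not place {n_crystals} non-overlapping crystals in {shape} "
                f"after {max_attempts} attempts"
            )

    truth = np.zeros(shape, dtype=np.int64)
    yy, xx = np.mgrid[0:H, 0:W]
    for cy, cx in centers:
        theta = rng.uniform(0, np.pi)
        a = crystal_size_px / 2.0
        b = max(crystal_size_px / 4.0, 2.0)
        dy, dx = yy - cy, xx - cx
        u = np.cos(theta) * dx + np.sin(theta) * dy
        v = -np.sin(theta) * dx + np.cos(theta) * dy
        blob = (u / a) ** 2 + (v / b) ** 2 <= 1.0
        truth[blob] = 1
        img[SHG][blob] = 0.85 + 0.05 * rng.standard_normal(int(blob.sum()))
        img[CARS][blob] = 0.50
        img[TPEF][blob] = 0.30

    np.clip(img, 0.0, 1.0, out=img)
    return MultimodalImage(img, pixel_size=pixel_size), AnnotationMask(truth, level=2)
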
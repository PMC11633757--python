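"""Core raster containers for the multimodal endomicroscopy pipeline.

The three nonlinear contrasts (CARS, TPEF, SHG) are carried together as a
channel-major float raster in [0, 1].  Mosaics are assembled from tile
stacks acquired on a stage raster with fractional overlap; annotation
masks are integer label rasters pixel-aligned to a mosaic at one of the
taxonomy levels (15 / 6 / 3 classes).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

CHANNELS = ("CARS", "TPEF", "SHG")
#: channel indices by name
CARS, TPEF, SHG = 0, 1, 2


@dataclass
class MultimodalImage:
    """3-channel (CARS, TPEF, SHG) float raster, channel-major, values in [0, 1].

    Parameters
    ----------
    data : ndarray of shape (3, H, W)
        Channel-major pixel data.  Stored as float32/float64; values are
        expected (not enforced) to lie in [0, 1] after normalization.
    pixel_size : float
        Lateral pixel size in micrometers.
    """

    data: np.ndarray
    pixel_size: float = 0.36

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3 or self.data.shape[0] != len(CHANNELS):
            raise ValueError(
                f"expected (3, H, W) channel-major data, got shape {self.data.shape}"
            )
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        """Spatial (rows, cols) shape."""
        return self.data.shape[1:]

    def channel(self, which: int | str) -> np.ndarray:
        """Return one channel as a 2-D array; accepts index or name."""
        if isinstance(which, str):
            which = CHANNELS.index(which.upper())
        return self.data[which]


@dataclass
class AcquisitionSpec:
    """Geometry of a tile-scan acquisition.

    ``tile_px`` is the tile side in pixels, ``overlap_frac`` the fractional
    overlap along x and y between neighbouring tiles, ``vignette_strength``
    the peak-to-edge multiplicative falloff of the illumination profile and
    ``grid`` the (n_rows, n_cols) stage raster.
    """

    tile_px: int = 1200
    overlap_frac: float = 0.10
    vignette_strength: float = 0.0
    grid: tuple[int, int] = (3, 3)
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.tile_px <= 0:
            raise ValueError("tile_px must be positive")
        if not (0.0 <= self.overlap_frac < 0.5):
            raise ValueError("overlap_frac must be in [0, 0.5)")
        if not (0.0 <= self.vignette_strength < 1.0):
            raise ValueError("vignette_strength must be in [0, 1)")

    @property
    def step_px(self) -> int:
        """Stage step between neighbouring tile origins, in pixels."""
        return int(round((1.0 - self.overlap_frac) * self.tile_px))


@dataclass
class TileStack:
    """Ordered raw tiles plus grid geometry, prior to stitching.

    ``tiles`` has shape (n_tiles, 3, tile_px, tile_px) in raster-scan
    (row-major) order matching ``spec.grid``.
    """

    tiles: np.ndarray
    spec: AcquisitionSpec
    pixel_size: float = 0.36

    def __post_init__(self) -> None:
        self.tiles = np.asarray(self.tiles, dtype=float)
        n_rows, n_cols = self.spec.grid
        if self.tiles.shape[0] != n_rows * n_cols:
            raise ValueError(
                f"{self.tiles.shape[0]} tiles inconsistent with grid {self.spec.grid}"
            )
        if self.tiles.shape[-2:] != (self.spec.tile_px, self.spec.tile_px):
            raise ValueError("tile raster size inconsistent with spec.tile_px")

    def __len__(self) -> int:
        return self.tiles.shape[0]

    def tile(self, row: int, col: int) -> np.ndarray:
        n_rows, n_cols = self.spec.grid
        return self.tiles[row * n_cols + col]


@dataclass
class AnnotationMask:
    """Integer label raster pixel-aligned to a mosaic.

    ``level`` is the taxonomy level the labels belong to (15, 6 or 3).
    """

    labels: np.ndarray
    level: int = 6

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("annotation labels must be an integer raster")
        if self.labels.ndim != 2:
            raise ValueError("annotation mask must be 2-D")
        if self.level not in (15, 6, 3, 2):
            raise ValueError(f"unsupported taxonomy level {self.level}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape


# ---------------------------------------------------------------------------
# I/O helpers (text-free formats standard in the field: TIFF + JSON sidecar)
# ---------------------------------------------------------------------------

def write_mosaic_tiff(path: str | Path, image: MultimodalImage) -> None:
    """Write a 3-channel mosaic as a 16-bit TIFF (intensities quantized from [0,1])."""
    import tifffile

    data = np.clip(image.data, 0.0, 1.0)
    tifffile.imwrite(
        str(path),
        (data * 65535).round().astype(np.uint16),
        photometric="minisblack",
        metadata={"axes": "CYX", "pixel_size_um": image.pixel_size},
    )


def read_mosaic_tiff(path: str | Path, pixel_size: float = 0.36) -> MultimodalImage:
    import tifffile

    raw = tifffile.imread(str(path))
    if raw.ndim == 3 and raw.shape[-1] == 3:  # tolerate HWC layout
        raw = np.moveaxis(raw, -1, 0)
    data = raw.astype(float)
    if raw.dtype == np.uint16:
        data /= 65535.0
    elif raw.dtype == np.uint8:
        data /= 255.0
    return MultimodalImage(data, pixel_size=pixel_size)


def write_tile_stack(path: str | Path, stack: TileStack) -> None:
    """Write tiles as a multi-page TIFF (row-major raster order) + JSON geometry sidecar."""
    import tifffile

    path = Path(path)
    data = np.clip(stack.tiles, 0.0, 1.0)
    tifffile.imwrite(
        str(path), (data * 65535).round().astype(np.uint16), photometric="minisblack"
    )
    sidecar = {
        "tile_px": stack.spec.tile_px,
        "overlap_frac": stack.spec.overlap_frac,
        "vignette_strength": stack.spec.vignette_strength,
        "grid": list(stack.spec.grid),
        "noise_sd": stack.spec.noise_sd,
        "pixel_size_um": stack.pixel_size,
        "tile_order": "row-major",
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_tile_stack(path: str | Path) -> TileStack:
    import tifffile

    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    raw = tifffile.imread(str(path)).astype(float)
    if raw.dtype != float:
        raw = raw.astype(float)
    raw = raw / 65535.0
    spec = AcquisitionSpec(
        tile_px=meta["tile_px"],
        overlap_frac=meta["overlap_frac"],
        vignette_strength=meta["vignette_strength"],
        grid=tuple(meta["grid"]),
        noise_sd=meta.get("noise_sd", 0.0),
    )
    return TileStack(raw, spec, pixel_size=meta.get("pixel_size_um", 0.36))


def write_label_raster(path: str | Path, mask: AnnotationMask) -> None:
    """Write a label raster as 8-bit PNG/TIFF using the taxonomy integer codebook."""
    import imageio.v3 as iio

    iio.imwrite(str(path), mask.labels.astype(np.uint8))


def read_label_raster(path: str | Path, level: int = 6) -> AnnotationMask:
    import imageio.v3 as iio

    return AnnotationMask(np.asarray(iio.imread(str(path))).astype(np.int64), level=level)
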
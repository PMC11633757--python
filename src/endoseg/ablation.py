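"""Image-guided "seek and treat" ablation planning.

A multimodal frame is divided into k independent regions by K-means
clustering of the per-pixel (CARS, TPEF, SHG) triples; the cluster with
the highest mean SHG intensity is selected as the ablation target
(cholesterol crystals are SHG-bright because of their crystalline
structure).  The raw binary mask is spatially filtered (median + closing)
to make it more homogeneous, then applied as the per-pixel gate of the
ablation laser's acousto-optic modulator (AOM) over several consecutive
scan frames until the targeted structures are removed.

Two small physics helpers convert the printed laser settings: the CARS
wavenumber probed by a pump/Stokes pair, and the pulse energy from average
power and repetition rate.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from skimage.filters import median as _median_filter
from skimage.morphology import closing as _closing, disk
from sklearn.base import BaseEstimator
from sklearn.cluster import KMeans

from .images import CHANNELS, SHG, MultimodalImage

__all__ = [
    "ClusterMap",
    "AblationMask",
    "cluster_frame",
    "select_cluster",
    "filter_mask",
    "plan_ablation",
    "AblationPlanner",
    "simulate_ablation",
    "wavenumber_difference",
    "pulse_energy",
    "export_aom_mask",
]


@dataclass
class ClusterMap:
    """Per-pixel K-means cluster assignment with the cluster centroids."""

    labels: np.ndarray
    k: int
    centroids: np.ndarray  # (k, 3) channel-mean triples
    seed: int

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.labels.min() < 0 or self.labels.max() >= self.k:
            raise ValueError("cluster labels out of range")


@dataclass
class AblationMask:
    """Binary ablation plan in scan coordinates.

    ``raw`` is the selected-cluster mask, ``filtered`` the spatially
    filtered version actually sent to the AOM; ``criterion`` records the
    selection rule, and ``n_frames`` the number of consecutive ablation
    frames.
    """

    raw: np.ndarray
    filtered: np.ndarray
    criterion: dict
    n_frames: int = 8


def cluster_frame(image: MultimodalImage, k: int = 4, seed: int = 0) -> ClusterMap:
    """K-means clustering of the per-pixel channel triples (k-means++ init).

    No spatial features are used: the frame is divided into k independent
    regions purely by multimodal intensity.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    pixels = image.data.reshape(3, -1).T
    if np.unique(pixels, axis=0).shape[0] < k:
        raise ValueError(f"fewer than k={k} distinct pixel values")
    km = KMeans(n_clusters=k, init="k-means++", n_init=4, random_state=seed)
    labels = km.fit_predict(pixels).reshape(image.shape)
    return ClusterMap(labels=labels, k=k, centroids=km.cluster_centers_, seed=seed)


def select_cluster(
    cmap: ClusterMap,
    image: MultimodalImage,
    channel: int | str = SHG,
    rule: str = "highest_mean",
) -> tuple[np.ndarray, dict]:
    """Binary mask of the cluster maximizing mean intensity in one channel.

    Ties resolve to the lowest cluster index with a warning.  Returns the
    raw mask and a criterion record (rule, channel, per-cluster means,
    chosen index).
    """
    if isinstance(channel, str):
        channel = CHANNELS.index(channel.upper())
    if channel not in range(3):
        raise ValueError(f"invalid channel {channel}")
    if rule != "highest_mean":
        raise ValueError(f"unknown selection rule {rule!r}")
    chan = image.data[channel]
    means = np.array(
        [chan[cmap.labels == i].mean() if np.any(cmap.labels == i) else -np.inf
         for i in range(cmap.k)]
    )
    best = means.max()
    winners = np.flatnonzero(np.isclose(means, best))
    if winners.size > 1:
        warnings.warn(
            f"tie between clusters {winners.tolist()} on channel mean; "
            "selecting the lowest index",
            stacklevel=2,
        )
    chosen = int(winners[0])
    criterion = {
        "rule": rule,
        "channel": CHANNELS[channel],
        "cluster_means": means.tolist(),
        "selected_cluster": chosen,
    }
    return cmap.labels == chosen, criterion


def filter_mask(raw: np.ndarray, radius_px: int = 3) -> np.ndarray:
    """Spatially filter a binary mask: median filter then morphological closing.

    Removes speckles smaller than the filter scale and fills comparable
    gaps, making the mask more homogeneous.  ``radius_px < 1`` returns the
    input unchanged with a warning.
    """
    raw = np.asarray(raw)
    if raw.dtype != bool:
        if not np.isin(raw, (0, 1)).all():
            raise ValueError("filter_mask expects a binary raster")
        raw = raw.astype(bool)
    if radius_px < 1:
        warnings.warn("radius < 1: returning mask unchanged", stacklevel=2)
        return raw.copy()
    selem = disk(radius_px)
    out = _median_filter(raw.astype(np.uint8), footprint=selem).astype(bool)
    out = _closing(out, footprint=selem).astype(bool)
    return out


def plan_ablation(
    image: MultimodalImage,
    k: int = 4,
    channel: int | str = SHG,
    radius_px: int = 3,
    n_frames: int = 8,
    seed: int = 0,
) -> AblationMask:
    """Full planning pipeline: cluster, select by channel criterion, filter."""
    cmap = cluster_frame(image, k=k, seed=seed)
    raw, criterion = select_cluster(cmap, image, channel=channel)
    filtered = filter_mask(raw, radius_px=radius_px)
    return AblationMask(raw=raw, filtered=filtered, criterion=criterion, n_frames=n_frames)


class AblationPlanner(BaseEstimator):
    """Estimator wrapper over the planning pipeline.

    ``fit`` clusters a frame and selects the target cluster; ``predict``
    returns the filtered binary mask for the fitted frame (fitted
    attributes: ``cluster_map_``, ``mask_``).
    """

    def __init__(self, k: int = 4, channel="SHG", radius_px: int = 3, n_frames: int = 8, seed: int = 0):
        self.k = k
        self.channel = channel
        self.radius_px = radius_px
        self.n_frames = n_frames
        self.seed = seed

    def fit(self, image: MultimodalImage, y=None) -> "AblationPlanner":
        self.cluster_map_ = cluster_frame(image, k=self.k, seed=self.seed)
        raw, criterion = select_cluster(self.cluster_map_, image, channel=self.channel)
        self.mask_ = AblationMask(
            raw=raw,
            filtered=filter_mask(raw, radius_px=self.radius_px),
            criterion=criterion,
            n_frames=self.n_frames,
        )
        return self

    def predict(self, image: MultimodalImage | None = None) -> np.ndarray:
        if not hasattr(self, "mask_"):
            raise RuntimeError("AblationPlanner is not fitted")
        return self.mask_.filtered


def simulate_ablation(
    phantom: MultimodalImage,
    mask: np.ndarray,
    n_frames: int = 8,
    per_frame_removal: float = 0.26,
) -> list[MultimodalImage]:
    """Simulate selective ablation over consecutive scan frames.

    Masked pixels are attenuated multiplicatively by ``1 -
    per_frame_removal`` each frame (default chosen so that 8 frames leave
    < 10% of the initial intensity); pixels outside the mask are never
    modified.  Returns the frame sequence [after frame 1, ..., after frame
    n_frames]; ``n_frames = 0`` returns an empty sequence (identity).
    """
    mask = np.asarray(mask).astype(bool)
    if mask.shape != phantom.shape:
        raise ValueError(f"mask shape {mask.shape} misaligned with phantom {phantom.shape}")
    if not (0.0 < per_frame_removal < 1.0):
        raise ValueError("per_frame_removal must be in (0, 1)")
    frames = []
    current = phantom.data.copy()
    keep = 1.0 - per_frame_removal
    for _ in range(n_frames):
        current = current.copy()
        current[:, mask] *= keep
        frames.append(MultimodalImage(current, pixel_size=phantom.pixel_size))
    return frames


def wavenumber_difference(pump_nm: float, stokes_nm: float) -> float:
    """CARS wavenumber (cm^-1) probed by a pump/Stokes wavelength pair in nm."""
    if pump_nm <= 0 or stokes_nm <= 0:
        raise ValueError("wavelengths must be positive")
    return 1e7 / pump_nm - 1e7 / stokes_nm


def pulse_energy(avg_power_mW: float, rep_rate_kHz: float) -> float:
    """Pulse energy in microjoules from average power (mW) and repetition rate (kHz)."""
    if avg_power_mW <= 0 or rep_rate_kHz <= 0:
        raise ValueError("power and repetition rate must be positive")
    return (avg_power_mW * 1e-3) / (rep_rate_kHz * 1e3) * 1e6


def export_aom_mask(path: str | Path, mask: AblationMask, pixel_size_um: float | None = None) -> None:
    """Write the filtered mask as a 1-bit PNG plus a JSON geometry sidecar.

    The raster is row-major scanline order matching the acquisition pixel
    grid, ready to gate the AOM during scanning.
    """
    import imageio.v3 as iio

    path = Path(path)
    iio.imwrite(str(path), (mask.filtered.astype(np.uint8) * 255))
    sidecar = {
        "shape": list(mask.filtered.shape),
        "order": "row-major scanline",
        "n_frames": mask.n_frames,
        "criterion": mask.criterion,
        "pixel_size_um": pixel_size_um,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
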
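"""Image-quality metrics: single-image FRC resolution, RMS contrast and SNR.

Fourier ring correlation (FRC) measures the spectral correlation between
two images of the same scene as a function of spatial frequency; the
resolution is read where the (smoothed) curve first drops below a fixed
threshold of 1/7.  The single-image variant splits one acquisition into
two statistically independent half-images by complementary 2x2 pixel
decimation (even/even vs odd/odd sub-lattices); the frequency axis of the
sub-images is corrected by the factor 2 for their halved sampling rate.

Root-mean-square contrast is the population standard deviation of the
pixel intensities.  SNR_sigma is the log ratio between the signal range of
the measurement and the background noise,

    SNR_sigma = 20 log10( (s_max - mu_bg) / sigma_bg )  [dB]

with s_max the image maximum and mu_bg, sigma_bg the mean/SD of a selected
background region.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .images import CHANNELS, MultimodalImage

__all__ = [
    "FRCCurve",
    "frc_resolution",
    "rms_contrast",
    "snr_sigma",
    "QualityReport",
    "quality_report",
    "default_background_region",
]

FRC_THRESHOLD = 1.0 / 7.0
FRC_SMOOTH_WINDOW = 13


@dataclass
class FRCCurve:
    """Radial FRC curve with its threshold crossing.

    ``frequency`` is normalized spatial frequency of the decimated
    sub-images (Nyquist = 0.5); ``correlation`` the ring-wise normalized
    cross-spectral correlation in [-1, 1], smoothed by a centered moving
    average of ``smooth_window`` radial bins.  ``crossing_frequency`` is the
    first sub-threshold crossing (linear interpolation) or None when the
    curve never drops below threshold; ``resolution_um`` is then reported
    as infinity ("beyond Nyquist").
    """

    frequency: np.ndarray
    correlation: np.ndarray
    smooth_window: int
    threshold: float
    crossing_frequency: float | None
    resolution_um: float
    pixel_size: float


def _radial_bins(n: int) -> tuple[np.ndarray, np.ndarray]:
    fy = np.fft.fftfreq(n)
    fx = np.fft.rfftfreq(n)
    r = np.sqrt(fy[:, None] ** 2 + fx[None, :] ** 2)
    n_bins = n // 2
    edges = np.linspace(0.0, 0.5, n_bins + 1)
    idx = np.clip(np.digitize(r, edges) - 1, 0, n_bins - 1)
    return idx, 0.5 * (edges[:-1] + edges[1:])


def _smooth(curve: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return curve
    pad = window // 2
    padded = np.pad(curve, pad, mode="edge")
    kernel = np.ones(window) / window
    return np.convolve(padded, kernel, mode="valid")


def frc_resolution(
    image: np.ndarray,
    pixel_size: float,
    threshold: float = FRC_THRESHOLD,
    smooth: int = FRC_SMOOTH_WINDOW,
) -> FRCCurve:
    """Single-image FRC resolution estimate for one channel.

    The image is center-cropped to an even square, split into the even/even
    and odd/odd 2x2-decimated sub-images, and the ring-wise normalized
    cross-correlation of their spectra is computed.  The resolution is the
    inverse of the first threshold crossing of the smoothed curve,
    converted to micrometers with the decimation-corrected sampling
    (sub-image pixel size = 2 * pixel_size):

        resolution = 2 * pixel_size / f_cross      (f in cycles/sub-pixel)
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("frc_resolution expects a single-channel 2-D image")
    if min(img.shape) < 64:
        raise ValueError("image must be at least 64 x 64 pixels")
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    if img.max() == img.min():
        raise ValueError("degenerate (constant) image")

    # center-crop to a square with even side
    side = (min(img.shape) // 2) * 2
    r0 = (img.shape[0] - side) // 2
    c0 = (img.shape[1] - side) // 2
    img = img[r0 : r0 + side, c0 : c0 + side]

    sub1 = img[0::2, 0::2]
    sub2 = img[1::2, 1::2]
    f1 = np.fft.rfft2(sub1 - sub1.mean())
    f2 = np.fft.rfft2(sub2 - sub2.mean())
    # the odd/odd lattice is offset by half a sub-pixel along both axes;
    # remove the resulting spectral phase ramp so a common band-limited
    # scene correlates to ~1 across its band
    fy = np.fft.fftfreq(sub1.shape[0])[:, None]
    fx = np.fft.rfftfreq(sub1.shape[1])[None, :]
    f2 = f2 * np.exp(-2j * np.pi * (fy + fx) * 0.5)

    idx, freqs = _radial_bins(sub1.shape[0])
    num = np.bincount(idx.ravel(), weights=(f1 * np.conj(f2)).real.ravel(), minlength=freqs.size)
    d1 = np.bincount(idx.ravel(), weights=(np.abs(f1) ** 2).ravel(), minlength=freqs.size)
    d2 = np.bincount(idx.ravel(), weights=(np.abs(f2) ** 2).ravel(), minlength=freqs.size)
    denom = np.sqrt(d1 * d2)
    with np.errstate(invalid="ignore", divide="ignore"):
        frc = np.where(denom > 0, num / denom, 0.0)
    # the DC ring holds only the (subtracted) mean and carries no signal;
    # copy its neighbour so numerical noise cannot leak into the smoothing
    frc[0] = frc[1]
    frc_s = _smooth(frc, smooth)

    # crossing search skips the DC ring (mean-subtracted spectra make it
    # uninformative); a curve that never drops below threshold reports the
    # beyond-Nyquist sentinel
    crossing = None
    below = frc_s < threshold
    if below[1]:
        crossing = float(freqs[1])
    else:
        for i in range(2, below.size):
            if below[i] and not below[i - 1]:
                f_lo, f_hi = freqs[i - 1], freqs[i]
                y_lo, y_hi = frc_s[i - 1], frc_s[i]
                crossing = f_lo + (y_lo - threshold) / (y_lo - y_hi) * (f_hi - f_lo)
                break

    if crossing is None:
        resolution = float("inf")  # beyond-Nyquist sentinel
    else:
        resolution = 2.0 * pixel_size / crossing
    return FRCCurve(
        frequency=freqs,
        correlation=frc_s,
        smooth_window=smooth,
        threshold=threshold,
        crossing_frequency=crossing,
        resolution_um=resolution,
        pixel_size=pixel_size,
    )


def rms_contrast(image: np.ndarray) -> float:
    """Population standard deviation of the pixel intensities."""
    img = np.asarray(image, dtype=float)
    if img.size == 0:
        raise ValueError("empty image")
    return float(img.std())


def default_background_region(image: np.ndarray, frac: float = 0.05) -> tuple[int, int, int, int]:
    """The 5% x 5% corner block with lowest mean, as (row, col, height, width)."""
    img = np.asarray(image, dtype=float)
    h = max(int(round(img.shape[0] * frac)), 5)
    w = max(int(round(img.shape[1] * frac)), 5)
    corners = {
        (0, 0): img[:h, :w],
        (0, img.shape[1] - w): img[:h, -w:],
        (img.shape[0] - h, 0): img[-h:, :w],
        (img.shape[0] - h, img.shape[1] - w): img[-h:, -w:],
    }
    (r, c), _ = min(corners.items(), key=lambda kv: kv[1].mean())
    return r, c, h, w


def snr_sigma(image: np.ndarray, background_region: tuple[int, int, int, int] | None = None) -> float:
    """SNR_sigma in dB: 20 log10((s_max - mu_bg) / sigma_bg).

    ``background_region`` is (row, col, height, width); by default the
    lowest-mean 5% x 5% corner block is used.
    """
    img = np.asarray(image, dtype=float)
    if background_region is None:
        background_region = default_background_region(img)
    r, c, h, w = background_region
    if r < 0 or c < 0 or r + h > img.shape[0] or c + w > img.shape[1]:
        raise ValueError("background region outside image")
    if h * w < 25:
        raise ValueError("background region must contain at least 25 pixels")
    bg = img[r : r + h, c : c + w]
    mu_bg, sd_bg = float(bg.mean()), float(bg.std())
    if sd_bg == 0:
        raise ValueError("degenerate background (zero standard deviation)")
    s_max = float(img.max())
    if s_max <= mu_bg:
        warnings.warn("image maximum does not exceed background mean", stacklevel=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        return float(20.0 * np.log10((s_max - mu_bg) / sd_bg))


@dataclass
class QualityReport:
    """Per-channel FRC resolution (um), C_RMS and SNR_sigma (dB)."""

    frc_res_um: dict[str, float]
    c_rms: dict[str, float]
    snr_db: dict[str, float]
    background_region: tuple[int, int, int, int]


def quality_report(
    image: MultimodalImage, background_region: tuple[int, int, int, int] | None = None
) -> QualityReport:
    """Compute all three metrics for each of the CARS/TPEF/SHG channels."""
    if background_region is None:
        background_region = default_background_region(image.data.mean(axis=0))
    frc_res, crms, snr = {}, {}, {}
    for ch, name in enumerate(CHANNELS):
        chan = image.data[ch]
        frc_res[name] = frc_resolution(chan, image.pixel_size).resolution_um
        crms[name] = rms_contrast(chan)
        snr[name] = snr_sigma(chan, background_region)
    return QualityReport(
        frc_res_um=frc_res, c_rms=crms, snr_db=snr, background_region=background_region
    )
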
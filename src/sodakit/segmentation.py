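"""Cluster segmentation of two-channel count images.

Pipeline: a foreground mask from the blurred channel sum, à-trous
B3-spline wavelet spot detection per channel, size/extent filtering, and
feature annotation with intensity-weighted centroids computed on the raw
image.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.optimize import curve_fit
from skimage import measure

__all__ = [
    "RawImagePair",
    "ForegroundMask",
    "ClusterRecord",
    "compute_foreground_mask",
    "wavelet_spot_detection",
    "filter_and_label_clusters",
    "compute_cluster_features",
    "estimate_localization_error",
    "fit_fwhm_line_profile",
    "records_to_dataframe",
]

FEATURE_COLUMNS = (
    "area",
    "eccentricity",
    "perimeter",
    "major_axis_length",
    "minor_axis_length",
)


@dataclass
class RawImagePair:
    ch1: np.ndarray
    ch2: np.ndarray
    pixel_size: float  # nm / px

    def __post_init__(self) -> None:
        self.ch1 = np.asarray(self.ch1)
        self.ch2 = np.asarray(self.ch2)
        if self.ch1.shape != self.ch2.shape:
            raise ValueError("channel shapes differ")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")


@dataclass
class ForegroundMask:
    mask: np.ndarray
    pixel_size: float

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def area_px(self) -> int:
        return int(np.count_nonzero(self.mask))

    @property
    def area_nm2(self) -> float:
        return self.area_px * self.pixel_size**2

    def contains(self, x_nm, y_nm) -> np.ndarray:
        """Nearest-pixel membership test for nm coordinates."""
        cols = np.round(np.asarray(x_nm) / self.pixel_size).astype(int)
        rows = np.round(np.asarray(y_nm) / self.pixel_size).astype(int)
        h, w = self.mask.shape
        ok = (rows >= 0) & (rows < h) & (cols >= 0) & (cols < w)
        out = np.zeros_like(ok)
        out[ok] = self.mask[rows[ok], cols[ok]]
        return out


@dataclass
class ClusterRecord:
    """One segmented cluster with morphology features.

    Centroid in nm (x = column, y = row); area in um^2, perimeter and
    axis lengths in um.
    """

    id: int
    channel: int
    rows: np.ndarray
    cols: np.ndarray
    intensities: np.ndarray
    pixel_size: float
    weighted_centroid: tuple  # (x_nm, y_nm)
    area: float
    eccentricity: float
    perimeter: float
    major_axis_length: float
    minor_axis_length: float
    total_intensity: float

    @property
    def area_px(self) -> int:
        return len(self.rows)


def compute_foreground_mask(
    images: RawImagePair,
    blur_sd: float = 10.0,
    threshold_fraction: float = 0.5,
) -> ForegroundMask:
    """Mask = blurred channel sum above a fraction of its frame mean.

    ``blur_sd`` is the Gaussian standard deviation in pixels; the mean
    is taken over the whole blurred frame.  All-zero input yields an
    empty mask with a warning.
    """
    total = images.ch1.astype(float) + images.ch2.astype(float)
    if not np.any(total):
        warnings.warn("all-zero image pair: foreground mask is empty",
                      stacklevel=2)
        return ForegroundMask(np.zeros_like(total, dtype=bool),
                              images.pixel_size)
    blurred = ndimage.gaussian_filter(total, sigma=blur_sd)
    mask = blurred > threshold_fraction * blurred.mean()
    return ForegroundMask(mask, images.pixel_size)


# ---------------------------------------------------------------------------
# à-trous wavelet detection
# ---------------------------------------------------------------------------

_B3 = np.array([1.0, 4.0, 6.0, 4.0, 1.0]) / 16.0


def _atrous_planes(image: np.ndarray, n_scales: int) -> list[np.ndarray]:
    """Detail planes W_1..W_n of the undecimated B3-spline transform."""
    approx = image.astype(float)
    planes = []
    for j in range(1, n_scales + 1):
        step = 2 ** (j - 1)
        kernel = np.zeros(4 * step + 1)
        kernel[:: step] = _B3
        smoothed = ndimage.convolve1d(approx, kernel, axis=0, mode="reflect")
        smoothed = ndimage.convolve1d(smoothed, kernel, axis=1, mode="reflect")
        planes.append(approx - smoothed)
        approx = smoothed
    return planes


def wavelet_spot_detection(
    image: np.ndarray,
    scales: tuple[int, ...] = (3, 4),
    k_mad: float = 3.0,
) -> np.ndarray:
    """Binary spot detection by à-trous wavelet hard thresholding.

    Each requested detail plane is thresholded at ``k_mad`` times its
    robust noise scale (MAD / 0.6745); the detection is the intersection
    of the significant pixels of all requested planes.
    """
    image = np.asarray(image)
    scales = tuple(sorted(int(s) for s in scales))
    if not scales or min(scales) < 1:
        raise ValueError("scales must be positive integers")
    min_size = 2 ** max(scales)
    if min(image.shape) < min_size:
        raise ValueError(
            f"image too small for scales {scales}: each dimension must be "
            f">= {min_size} px"
        )
    if not np.any(image):
        return np.zeros(image.shape, dtype=bool)
    planes = _atrous_planes(image, max(scales))
    detection = np.ones(image.shape, dtype=bool)
    for s in scales:
        w = planes[s - 1]
        mad = np.median(np.abs(w - np.median(w)))
        noise = mad / 0.6745
        detection &= w > k_mad * noise
    return detection


# ---------------------------------------------------------------------------
# filtering and features
# ---------------------------------------------------------------------------

def compute_cluster_features(
    rows: np.ndarray, cols: np.ndarray, pixel_size: float
) -> dict:
    """Morphology features of a pixel support, in physical units.

    Area in um^2; perimeter / axis lengths in um; eccentricity from the
    ellipse with matching second central moments.
    """
    rows = np.asarray(rows, dtype=int)
    cols = np.asarray(cols, dtype=int)
    if len(rows) == 0:
        raise ValueError("empty pixel support")
    r0, c0 = rows.min(), cols.min()
    patch = np.zeros((rows.max() - r0 + 1, cols.max() - c0 + 1), dtype=np.uint8)
    patch[rows - r0, cols - c0] = 1
    prop = measure.regionprops(patch)[0]
    px_um = pixel_size / 1000.0
    return {
        "area": prop.area * px_um**2,
        "eccentricity": float(prop.eccentricity),
        "perimeter": prop.perimeter * px_um,
        "major_axis_length": prop.axis_major_length * px_um,
        "minor_axis_length": prop.axis_minor_length * px_um,
    }


def filter_and_label_clusters(
    detection: np.ndarray,
    mask: ForegroundMask,
    raw: np.ndarray,
    pixel_size: float | None = None,
    channel: int = 1,
    min_area_px: int = 5,
    min_extent_px: int = 3,
) -> list[ClusterRecord]:
    """Connected components of the detection image, filtered and annotated.

    Removes components with area < ``min_area_px`` or bounding box
    thinner than ``min_extent_px`` in either direction, and components
    whose intensity-weighted centroid (computed on the raw image) falls
    outside the foreground mask.
    """
    pixel_size = mask.pixel_size if pixel_size is None else pixel_size
    detection = np.asarray(detection, dtype=bool)
    raw = np.asarray(raw, dtype=float)
    if detection.shape != raw.shape or detection.shape != mask.mask.shape:
        raise ValueError("detection, raw image and mask shapes must agree")
    labels = measure.label(detection, connectivity=2)
    records: list[ClusterRecord] = []
    next_id = 0
    for prop in measure.regionprops(labels, intensity_image=raw):
        if prop.area < min_area_px:
            continue
        minr, minc, maxr, maxc = prop.bbox
        if (maxc - minc) < min_extent_px or (maxr - minr) < min_extent_px:
            continue
        coords = prop.coords
        intens = raw[coords[:, 0], coords[:, 1]]
        total = float(intens.sum())
        if total > 0:
            wr, wc = prop.centroid_weighted
        else:  # degenerate: no counts on support, fall back to geometric
            wr, wc = prop.centroid
        x_nm, y_nm = wc * pixel_size, wr * pixel_size
        if not bool(mask.contains(np.array([x_nm]), np.array([y_nm]))[0]):
            continue
        feats = compute_cluster_features(coords[:, 0], coords[:, 1], pixel_size)
        records.append(
            ClusterRecord(
                id=next_id,
                channel=channel,
                rows=coords[:, 0].copy(),
                cols=coords[:, 1].copy(),
                intensities=intens,
                pixel_size=pixel_size,
                weighted_centroid=(float(x_nm), float(y_nm)),
                total_intensity=total,
                **feats,
            )
        )
        next_id += 1
    return records


def records_to_dataframe(records: list[ClusterRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "id": [r.id for r in records],
            "channel": [r.channel for r in records],
            "x_nm": [r.weighted_centroid[0] for r in records],
            "y_nm": [r.weighted_centroid[1] for r in records],
            "area": [r.area for r in records],
            "eccentricity": [r.eccentricity for r in records],
            "perimeter": [r.perimeter for r in records],
            "major_axis_length": [r.major_axis_length for r in records],
            "minor_axis_length": [r.minor_axis_length for r in records],
            "total_intensity": [r.total_intensity for r in records],
            "area_px": [r.area_px for r in records],
        }
    )


def estimate_localization_error(
    record: ClusterRecord, count_uncertainty: float = 0.005
) -> float:
    """Standard error (nm) of the weighted centroid from count uncertainty.

    Each pixel's count ``I_i`` carries an independent uncertainty
    ``count_uncertainty * I_i``; first-order propagation through
    ``x_bar = sum(I_i x_i) / sum(I_i)`` gives
    ``var(x_bar) = c^2 * sum(I_i^2 (x_i - x_bar)^2) / (sum I_i)^2``.
    Returns the quadrature sum of the x and y components.
    """
    intens = np.asarray(record.intensities, dtype=float)
    total = intens.sum()
    if total <= 0:
        raise ValueError("zero total intensity: localization error undefined")
    x = record.cols * record.pixel_size
    y = record.rows * record.pixel_size
    xbar = (intens * x).sum() / total
    ybar = (intens * y).sum() / total
    c = count_uncertainty
    var_x = c**2 * np.sum(intens**2 * (x - xbar) ** 2) / total**2
    var_y = c**2 * np.sum(intens**2 * (y - ybar) ** 2) / total**2
    return float(np.sqrt(var_x + var_y))


def _lorentzian(x, amplitude, center, gamma, offset):
    return amplitude * gamma**2 / ((x - center) ** 2 + gamma**2) + offset


def fit_fwhm_line_profile(profile: np.ndarray, pixel_size: float) -> float:
    """FWHM (nm) of a single-peak line profile by Lorentzian least squares.

    Fits amplitude, center, half-width gamma and offset; FWHM equals
    ``2 * gamma * pixel_size``.  Raises on flat or non-convergent
    profiles with residual diagnostics.
    """
    profile = np.asarray(profile, dtype=float)
    if np.ptp(profile) == 0:
        raise ValueError("flat profile: no peak to fit")
    x = np.arange(len(profile), dtype=float)
    amp0 = float(np.ptp(profile))
    cen0 = float(np.argmax(profile))
    off0 = float(profile.min())
    half = off0 + amp0 / 2.0
    above = np.flatnonzero(profile >= half)
    gamma0 = max((above[-1] - above[0]) / 2.0, 0.5) if len(above) else 1.0
    try:
        popt, _ = curve_fit(
            _lorentzian, x, profile,
            p0=[amp0, cen0, gamma0, off0],
            maxfev=10000,
        )
    except RuntimeError as exc:
        raise ValueError(f"Lorentzian fit did not converge: {exc}") from exc
    amplitude, center, gamma, offset = popt
    residual = profile - _lorentzian(x, *popt)
    rms = float(np.sqrt(np.mean(residual**2)))
    if amplitude <= 0 or abs(gamma) < 1e-6 or rms > amp0:
        raise ValueError(
            f"Lorentzian fit rejected (amplitude={amplitude:.3g}, "
            f"gamma={gamma:.3g}, residual rms={rms:.3g})"
        )
    return float(2.0 * abs(gamma) * pixel_size)
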
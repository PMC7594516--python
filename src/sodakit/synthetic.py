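"""Ground-truth simulations for the coupling-analysis pipeline.

Generates two-channel count images with a known fraction of
cross-channel cluster pairs at a controlled centroid offset, plus 7-D
Gaussian feature blobs for testing the subtype-discovery chain.
Positions are continuous nm coordinates (x = column * pixel_size,
y = row * pixel_size); rasterization happens only at rendering.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage

from .segmentation import FEATURE_COLUMNS

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "generate_roi_mask",
    "simulate_cluster_pairs",
    "render_image_pair",
    "simulate_feature_blobs",
    "save_dataset",
]

MIN_ROI_SHAPE = 64

#: order of the 7-D feature space used by the subtype analysis
FEATURE_SPACE = tuple(FEATURE_COLUMNS) + ("coupling_distance", "coupling_probability")


@dataclass
class SimulationConfig:
    image_shape: tuple = (512, 512)           # (H, W) px
    pixel_size: float = 15.0                  # nm / px
    psf_fwhm: tuple = (70.0, 70.0)            # nm, per channel
    n_clusters_ch1: int = 300
    n_clusters_ch2: int = 300
    coupling_fraction: float = 0.0            # f in [0, 1]
    coupling_distance_mean: float = 45.0      # nm
    coupling_distance_sd: float = 5.0         # nm
    cluster_area_range: tuple = (2000.0, 12000.0)   # nm^2
    cluster_eccentricity_range: tuple = (0.0, 0.9)
    photon_scale: float = 500.0               # expected peak counts
    background_rate: float = 2.0              # counts / px
    roi_style: str = "dendrite_band"          # {full, dendrite_band}
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.coupling_fraction <= 1.0:
            raise ValueError("coupling_fraction must be in [0, 1]")
        if self.n_clusters_ch1 < 0 or self.n_clusters_ch2 < 0:
            raise ValueError("cluster counts must be >= 0")
        if min(self.psf_fwhm) <= self.pixel_size:
            raise ValueError("psf_fwhm must exceed pixel_size")
        if self.coupling_distance_mean < 0:
            raise ValueError("coupling_distance_mean must be >= 0")
        if self.coupling_distance_sd < 0:
            raise ValueError("coupling_distance_sd must be >= 0")
        if self.roi_style not in ("full", "dendrite_band"):
            raise ValueError(f"unknown roi_style {self.roi_style!r}")


@dataclass
class GroundTruth:
    positions_ch1: np.ndarray     # (n1, 2) nm
    positions_ch2: np.ndarray     # (n2, 2) nm
    coupled_pairs: np.ndarray     # (m, 3): idx_ch1, idx_ch2, offset_nm
    roi_mask: np.ndarray          # bool (H, W)
    pixel_size: float

    def to_dataframe(self) -> pd.DataFrame:
        """One row per cluster: channel, x_nm, y_nm, partner_id, offset_nm."""
        partner1 = np.full(len(self.positions_ch1), -1)
        partner2 = np.full(len(self.positions_ch2), -1)
        offset1 = np.full(len(self.positions_ch1), np.nan)
        offset2 = np.full(len(self.positions_ch2), np.nan)
        for i, j, off in self.coupled_pairs:
            partner1[int(i)] = int(j)
            partner2[int(j)] = int(i)
            offset1[int(i)] = off
            offset2[int(j)] = off
        rows = []
        for ch, pos, partner, offset in (
            (1, self.positions_ch1, partner1, offset1),
            (2, self.positions_ch2, partner2, offset2),
        ):
            rows.append(pd.DataFrame({
                "channel": ch,
                "x_nm": pos[:, 0] if len(pos) else [],
                "y_nm": pos[:, 1] if len(pos) else [],
                "partner_id": partner,
                "offset_nm": offset,
            }))
        return pd.concat(rows, ignore_index=True)


def generate_roi_mask(shape: tuple, style: str, seed: int = 0) -> np.ndarray:
    """Binary ROI mask: full frame or a curved band with protrusions.

    ``dendrite_band`` draws a smooth sinusoidal band (per-column
    contiguous, hence connected) whose half-width carries a few Gaussian
    bumps; foreground fraction stays within [0.2, 0.8].
    """
    h, w = shape
    if h < MIN_ROI_SHAPE or w < MIN_ROI_SHAPE:
        raise ValueError(
            f"ROI shape must be at least {MIN_ROI_SHAPE}x{MIN_ROI_SHAPE} px"
        )
    if style == "full":
        return np.ones(shape, dtype=bool)
    if style != "dendrite_band":
        raise ValueError(f"unknown ROI style {style!r}")
    rng = np.random.default_rng(seed)
    x = np.arange(w) / w
    phase1, phase2 = rng.uniform(0, 2 * np.pi, size=2)
    center = h * (0.5
                  + 0.15 * np.sin(2 * np.pi * rng.uniform(0.7, 1.4) * x + phase1)
                  + 0.06 * np.sin(2 * np.pi * rng.uniform(2.0, 3.2) * x + phase2))
    halfwidth = np.full(w, 0.13 * h)
    for _ in range(rng.integers(3, 6)):  # protrusion bumps
        loc = rng.uniform(0.1, 0.9) * w
        amp = rng.uniform(0.04, 0.10) * h
        sd = rng.uniform(0.01, 0.03) * w
        halfwidth += amp * np.exp(-0.5 * ((np.arange(w) - loc) / sd) ** 2)
    rows = np.arange(h)[:, None]
    mask = np.abs(rows - center[None, :]) <= halfwidth[None, :]
    frac = mask.mean()
    assert 0.2 <= frac <= 0.8, f"mask fraction {frac:.2f} out of range"
    return mask


def _uniform_in_mask(mask, n, rng, pixel_size):
    flat = np.flatnonzero(mask)
    choice = rng.choice(flat, size=n, replace=True)
    r, c = np.unravel_index(choice, mask.shape)
    offs = rng.uniform(-0.5, 0.5, size=(n, 2))
    return np.column_stack([(c + offs[:, 0]) * pixel_size,
                            (r + offs[:, 1]) * pixel_size])


def _inside(mask, pts, pixel_size):
    cols = np.round(pts[:, 0] / pixel_size).astype(int)
    rows = np.round(pts[:, 1] / pixel_size).astype(int)
    h, w = mask.shape
    ok = (rows >= 0) & (rows < h) & (cols >= 0) & (cols < w)
    out = np.zeros(len(pts), dtype=bool)
    out[ok] = mask[rows[ok], cols[ok]]
    return out


def simulate_cluster_pairs(config: SimulationConfig) -> GroundTruth:
    """Place channel-1 clusters by CSR; pair a fraction ``f`` with
    channel-2 partners at a truncated-Normal offset and uniform angle;
    remaining channel-2 clusters are CSR.  Deterministic given the seed.
    """
    rng = np.random.default_rng([config.seed, 1])
    mask = generate_roi_mask(config.image_shape, config.roi_style, config.seed)
    px = config.pixel_size
    n1, n2 = config.n_clusters_ch1, config.n_clusters_ch2
    pos1 = _uniform_in_mask(mask, n1, rng, px) if n1 else np.empty((0, 2))
    n_pairs = min(int(round(config.coupling_fraction * n1)), n2)
    paired_idx = rng.permutation(n1)[:n_pairs] if n_pairs else np.empty(0, int)
    partners = np.empty((n_pairs, 2))
    offsets = np.empty(n_pairs)
    for k, i in enumerate(paired_idx):
        for _ in range(1000):
            if config.coupling_distance_sd == 0:
                length = config.coupling_distance_mean
            else:
                length = rng.normal(config.coupling_distance_mean,
                                    config.coupling_distance_sd)
                if length < 0:
                    continue
            angle = rng.uniform(0, 2 * np.pi)
            cand = pos1[i] + length * np.array([np.cos(angle), np.sin(angle)])
            if _inside(mask, cand[None, :], px)[0]:
                partners[k] = cand
                offsets[k] = length
                break
        else:
            raise RuntimeError("could not place coupled partner inside ROI")
    n_free = n2 - n_pairs
    free = _uniform_in_mask(mask, n_free, rng, px) if n_free else np.empty((0, 2))
    pos2 = np.vstack([partners, free]) if n2 else np.empty((0, 2))
    coupled = np.column_stack([
        paired_idx.astype(float), np.arange(n_pairs, dtype=float), offsets
    ]) if n_pairs else np.empty((0, 3))
    return GroundTruth(
        positions_ch1=pos1, positions_ch2=pos2, coupled_pairs=coupled,
        roi_mask=mask, pixel_size=px,
    )


def _render_channel(positions, shape, pixel_size, psf_fwhm, config, rng):
    h, w = shape
    image = np.zeros(shape, dtype=float)
    sigma_psf = psf_fwhm / 2.3548200450309493  # FWHM -> sd
    for x_nm, y_nm in positions:
        area = rng.uniform(*config.cluster_area_range)
        ecc = rng.uniform(*config.cluster_eccentricity_range)
        axis_ratio = np.sqrt(1.0 - ecc**2)      # minor / major
        a = np.sqrt(area / (np.pi * axis_ratio))  # semi-major, nm
        b = a * axis_ratio
        s_maj = np.sqrt((a / 2.0) ** 2 + sigma_psf**2)
        s_min = np.sqrt((b / 2.0) ** 2 + sigma_psf**2)
        theta = rng.uniform(0, np.pi)
        amp = config.photon_scale * rng.uniform(0.5, 1.5)
        half = int(np.ceil(4.0 * s_maj / pixel_size))
        c0 = int(round(x_nm / pixel_size))
        r0 = int(round(y_nm / pixel_size))
        rlo, rhi = max(r0 - half, 0), min(r0 + half + 1, h)
        clo, chi = max(c0 - half, 0), min(c0 + half + 1, w)
        if rlo >= rhi or clo >= chi:
            continue
        cc, rr = np.meshgrid(np.arange(clo, chi), np.arange(rlo, rhi))
        dx = cc * pixel_size - x_nm
        dy = rr * pixel_size - y_nm
        u = dx * np.cos(theta) + dy * np.sin(theta)
        v = -dx * np.sin(theta) + dy * np.cos(theta)
        image[rlo:rhi, clo:chi] += amp * np.exp(
            -0.5 * ((u / s_maj) ** 2 + (v / s_min) ** 2)
        )
    return image


def render_image_pair(
    truth: GroundTruth, config: SimulationConfig, noise: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Render both channels as count images (uint16).

    Each cluster is an anisotropic Gaussian blob (area and eccentricity
    drawn from the configured ranges) broadened by the channel PSF, with
    post-PSF peak amplitude ~ photon_scale * U(0.5, 1.5).  With
    ``noise=True`` the signal-plus-background expectation is Poisson
    sampled (photon-counting detector model).
    """
    shape = config.image_shape
    for pos in (truth.positions_ch1, truth.positions_ch2):
        if len(pos):
            if (np.any(pos < -truth.pixel_size / 2)
                    or np.any(pos[:, 0] > (shape[1] - 0.5) * truth.pixel_size)
                    or np.any(pos[:, 1] > (shape[0] - 0.5) * truth.pixel_size)):
                raise ValueError("all centroids must lie within the frame")
    rng = np.random.default_rng([config.seed, 2])
    images = []
    for pos, fwhm in ((truth.positions_ch1, config.psf_fwhm[0]),
                      (truth.positions_ch2, config.psf_fwhm[1])):
        expectation = _render_channel(
            pos, shape, truth.pixel_size, fwhm, config, rng
        ) + config.background_rate
        counts = rng.poisson(expectation) if noise else np.round(expectation)
        images.append(np.clip(counts, 0, 65535).astype(np.uint16))
    return images[0], images[1]


def simulate_feature_blobs(
    k: int, n_per_group: int, separation: float, seed: int = 0
) -> pd.DataFrame:
    """7-D Gaussian blobs with centers >= ``separation`` apart.

    Returns a DataFrame with the 7 feature columns plus a ``label``
    column of true group ids; per-dimension blob sd is separation / 8.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    rng = np.random.default_rng(seed)
    centers = []
    for _ in range(5000):
        cand = rng.uniform(0, 1, size=7)
        if all(np.linalg.norm(cand - c) >= separation for c in centers):
            centers.append(cand)
        if len(centers) == k:
            break
    else:
        raise ValueError(
            f"could not place {k} blob centers at separation {separation}"
        )
    sd = separation / 8.0
    frames = []
    for g, center in enumerate(centers):
        pts = rng.normal(center, sd, size=(n_per_group, 7))
        df = pd.DataFrame(pts, columns=list(FEATURE_SPACE))
        df["label"] = g
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def save_dataset(
    truth: GroundTruth,
    images: tuple[np.ndarray, np.ndarray],
    config: SimulationConfig,
    outdir: str | Path,
) -> dict:
    """Write images (16-bit TIFF), ROI mask (8-bit TIFF), ground-truth
    CSV and resolved config JSON; returns the written paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "ch1": outdir / "ch1.tif",
        "ch2": outdir / "ch2.tif",
        "roi": outdir / "roi_mask.tif",
        "truth": outdir / "ground_truth.csv",
        "config": outdir / "simulation_config.json",
    }
    tifffile.imwrite(paths["ch1"], images[0].astype(np.uint16))
    tifffile.imwrite(paths["ch2"], images[1].astype(np.uint16))
    tifffile.imwrite(paths["roi"], truth.roi_mask.astype(np.uint8) * 255)
    truth.to_dataframe().to_csv(paths["truth"], index=False)
    with open(paths["config"], "w") as fh:
        json.dump(asdict(config), fh, indent=2, default=list)
    return {k: str(v) for k, v in paths.items()}
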
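"""Ring-binned Ripley coupling statistics between two channels of clusters.

The analysis quantifies non-random spatial association between two sets
of cluster centroids.  Cross-channel centroid distances are binned into
concentric rings; a boundary-corrected Ripley ``K`` is accumulated per
ring (vector ``G``), standardized against its complete-spatial-randomness
(CSR) null moments, thresholded at the universal threshold
``T(N) = 2 ln N``, and converted into a per-pair coupling probability.

All coordinates are in nanometres with ``x = column * pixel_size`` and
``y = row * pixel_size`` (origin at the centre of pixel ``(0, 0)``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import sqrtm
from scipy.spatial import cKDTree

__all__ = [
    "RingSet",
    "RipleyStatistics",
    "SodaSummary",
    "SodaResult",
    "pairwise_candidate_distances",
    "edge_correction_weights",
    "compute_G_vector",
    "sample_uniform_in_mask",
    "null_moments",
    "estimate_ring_coupling_matrix",
    "reduce_and_threshold",
    "pair_coupling_probabilities",
    "summarize_coupling",
    "analyze_points",
]

#: default cap on the boundary-correction weight; bounds the variance
#: contributed by centroids sitting in very thin mask processes.
WEIGHT_CAP = 8.0


@dataclass(frozen=True)
class RingSet:
    """Concentric annuli over which coupling is assessed.

    Ring ``i`` (0-based) covers the half-open distance interval
    ``(r_i, r_{i+1}]`` with ``r_i = i * ring_width``.
    """

    n_rings: int = 16
    ring_width: float = 15.0

    def __post_init__(self) -> None:
        if self.n_rings < 1:
            raise ValueError("n_rings must be >= 1")
        if self.ring_width <= 0:
            raise ValueError("ring_width must be > 0")

    @property
    def radii(self) -> np.ndarray:
        """Ring boundaries ``r_0 .. r_N`` in nm (``r_0 = 0``)."""
        return np.arange(self.n_rings + 1) * self.ring_width

    @property
    def r_max(self) -> float:
        return self.n_rings * self.ring_width

    @property
    def threshold(self) -> float:
        """Universal threshold ``T(N) = 2 ln(N)`` (natural log)."""
        return 2.0 * np.log(self.n_rings)

    def ring_index(self, distances) -> np.ndarray:
        """Ring index for each distance; -1 if outside every ring.

        Membership is half-open, ``r_i < d <= r_{i+1}``; a distance of
        exactly 0 therefore belongs to no ring.
        """
        d = np.asarray(distances, dtype=float)
        idx = np.searchsorted(self.radii, d, side="left") - 1
        idx = np.where((d <= 0) | (d > self.r_max), -1, idx)
        return idx


@dataclass
class RipleyStatistics:
    """Per-ring statistics for one image / channel pair."""

    G: np.ndarray
    mu: np.ndarray
    sigma: np.ndarray
    A: np.ndarray
    G0: np.ndarray          # thresholded reduced vector (0 where not significant)
    G0_raw: np.ndarray      # reduced vector before thresholding
    threshold: float

    @property
    def significant(self) -> np.ndarray:
        return self.G0 > 0


@dataclass
class SodaSummary:
    """Image-level coupling summary.

    ``coupling_index`` is the probability-weighted estimate of the
    fraction of a channel's clusters with a non-random partner
    (sum of pair coupling probabilities / cluster count, clipped to
    [0, 1]); ``coupled_fraction`` is the raw fraction of clusters with
    at least one pair of positive coupling probability.
    """

    n_ch1: int
    n_ch2: int
    coupled_ids_ch1: np.ndarray
    coupled_ids_ch2: np.ndarray
    uncoupled_ids_ch1: np.ndarray
    uncoupled_ids_ch2: np.ndarray
    coupling_index_ch1: float
    coupling_index_ch2: float
    coupled_fraction_ch1: float
    coupled_fraction_ch2: float
    mean_probability_ch1: float
    mean_probability_ch2: float
    cluster_probability_ch1: np.ndarray
    cluster_probability_ch2: np.ndarray
    cluster_distance_ch1: np.ndarray
    cluster_distance_ch2: np.ndarray
    ring_mean_probability: np.ndarray
    ring_pair_counts: np.ndarray
    mean_coupling_distance: float

    def to_dict(self) -> dict:
        return {
            "n_ch1": int(self.n_ch1),
            "n_ch2": int(self.n_ch2),
            "coupling_index_ch1": float(self.coupling_index_ch1),
            "coupling_index_ch2": float(self.coupling_index_ch2),
            "coupled_fraction_ch1": float(self.coupled_fraction_ch1),
            "coupled_fraction_ch2": float(self.coupled_fraction_ch2),
            "mean_probability_ch1": float(self.mean_probability_ch1),
            "mean_probability_ch2": float(self.mean_probability_ch2),
            "mean_coupling_distance_nm": float(self.mean_coupling_distance),
            "ring_mean_probability": [float(v) for v in self.ring_mean_probability],
            "ring_pair_counts": [int(v) for v in self.ring_pair_counts],
        }


@dataclass
class SodaResult:
    stats: RipleyStatistics
    pairs: pd.DataFrame
    summary: SodaSummary


# ---------------------------------------------------------------------------
# pair enumeration
# ---------------------------------------------------------------------------

def pairwise_candidate_distances(
    positions_ch1: np.ndarray,
    positions_ch2: np.ndarray,
    rings: RingSet,
) -> pd.DataFrame:
    """All cross-channel pairs with centroid distance in ``(0, r_max]``.

    Uses a k-d tree; the result is identical to exhaustive enumeration.
    Returns a DataFrame with columns ``idx1, idx2, distance, ring``.
    """
    p1 = np.atleast_2d(np.asarray(positions_ch1, dtype=float))
    p2 = np.atleast_2d(np.asarray(positions_ch2, dtype=float))
    if len(p1) == 0 or len(p2) == 0:
        return pd.DataFrame(columns=["idx1", "idx2", "distance", "ring"])
    tree1 = cKDTree(p1)
    tree2 = cKDTree(p2)
    neighbors = tree1.query_ball_tree(tree2, r=rings.r_max)
    idx1 = np.repeat(np.arange(len(p1)), [len(n) for n in neighbors])
    idx2 = np.concatenate([np.asarray(n, dtype=int) for n in neighbors]) \
        if len(idx1) else np.empty(0, dtype=int)
    if len(idx1) == 0:
        return pd.DataFrame(columns=["idx1", "idx2", "distance", "ring"])
    d = np.linalg.norm(p1[idx1] - p2[idx2], axis=1)
    ring = rings.ring_index(d)
    keep = ring >= 0
    return pd.DataFrame(
        {"idx1": idx1[keep], "idx2": idx2[keep],
         "distance": d[keep], "ring": ring[keep]}
    )


# ---------------------------------------------------------------------------
# boundary correction
# ---------------------------------------------------------------------------

def edge_correction_weights(
    centers: np.ndarray,
    distances: np.ndarray,
    roi_mask: np.ndarray,
    pixel_size: float,
    n_angles: int = 64,
    cap: float = WEIGHT_CAP,
) -> np.ndarray:
    """Boundary-correction weight ``k`` for circles around ``centers``.

    ``k = 1 / f`` where ``f`` is the fraction of the circle of radius
    ``distance`` lying inside the ROI, estimated by sampling the circle
    at ``n_angles`` equally spaced angles ``2*pi*j/n_angles``.  A point
    is inside if its nearest pixel is foreground.  ``k`` is capped at
    ``cap``.
    """
    if n_angles < 64:
        raise ValueError("n_angles must be >= 64")
    centers = np.atleast_2d(np.asarray(centers, dtype=float))
    distances = np.asarray(distances, dtype=float)
    if np.any(distances <= 0):
        raise ValueError("edge correction requires distance > 0")
    mask = np.asarray(roi_mask, dtype=bool)
    h, w = mask.shape
    theta = 2.0 * np.pi * np.arange(n_angles) / n_angles
    dx = np.cos(theta)
    dy = np.sin(theta)
    x = centers[:, 0, None] + distances[:, None] * dx
    y = centers[:, 1, None] + distances[:, None] * dy
    cols = np.round(x / pixel_size).astype(int)
    rows = np.round(y / pixel_size).astype(int)
    inframe = (rows >= 0) & (rows < h) & (cols >= 0) & (cols < w)
    inside = np.zeros_like(inframe)
    inside[inframe] = mask[rows[inframe], cols[inframe]]
    frac = inside.mean(axis=1)
    if np.any(frac == 0):
        raise ValueError(
            "circle entirely outside ROI for some pair; centers must lie "
            "inside the foreground mask"
        )
    return np.minimum(1.0 / frac, cap)


# ---------------------------------------------------------------------------
# G vector and null moments
# ---------------------------------------------------------------------------

def compute_G_vector(
    ring: np.ndarray,
    weights: np.ndarray,
    n1: int,
    n2: int,
    roi_area: float,
    rings: RingSet,
) -> np.ndarray:
    """Ring increments of the boundary-corrected Ripley ``K``.

    ``K(r) = roi_area / (n1 n2) * sum_{d <= r} k`` and
    ``G_i = K(r_{i+1}) - K(r_i)``; since the rings partition ``(0, r_N]``
    this equals the weighted pair count per ring times
    ``roi_area / (n1 n2)``.
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("no clusters in channel: n1 and n2 must be > 0")
    ring = np.asarray(ring, dtype=int)
    weights = np.asarray(weights, dtype=float)
    counts = np.bincount(ring, weights=weights, minlength=rings.n_rings)
    return roi_area / (n1 * n2) * counts[: rings.n_rings]


def sample_uniform_in_mask(
    roi_mask: np.ndarray,
    n: int,
    rng: np.random.Generator,
    pixel_size: float,
) -> np.ndarray:
    """``n`` points uniform over the foreground area (continuous, nm).

    A foreground pixel ``(r, c)`` covers the square
    ``[c*px - px/2, c*px + px/2) x [r*px - px/2, r*px + px/2)``.
    """
    mask = np.asarray(roi_mask, dtype=bool)
    flat = np.flatnonzero(mask)
    if len(flat) == 0:
        raise ValueError("empty ROI mask")
    choice = rng.choice(flat, size=n, replace=True)
    rows, cols = np.unravel_index(choice, mask.shape)
    offs = rng.uniform(-0.5, 0.5, size=(n, 2))
    x = (cols + offs[:, 0]) * pixel_size
    y = (rows + offs[:, 1]) * pixel_size
    return np.column_stack([x, y])


def _csr_G_samples(
    rings: RingSet,
    roi_mask: np.ndarray,
    pixel_size: float,
    n1: int,
    n2: int,
    n_reps: int,
    rng: np.random.Generator,
    n_angles: int,
    cap: float,
) -> np.ndarray:
    roi_area = float(np.count_nonzero(roi_mask)) * pixel_size**2
    samples = np.empty((n_reps, rings.n_rings))
    for rep in range(n_reps):
        p1 = sample_uniform_in_mask(roi_mask, n1, rng, pixel_size)
        p2 = sample_uniform_in_mask(roi_mask, n2, rng, pixel_size)
        pairs = pairwise_candidate_distances(p1, p2, rings)
        if len(pairs) == 0:
            samples[rep] = 0.0
            continue
        w = edge_correction_weights(
            p1[pairs["idx1"].to_numpy()],
            pairs["distance"].to_numpy(),
            roi_mask, pixel_size, n_angles=n_angles, cap=cap,
        )
        samples[rep] = compute_G_vector(
            pairs["ring"].to_numpy(), w, n1, n2, roi_area, rings
        )
    return samples


def null_moments(
    rings: RingSet,
    roi_mask: np.ndarray,
    pixel_size: float,
    n1: int,
    n2: int,
    mode: str = "analytic",
    n_reps: int = 100,
    seed: int = 0,
    n_angles: int = 64,
    cap: float = WEIGHT_CAP,
    return_samples: bool = False,
):
    """CSR null mean and standard deviation of ``G``.

    ``mode='analytic'``: mu_i = pi * (r_{i+1}^2 - r_i^2) (the CSR
    expectation of the boundary-corrected K increments, independent of
    ROI shape); sigma is always estimated by Monte Carlo (``n_reps``
    uniform re-draws of both channels over the ROI, counts preserved).
    ``mode='monte_carlo'``: mu is the empirical Monte-Carlo mean too.
    """
    if mode not in ("analytic", "monte_carlo"):
        raise ValueError(f"unknown mode {mode!r}")
    if n_reps < 10:
        raise ValueError("n_reps must be >= 10")
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least 2 clusters per channel")
    if n1 + n2 <= 100:
        warnings.warn(
            "fewer than ~100 total objects: Gaussian approximation of the "
            "ring statistics may be unreliable", stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    samples = _csr_G_samples(
        rings, roi_mask, pixel_size, n1, n2, n_reps, rng, n_angles, cap
    )
    radii = rings.radii
    if mode == "analytic":
        mu = np.pi * np.diff(radii**2)
    else:
        mu = samples.mean(axis=0)
    sigma = samples.std(axis=0, ddof=1)
    # guard: a ring with zero empirical variance would make the reduced
    # vector undefined; fall back to the Poisson-scale floor
    if np.any(sigma <= 0):
        roi_area = float(np.count_nonzero(roi_mask)) * pixel_size**2
        scale = roi_area / (n1 * n2)
        lam = np.maximum(mu / scale, 1e-12)
        sigma = np.where(sigma > 0, sigma, scale * np.sqrt(lam))
    if return_samples:
        return mu, sigma, samples
    return mu, sigma


def estimate_ring_coupling_matrix(
    samples: np.ndarray, mu: np.ndarray, sigma: np.ndarray
) -> np.ndarray:
    """Ring-coupling matrix ``A`` from CSR Monte-Carlo samples of ``G``.

    ``A`` is the square root of the empirical correlation matrix of the
    standardized samples, so that ``A^{-1}`` whitens residual overlap
    between rings.  With disjoint annuli the correlation is near the
    identity; shrinkage towards the identity keeps ``A`` well
    conditioned at small ``n_reps``.
    """
    z = (samples - mu) / sigma
    corr = np.corrcoef(z, rowvar=False)
    corr = 0.5 * (corr + corr.T)
    n = corr.shape[0]
    corr = 0.8 * corr + 0.2 * np.eye(n)
    a = np.real_if_close(sqrtm(corr))
    return np.asarray(a, dtype=float)


# ---------------------------------------------------------------------------
# reduction, thresholding, coupling probability
# ---------------------------------------------------------------------------

def reduce_and_threshold(
    G: np.ndarray,
    mu: np.ndarray,
    sigma: np.ndarray,
    A: np.ndarray | None = None,
    threshold: float | None = None,
) -> RipleyStatistics:
    """Reduced ring vector ``G0 = diag(1/sigma) A^{-1} (G - mu)``.

    Entries not exceeding the universal threshold ``T(N) = 2 ln N`` are
    set to 0.  Thresholding is idempotent.
    """
    G = np.asarray(G, dtype=float)
    mu = np.asarray(mu, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    n = len(G)
    if A is None:
        A = np.eye(n)
    A = np.asarray(A, dtype=float)
    if np.linalg.cond(A) > 1e12:
        raise np.linalg.LinAlgError("ring-coupling matrix A is singular")
    if np.any(sigma <= 0):
        raise ValueError("sigma must be positive in every ring")
    if threshold is None:
        threshold = 2.0 * np.log(n)
    g0_raw = np.linalg.solve(A, G - mu) / sigma
    g0 = np.where(g0_raw > threshold, g0_raw, 0.0)
    return RipleyStatistics(
        G=G, mu=mu, sigma=sigma, A=A, G0=g0, G0_raw=g0_raw, threshold=threshold
    )


def pair_coupling_probabilities(
    stats: RipleyStatistics, pair_rings: np.ndarray
) -> np.ndarray:
    """Coupling probability for pairs given their ring index.

    ``P = sigma_i * G0_i / G_i`` when ring ``i`` is significant, else 0;
    clipped to [0, 1].
    """
    sig = stats.significant
    if np.any(sig & (stats.G <= 0)):
        raise AssertionError(
            "significant ring with zero G cannot occur (significance "
            "requires excess counts)"
        )
    ring_p = np.zeros(len(stats.G))
    ring_p[sig] = np.clip(
        stats.sigma[sig] * stats.G0[sig] / stats.G[sig], 0.0, 1.0
    )
    pair_rings = np.asarray(pair_rings, dtype=int)
    return ring_p[pair_rings]


def summarize_coupling(
    pairs: pd.DataFrame,
    n1: int,
    n2: int,
    rings: RingSet,
    ids_ch1: np.ndarray | None = None,
    ids_ch2: np.ndarray | None = None,
) -> SodaSummary:
    """Aggregate pair records to cluster- and image-level summaries.

    Per cluster the coupling probability is the max over its pairs and
    the coupling distance is that of the max-P pair.
    """
    ids_ch1 = np.arange(n1) if ids_ch1 is None else np.asarray(ids_ch1)
    ids_ch2 = np.arange(n2) if ids_ch2 is None else np.asarray(ids_ch2)
    p1 = np.zeros(n1)
    p2 = np.zeros(n2)
    d1 = np.full(n1, np.nan)
    d2 = np.full(n2, np.nan)
    ring_sum = np.zeros(rings.n_rings)
    ring_cnt = np.zeros(rings.n_rings, dtype=int)
    total_p = 0.0
    coupled_distances = []
    if len(pairs):
        for row in pairs.itertuples(index=False):
            i, j, d, r, p = (int(row.idx1), int(row.idx2),
                             float(row.distance), int(row.ring),
                             float(row.coupling_probability))
            total_p += p
            if p > p1[i] or (p == p1[i] and p > 0 and np.isnan(d1[i])):
                p1[i] = p
                d1[i] = d
            if p > p2[j] or (p == p2[j] and p > 0 and np.isnan(d2[j])):
                p2[j] = p
                d2[j] = d
            if p > 0:
                ring_sum[r] += p
                ring_cnt[r] += 1
                coupled_distances.append(d)
    with np.errstate(invalid="ignore"):
        ring_mean = np.where(ring_cnt > 0, ring_sum / np.maximum(ring_cnt, 1), 0.0)
    coupled1 = p1 > 0
    coupled2 = p2 > 0
    return SodaSummary(
        n_ch1=n1,
        n_ch2=n2,
        coupled_ids_ch1=ids_ch1[coupled1],
        coupled_ids_ch2=ids_ch2[coupled2],
        uncoupled_ids_ch1=ids_ch1[~coupled1],
        uncoupled_ids_ch2=ids_ch2[~coupled2],
        coupling_index_ch1=float(min(total_p / n1, 1.0)) if n1 else 0.0,
        coupling_index_ch2=float(min(total_p / n2, 1.0)) if n2 else 0.0,
        coupled_fraction_ch1=float(coupled1.mean()) if n1 else 0.0,
        coupled_fraction_ch2=float(coupled2.mean()) if n2 else 0.0,
        mean_probability_ch1=float(p1.mean()) if n1 else 0.0,
        mean_probability_ch2=float(p2.mean()) if n2 else 0.0,
        cluster_probability_ch1=p1,
        cluster_probability_ch2=p2,
        cluster_distance_ch1=d1,
        cluster_distance_ch2=d2,
        ring_mean_probability=ring_mean,
        ring_pair_counts=ring_cnt,
        mean_coupling_distance=float(np.mean(coupled_distances))
        if coupled_distances else float("nan"),
    )


# ---------------------------------------------------------------------------
# end-to-end on point sets
# ---------------------------------------------------------------------------

def analyze_points(
    positions_ch1: np.ndarray,
    positions_ch2: np.ndarray,
    roi_mask: np.ndarray,
    pixel_size: float,
    rings: RingSet | None = None,
    mode: str = "analytic",
    n_reps: int = 100,
    seed: int = 0,
    n_angles: int = 64,
    cap: float = WEIGHT_CAP,
    ring_matrix: str = "identity",
    ids_ch1: np.ndarray | None = None,
    ids_ch2: np.ndarray | None = None,
) -> SodaResult:
    """Full coupling analysis on two centroid sets inside an ROI.

    ``ring_matrix`` selects the ring-coupling matrix ``A``:
    ``'identity'`` (rings treated as disjoint annuli, the default) or
    ``'monte_carlo'`` (estimated from the CSR null samples).
    """
    rings = rings or RingSet()
    p1 = np.atleast_2d(np.asarray(positions_ch1, dtype=float))
    p2 = np.atleast_2d(np.asarray(positions_ch2, dtype=float))
    n1, n2 = len(p1), len(p2)
    roi_area = float(np.count_nonzero(roi_mask)) * pixel_size**2
    pairs = pairwise_candidate_distances(p1, p2, rings)
    if len(pairs):
        w = edge_correction_weights(
            p1[pairs["idx1"].to_numpy()], pairs["distance"].to_numpy(),
            roi_mask, pixel_size, n_angles=n_angles, cap=cap,
        )
    else:
        w = np.empty(0)
    G = compute_G_vector(
        pairs["ring"].to_numpy() if len(pairs) else np.empty(0, dtype=int),
        w, n1, n2, roi_area, rings,
    )
    mu, sigma, samples = null_moments(
        rings, roi_mask, pixel_size, n1, n2, mode=mode, n_reps=n_reps,
        seed=seed, n_angles=n_angles, cap=cap, return_samples=True,
    )
    A = (estimate_ring_coupling_matrix(samples, mu, sigma)
         if ring_matrix == "monte_carlo" else None)
    stats = reduce_and_threshold(G, mu, sigma, A=A)
    pairs = pairs.copy()
    pairs["coupling_probability"] = (
        pair_coupling_probabilities(stats, pairs["ring"].to_numpy())
        if len(pairs) else np.empty(0)
    )
    pairs["weight"] = w
    summary = summarize_coupling(pairs, n1, n2, rings, ids_ch1, ids_ch2)
    return SodaResult(stats=stats, pairs=pairs, summary=summary)
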
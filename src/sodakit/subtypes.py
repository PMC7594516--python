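"""Unsupervised subtype discovery in the 7-D cluster feature space.

Coupled clusters are described by five morphology features plus the
coupling distance and probability, min-max scaled to [0, 1], embedded to
2-D with UMAP, and summarized per condition by the local maxima of a
kernel density estimate.  Maxima prototypes (local average feature
vectors) are grouped by Ward-linkage agglomerative clustering with the
group count selected by silhouette maximization; every cluster is then
assigned to the group of its nearest prototype.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.stats import gaussian_kde
from skimage.feature import peak_local_max
from sklearn.cluster import AgglomerativeClustering
from sklearn.metrics import silhouette_score

from .synthetic import FEATURE_SPACE

__all__ = [
    "FeatureTable",
    "KdeMap",
    "SubtypeModel",
    "build_feature_table",
    "embed_2d",
    "density_map",
    "detect_subtype_maxima",
    "hierarchical_grouping",
    "assign_to_subtypes",
    "cross_dataset_mapping",
    "discover_subtypes",
]

GRID_SIZE = 256
MIN_SEPARATION_PX = 10
MAXIMA_FLOOR_FRACTION = 0.05


@dataclass
class FeatureTable:
    """Min-max scaled 7-D feature table of coupled clusters."""

    scaled: pd.DataFrame
    raw: pd.DataFrame
    condition: pd.Series
    scale_min: pd.Series
    scale_max: pd.Series

    def __len__(self) -> int:
        return len(self.scaled)

    def inverse_transform(self, scaled: pd.DataFrame) -> pd.DataFrame:
        rng = self.scale_max - self.scale_min
        return scaled * rng + self.scale_min


@dataclass
class KdeMap:
    xs: np.ndarray                  # grid x coordinates (embedding units)
    ys: np.ndarray
    grids: dict                     # condition -> (grid_size, grid_size)
    contour_levels: dict            # condition -> 10 uniform levels


@dataclass
class SubtypeModel:
    prototypes: pd.DataFrame        # (m, 7) scaled prototype vectors
    maxima_positions: np.ndarray    # (m, 2) embedding coordinates
    maxima_condition: list
    group_of_maximum: np.ndarray    # (m,) group label per prototype
    k: int
    silhouette: float
    silhouette_by_k: dict
    scale_min: pd.Series
    scale_max: pd.Series


def build_feature_table(features: pd.DataFrame, conditions=None) -> FeatureTable:
    """Join and min-max scale the 7 feature columns over the pooled data.

    ``features`` must contain the columns of ``FEATURE_SPACE`` (coupled
    clusters only); constant columns scale to all-zeros with a warning.
    """
    for col in FEATURE_SPACE:
        if col not in features.columns:
            raise ValueError(f"missing feature column: {col!r}")
    raw = features.loc[:, list(FEATURE_SPACE)].astype(float).reset_index(drop=True)
    if conditions is None:
        conditions = pd.Series(["all"] * len(raw))
    conditions = pd.Series(list(conditions), name="condition")
    lo = raw.min()
    hi = raw.max()
    rng = hi - lo
    zero = rng == 0
    if zero.any():
        warnings.warn(
            f"constant feature column(s) {list(rng.index[zero])}: "
            "scaled to all-zeros", stacklevel=2,
        )
    scaled = (raw - lo) / rng.where(~zero, 1.0)
    scaled[rng.index[zero]] = 0.0
    return FeatureTable(scaled=scaled, raw=raw, condition=conditions,
                        scale_min=lo, scale_max=hi)


def embed_2d(
    table: FeatureTable, n_neighbors: int = 25, min_dist: float = 0.05,
    seed: int = 0,
) -> np.ndarray:
    """UMAP embedding of the scaled feature table; deterministic per seed."""
    if len(table) < n_neighbors + 1:
        raise ValueError(
            f"need at least n_neighbors + 1 = {n_neighbors + 1} rows, "
            f"got {len(table)}"
        )
    import umap  # deferred: heavy numba import

    reducer = umap.UMAP(
        n_components=2, n_neighbors=n_neighbors, min_dist=min_dist,
        random_state=seed,
    )
    return np.asarray(reducer.fit_transform(table.scaled.to_numpy()))


def density_map(
    embeddings: dict, grid_size: int = GRID_SIZE, n_levels: int = 10
) -> KdeMap:
    """Gaussian KDE (Scott's rule) per condition on a shared grid.

    The grid spans the pooled bounding box of all conditions, padded by
    5%, so per-condition maps are directly comparable; contour levels
    are uniform between 0 and each map's maximum.
    """
    all_pts = np.vstack(list(embeddings.values()))
    if len(all_pts) < 10:
        raise ValueError("need at least 10 embedded points")
    lo = all_pts.min(axis=0)
    hi = all_pts.max(axis=0)
    pad = 0.05 * np.where(hi > lo, hi - lo, 1.0)
    xs = np.linspace(lo[0] - pad[0], hi[0] + pad[0], grid_size)
    ys = np.linspace(lo[1] - pad[1], hi[1] + pad[1], grid_size)
    gx, gy = np.meshgrid(xs, ys)
    grids, levels = {}, {}
    for cond, pts in embeddings.items():
        pts = np.asarray(pts, dtype=float)
        try:
            kde = gaussian_kde(pts.T)
        except np.linalg.LinAlgError as exc:
            raise ValueError(
                f"degenerate embedding for condition {cond!r}: {exc}"
            ) from exc
        grid = kde(np.vstack([gx.ravel(), gy.ravel()])).reshape(gx.shape)
        grids[cond] = grid
        levels[cond] = np.linspace(0, grid.max(), n_levels + 1)[1:]
    return KdeMap(xs=xs, ys=ys, grids=grids, contour_levels=levels)


def detect_subtype_maxima(
    kde_map: KdeMap,
    embeddings: dict,
    table: FeatureTable,
    row_indices: dict,
    min_separation: int = MIN_SEPARATION_PX,
    floor_fraction: float = MAXIMA_FLOOR_FRACTION,
):
    """KDE local maxima with prototype feature vectors.

    Maxima below ``floor_fraction`` of the map maximum or closer than
    ``min_separation`` grid pixels are suppressed.  Each maximum's
    prototype is the mean scaled 7-D feature vector of the clusters
    whose embedded points fall within the equivalent radius (nearest
    point if none).  ``row_indices`` maps condition -> row positions of
    its points in ``table``.
    """
    dx = kde_map.xs[1] - kde_map.xs[0]
    dy = kde_map.ys[1] - kde_map.ys[0]
    radius = min_separation * float(np.hypot(dx, dy) / np.sqrt(2))
    positions, prototypes, conditions = [], [], []
    feats = table.scaled.to_numpy()
    for cond, grid in kde_map.grids.items():
        peaks = peak_local_max(
            grid, min_distance=min_separation,
            threshold_abs=floor_fraction * grid.max(),
            exclude_border=False,
        )
        pts = np.asarray(embeddings[cond], dtype=float)
        rows = np.asarray(row_indices[cond], dtype=int)
        for r, c in peaks:
            pos = np.array([kde_map.xs[c], kde_map.ys[r]])
            dist = np.linalg.norm(pts - pos, axis=1)
            near = dist <= radius
            if not near.any():
                near = dist == dist.min()
            positions.append(pos)
            prototypes.append(feats[rows[near]].mean(axis=0))
            conditions.append(cond)
    if not positions:
        raise ValueError("no KDE maxima found")
    proto = pd.DataFrame(prototypes, columns=list(FEATURE_SPACE))
    return np.asarray(positions), proto, conditions


def hierarchical_grouping(
    prototypes: pd.DataFrame,
    k_range=None,
    data: np.ndarray | None = None,
):
    """Ward-linkage grouping of prototypes with silhouette-selected k.

    When ``data`` (the scaled per-cluster feature matrix) is provided,
    the silhouette of each candidate k is computed on the full dataset
    labeled via nearest prototype, which also allows ``k`` up to the
    prototype count; otherwise it is computed on the prototype vectors
    (k limited to m - 1).  Ties break toward smaller k.  Fewer than 3
    prototypes yield the trivial single group with a warning.
    """
    proto = np.asarray(prototypes, dtype=float)
    m = len(proto)
    if m < 3:
        warnings.warn("fewer than 3 prototypes: returning a single group",
                      stacklevel=2)
        return np.zeros(m, dtype=int), 1, float("nan"), {}
    if np.allclose(proto, proto[0]):
        warnings.warn("all prototypes identical: silhouette undefined, k=1",
                      stacklevel=2)
        return np.zeros(m, dtype=int), 1, float("nan"), {}
    k_max = m if data is not None else m - 1
    if k_range is None:
        k_range = range(2, k_max + 1)
    scores: dict[int, float] = {}
    labelings: dict[int, np.ndarray] = {}
    for k in k_range:
        if k < 2 or k > m:
            continue
        labels = AgglomerativeClustering(
            n_clusters=k, linkage="ward", metric="euclidean"
        ).fit_predict(proto)
        labelings[k] = labels
        if data is not None:
            nearest = cdist(data, proto).argmin(axis=1)
            data_labels = labels[nearest]
            if len(np.unique(data_labels)) < 2:
                continue
            scores[k] = float(silhouette_score(data, data_labels))
        else:
            if k > m - 1:
                continue
            scores[k] = float(silhouette_score(proto, labels))
    if not scores:
        warnings.warn("no valid candidate k: returning a single group",
                      stacklevel=2)
        return np.zeros(m, dtype=int), 1, float("nan"), {}
    best_k = min(scores, key=lambda k: (-scores[k], k))
    return labelings[best_k], best_k, scores[best_k], scores


def assign_to_subtypes(
    scaled_features, prototypes, group_of_maximum
) -> np.ndarray:
    """Group of the nearest prototype (Euclidean, scaled space) per row."""
    data = np.asarray(scaled_features, dtype=float)
    proto = np.asarray(prototypes, dtype=float)
    nearest = cdist(data, proto).argmin(axis=1)
    return np.asarray(group_of_maximum)[nearest]


def discover_subtypes(
    table: FeatureTable,
    n_neighbors: int = 25,
    min_dist: float = 0.05,
    seed: int = 0,
    grid_size: int = GRID_SIZE,
    min_separation: int = MIN_SEPARATION_PX,
    k_range=None,
) -> tuple[SubtypeModel, np.ndarray, KdeMap, np.ndarray]:
    """Full chain: embed -> per-condition KDE -> maxima -> grouping.

    Maxima are detected per condition; prototype grouping and silhouette
    selection are pooled.  Returns the model, the embedding, the KDE map
    and the per-row group assignment.
    """
    embedding = embed_2d(table, n_neighbors=n_neighbors, min_dist=min_dist,
                         seed=seed)
    conds = table.condition.to_numpy()
    embeddings = {c: embedding[conds == c] for c in pd.unique(conds)}
    row_indices = {c: np.flatnonzero(conds == c) for c in pd.unique(conds)}
    kde_map = density_map(embeddings, grid_size=grid_size)
    positions, prototypes, proto_conds = detect_subtype_maxima(
        kde_map, embeddings, table, row_indices,
        min_separation=min_separation,
    )
    labels, k, sil, by_k = hierarchical_grouping(
        prototypes, k_range=k_range, data=table.scaled.to_numpy()
    )
    model = SubtypeModel(
        prototypes=prototypes,
        maxima_positions=positions,
        maxima_condition=proto_conds,
        group_of_maximum=labels,
        k=k,
        silhouette=sil,
        silhouette_by_k=by_k,
        scale_min=table.scale_min,
        scale_max=table.scale_max,
    )
    assignment = assign_to_subtypes(
        table.scaled.to_numpy(), prototypes.to_numpy(), labels
    )
    return model, embedding, kde_map, assignment


def cross_dataset_mapping(
    table_a: FeatureTable, model_a: SubtypeModel,
    table_b: FeatureTable, model_b: SubtypeModel,
    link_threshold: float = 0.4,
):
    """Project each dataset onto the other's prototypes.

    ``M_ab[g_a, g_b]`` is the fraction of dataset-A clusters of subtype
    ``g_a`` whose nearest dataset-B prototype belongs to subtype
    ``g_b``; rows sum to 1.  Each dataset keeps its own min-max scaling.
    Links with fraction > ``link_threshold`` are flagged as major
    connections.
    """
    for t in (table_a, table_b):
        if list(t.scaled.columns) != list(FEATURE_SPACE):
            raise ValueError("feature definitions of both tables must match")

    def proportion_matrix(table, own_model, other_model):
        data = table.scaled.to_numpy()
        own = assign_to_subtypes(
            data, own_model.prototypes.to_numpy(), own_model.group_of_maximum
        )
        mapped = assign_to_subtypes(
            data, other_model.prototypes.to_numpy(),
            other_model.group_of_maximum,
        )
        own_groups = np.unique(own_model.group_of_maximum)
        other_groups = np.unique(other_model.group_of_maximum)
        mat = pd.DataFrame(0.0, index=own_groups, columns=other_groups)
        for g in own_groups:
            sel = own == g
            if sel.sum() == 0:
                mat.loc[g] = np.nan
                continue
            for h in other_groups:
                mat.loc[g, h] = np.mean(mapped[sel] == h)
        return mat

    m_ab = proportion_matrix(table_a, model_a, model_b)
    m_ba = proportion_matrix(table_b, model_b, model_a)
    links = []
    for name, mat in (("A->B", m_ab), ("B->A", m_ba)):
        for g in mat.index:
            for h in mat.columns:
                frac = mat.loc[g, h]
                if np.isfinite(frac) and frac > link_threshold:
                    links.append({"direction": name, "source_group": int(g),
                                  "target_group": int(h),
                                  "fraction": float(frac)})
    return m_ab, m_ba, links
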
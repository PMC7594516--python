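"""Randomization tests and binned distributions for population comparisons.

Monte-Carlo p-values use the +1 correction,
``p = (#{D_rand >= D_gt} + 1) / (n_reps + 1)``, so they are never
exactly zero and the tests are exact at any replicate count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "BinnedDistribution",
    "permutation_mean_test",
    "permutation_F_test",
    "chi_square_subtypes",
    "build_distribution",
    "per_bin_permutation_test",
]

ALPHA = 0.05


@dataclass
class BinnedDistribution:
    bin_edges: np.ndarray
    mean: np.ndarray          # per-bin mean across units
    sem: np.ndarray           # per-bin standard error across units
    per_unit: np.ndarray      # (n_units, n_bins)
    cumulative: bool


def _check_group(values, name):
    v = np.asarray(values, dtype=float).ravel()
    if len(v) < 2:
        raise ValueError(f"group {name} needs at least 2 values")
    return v


def permutation_mean_test(
    a, b, n_reps: int = 10000, seed: int = 0
) -> float:
    """Two-sided randomization test on |mean(A) - mean(B)|.

    Group labels are shuffled ``n_reps`` times preserving group sizes.
    """
    a = _check_group(a, "A")
    b = _check_group(b, "B")
    rng = np.random.default_rng(seed)
    pooled = np.concatenate([a, b])
    n, na = len(pooled), len(a)
    d_gt = abs(a.mean() - b.mean())
    total = pooled.sum()
    # vectorized label shuffles: each row is one permutation
    idx = np.argsort(rng.random((n_reps, n)), axis=1)[:, :na]
    sum_a = pooled[idx].sum(axis=1)
    mean_a = sum_a / na
    mean_b = (total - sum_a) / (n - na)
    d_rand = np.abs(mean_a - mean_b)
    return float((np.count_nonzero(d_rand >= d_gt) + 1) / (n_reps + 1))


def _f_statistic(pooled, starts, sizes):
    """One-way F for groups laid out contiguously in ``pooled`` rows."""
    n = pooled.shape[-1]
    k = len(sizes)
    grand = pooled.mean(axis=-1)
    ssb = np.zeros(pooled.shape[:-1])
    ssw = np.zeros(pooled.shape[:-1])
    for s, size in zip(starts, sizes):
        block = pooled[..., s:s + size]
        m = block.mean(axis=-1)
        ssb += size * (m - grand) ** 2
        ssw += ((block - m[..., None]) ** 2).sum(axis=-1)
    return (ssb / (k - 1)) / (ssw / (n - k))


def permutation_F_test(
    groups, n_reps: int = 10000, seed: int = 0, post_hoc: bool = True
) -> dict:
    """Randomization test on the one-way F-statistic for >= 3 groups.

    Returns ``{"p_value", "F", "post_hoc"}``; pairwise randomization
    mean tests are run only when the global null is rejected at 0.05.
    """
    if len(groups) < 3:
        raise ValueError("permutation_F_test requires at least 3 groups")
    arrays = [_check_group(g, i) for i, g in enumerate(groups)]
    rng = np.random.default_rng(seed)
    pooled = np.concatenate(arrays)
    sizes = [len(g) for g in arrays]
    starts = np.concatenate([[0], np.cumsum(sizes)[:-1]])
    f_gt = _f_statistic(pooled[None, :], starts, sizes)[0]
    idx = np.argsort(rng.random((n_reps, len(pooled))), axis=1)
    f_rand = _f_statistic(pooled[idx], starts, sizes)
    p = float((np.count_nonzero(f_rand >= f_gt) + 1) / (n_reps + 1))
    result = {"p_value": p, "F": float(f_gt), "post_hoc": {}}
    if post_hoc and p < ALPHA:
        for i in range(len(arrays)):
            for j in range(i + 1, len(arrays)):
                result["post_hoc"][(i, j)] = permutation_mean_test(
                    arrays[i], arrays[j], n_reps=n_reps,
                    seed=seed + 1 + i * len(arrays) + j,
                )
    return result


def chi_square_subtypes(counts) -> dict:
    """Global chi-square on a subtype x condition table plus post-hoc
    2x2 tests (each subtype vs all others pooled).

    Returns global p and per-subtype raw p-values with Bonferroni flags.
    """
    table = np.asarray(counts, dtype=float)
    names = list(counts.index) if isinstance(counts, pd.DataFrame) \
        else list(range(table.shape[0]))
    if np.any(table < 0):
        raise ValueError("counts must be non-negative")
    chi2, p, dof, expected = sps.chi2_contingency(table)
    if np.any(expected < 5):
        warnings.warn("some expected counts are below 5", stacklevel=2)
    post_hoc = {}
    m = table.shape[0]
    for i, name in enumerate(names):
        sub = np.vstack([table[i], table.sum(axis=0) - table[i]])
        if m == 1:
            post_hoc[name] = {"p_value": float("nan"), "bonferroni_significant": False}
            continue
        _, p_i, _, _ = sps.chi2_contingency(sub)
        post_hoc[name] = {
            "p_value": float(p_i),
            "bonferroni_significant": bool(p_i < ALPHA / m),
        }
    return {"chi2": float(chi2), "p_value": float(p), "dof": int(dof),
            "post_hoc": post_hoc}


def build_distribution(
    values_per_unit, bin_edges=None, bin_width: float | None = None,
    cumulative: bool = False,
) -> BinnedDistribution:
    """Per-bin mean with standard error across units (neurons/images).

    Histogram mode bins each unit's values and normalizes to a
    fraction; cumulative mode uses the running sum, normalized to 1 at
    the last bin.
    """
    units = [np.asarray(u, dtype=float).ravel() for u in values_per_unit]
    if not units:
        raise ValueError("need at least one unit")
    if bin_edges is None:
        if bin_width is None or bin_width <= 0:
            raise ValueError("bin_width must be > 0")
        top = max((u.max() for u in units if len(u)), default=bin_width)
        n_bins = max(int(np.ceil(top / bin_width)), 1)
        bin_edges = np.arange(n_bins + 1) * bin_width
    bin_edges = np.asarray(bin_edges, dtype=float)
    per_unit = []
    for u in units:
        h, _ = np.histogram(u, bins=bin_edges)
        h = h.astype(float)
        total = h.sum()
        if cumulative:
            c = np.cumsum(h)
            per_unit.append(c / c[-1] if c[-1] > 0 else c)
        else:
            per_unit.append(h / total if total > 0 else h)
    per_unit = np.vstack(per_unit)
    mean = per_unit.mean(axis=0)
    sem = (per_unit.std(axis=0, ddof=1) / np.sqrt(len(units))
           if len(units) > 1 else np.zeros(per_unit.shape[1]))
    return BinnedDistribution(bin_edges=bin_edges, mean=mean, sem=sem,
                              per_unit=per_unit, cumulative=cumulative)


def per_bin_permutation_test(
    units_a, units_b, bin_edges, cumulative: bool = False,
    n_reps: int = 10000, seed: int = 0, null: str = "global",
) -> np.ndarray:
    """Per-bin randomization p-values between two binned distributions.

    Units (per-neuron value lists) are permuted between conditions; the
    per-bin statistic is |mean_A - mean_B| of the binned curves.  With
    ``null='global'`` one set of label shuffles serves every bin; with
    ``null='per_bin'`` each bin is re-randomized independently.
    """
    if null not in ("global", "per_bin"):
        raise ValueError("null must be 'global' or 'per_bin'")
    bin_edges = np.asarray(bin_edges, dtype=float)
    da = build_distribution(units_a, bin_edges=bin_edges, cumulative=cumulative)
    db = build_distribution(units_b, bin_edges=bin_edges, cumulative=cumulative)
    curves = np.vstack([da.per_unit, db.per_unit])
    na = len(da.per_unit)
    n = len(curves)
    d_gt = np.abs(da.mean - db.mean)
    rng = np.random.default_rng(seed)
    n_bins = curves.shape[1]
    counts = np.zeros(n_bins)
    for rep in range(n_reps):
        if null == "global":
            perm = rng.permutation(n)
            d = np.abs(curves[perm[:na]].mean(axis=0)
                       - curves[perm[na:]].mean(axis=0))
            counts += d >= d_gt
        else:
            for b in range(n_bins):
                perm = rng.permutation(n)
                d = abs(curves[perm[:na], b].mean()
                        - curves[perm[na:], b].mean())
                counts[b] += d >= d_gt[b]
    return (counts + 1) / (n_reps + 1)
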
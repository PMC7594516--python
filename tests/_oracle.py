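"""Independent brute-force reference implementation of the coupling analysis.

Deliberately naive: exhaustive O(n1*n2) pair enumeration, cumulative
K(r) accumulation (instead of per-ring bincounts), per-pair python-loop
edge weights, and scalar ring scans for the coupling probability.  Used
only to validate the optimized implementation.
"""

import math

import numpy as np

WEIGHT_CAP = 8.0


def brute_weight(center, distance, mask, pixel_size, n_angles):
    """Fraction-of-circle-inside-ROI weight, python loop over angles."""
    h, w = mask.shape
    inside = 0
    for j in range(n_angles):
        theta = 2.0 * math.pi * j / n_angles
        x = center[0] + distance * math.cos(theta)
        y = center[1] + distance * math.sin(theta)
        col = int(round(x / pixel_size))
        row = int(round(y / pixel_size))
        if 0 <= row < h and 0 <= col < w and mask[row, col]:
            inside += 1
    frac = inside / n_angles
    if frac == 0:
        raise ValueError("circle entirely outside ROI")
    return min(1.0 / frac, WEIGHT_CAP)


def brute_force_soda(
    positions_ch1,
    positions_ch2,
    mask,
    pixel_size,
    mu,
    sigma,
    n_rings=16,
    ring_width=15.0,
    n_angles=64,
):
    """Full brute-force analysis given null moments.

    Returns (pairs, G, G0, threshold) where pairs is a list of dicts
    with keys idx1, idx2, distance, ring, weight, probability.
    """
    p1 = np.asarray(positions_ch1, dtype=float)
    p2 = np.asarray(positions_ch2, dtype=float)
    n1, n2 = len(p1), len(p2)
    radii = [i * ring_width for i in range(n_rings + 1)]
    r_max = radii[-1]
    area = float(np.count_nonzero(mask)) * pixel_size**2

    pairs = []
    K = [0.0] * (n_rings + 1)  # cumulative weighted counts at each radius
    for i in range(n1):
        for j in range(n2):
            d = math.hypot(p1[i, 0] - p2[j, 0], p1[i, 1] - p2[j, 1])
            if d <= 0 or d > r_max:
                continue
            ring = None
            for r in range(n_rings):
                if radii[r] < d <= radii[r + 1]:
                    ring = r
                    break
            w = brute_weight(p1[i], d, mask, pixel_size, n_angles)
            for r in range(n_rings + 1):
                if d <= radii[r]:
                    K[r] += w
            pairs.append({"idx1": i, "idx2": j, "distance": d,
                          "ring": ring, "weight": w})

    scale = area / (n1 * n2)
    G = [scale * (K[r + 1] - K[r]) for r in range(n_rings)]
    threshold = 2.0 * math.log(n_rings)
    G0 = []
    for r in range(n_rings):
        z = (G[r] - mu[r]) / sigma[r]
        G0.append(z if z > threshold else 0.0)
    for pair in pairs:
        r = pair["ring"]
        if G0[r] > 0 and G[r] > 0:
            pair["probability"] = min(max(sigma[r] * G0[r] / G[r], 0.0), 1.0)
        else:
            pair["probability"] = 0.0
    return pairs, np.array(G), np.array(G0), threshold
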
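"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's recursive/vectorized code paths:
the likelihood oracle enumerates latent origination/extinction occasions
explicitly, and the distance oracle is a from-scratch pairwise haversine.
"""

from __future__ import annotations

import math

import numpy as np


def unrolled_pradel_loglik(
    phi: np.ndarray, gamma: np.ndarray, p: np.ndarray, w: np.ndarray
) -> float:
    """Log-probability of one capture history by explicit enumeration.

    Sums over every latent (origination occasion a, extinction occasion b)
    pair with a <= f and b >= l: the seniority-weighted entry path, the
    survival-weighted exit path, and the Bernoulli detection outcomes at
    every occasion the genus was extant.  ``phi`` has length T-1 (interval
    t -> t+1 at index t), ``gamma`` length T-1 (seniority of occasion t at
    index t-1), ``p`` length T.
    """
    w = np.asarray(w)
    T = len(w)
    det_idx = np.flatnonzero(w)
    f, l = det_idx[0], det_idx[-1]

    def entry_weight(a: int) -> float:
        # probability (under the seniority chain) that the genus entered
        # exactly at occasion a, given presence at f
        out = 1.0
        for t in range(a + 1, f + 1):
            out *= gamma[t - 1]
        if a > 0:
            out *= 1.0 - gamma[a - 1]
        return out

    def exit_weight(b: int) -> float:
        out = 1.0
        for t in range(l, b):
            out *= phi[t]
        if b < T - 1:
            out *= 1.0 - phi[b]
        return out

    span = 1.0  # survival across the observed span f..l
    for t in range(f, l):
        span *= phi[t]

    total = 0.0
    for a in range(0, f + 1):
        for b in range(l, T):
            det = 1.0
            for t in range(a, b + 1):
                det *= p[t] if w[t] else 1.0 - p[t]
            total += entry_weight(a) * span * exit_weight(b) * det
    return math.log(total)


def brute_force_max_gcd_km(points: np.ndarray, radius: float = 6371.0) -> float:
    """Max pairwise great-circle distance by explicit double loop."""
    best = 0.0
    pts = np.asarray(points, dtype=float)
    for i in range(len(pts)):
        for j in range(i + 1, len(pts)):
            lng1, lat1 = map(math.radians, pts[i])
            lng2, lat2 = map(math.radians, pts[j])
            a = (
                math.sin((lat2 - lat1) / 2) ** 2
                + math.cos(lat1)
                * math.cos(lat2)
                * math.sin((lng2 - lng1) / 2) ** 2
            )
            best = max(best, 2 * radius * math.asin(math.sqrt(min(a, 1.0))))
    return best


def all_histories(T: int):
    """Every nonzero 0/1 detection vector of length T."""
    for code in range(1, 2**T):
        yield np.array([(code >> t) & 1 for t in range(T)], dtype=np.int8)
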
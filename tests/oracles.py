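"""Independent brute-force oracles used by the tests.

These deliberately avoid the library code paths they check: the DCT oracle is
the O(N^4) double sum straight from the DCT-II definition, and the threshold
oracle is an exhaustive sweep.
"""

from __future__ import annotations

import numpy as np


def naive_dct2_ortho(x: np.ndarray) -> np.ndarray:
    """Orthonormal 2-D DCT-II by the direct O(N^4) double sum."""
    x = np.asarray(x, dtype=np.float64)
    n1, n2 = x.shape
    out = np.zeros((n1, n2))
    for k1 in range(n1):
        a1 = np.sqrt(1.0 / n1) if k1 == 0 else np.sqrt(2.0 / n1)
        for k2 in range(n2):
            a2 = np.sqrt(1.0 / n2) if k2 == 0 else np.sqrt(2.0 / n2)
            acc = 0.0
            for m in range(n1):
                for n in range(n2):
                    acc += (
                        x[m, n]
                        * np.cos(np.pi * (2 * m + 1) * k1 / (2 * n1))
                        * np.cos(np.pi * (2 * n + 1) * k2 / (2 * n2))
                    )
            out[k1, k2] = a1 * a2 * acc
    return out


def naive_nonzero_fraction(x: np.ndarray, magnitude_threshold: float) -> float:
    """Non-zero fraction after zeroing small coefficients, via the naive DCT."""
    coeffs = naive_dct2_ortho(x)
    return int(np.sum(np.abs(coeffs) >= magnitude_threshold)) / coeffs.size


def sweep_best_threshold(fractions, labels) -> tuple[float, float]:
    """Exhaustive candidate sweep for the F-maximizing decision threshold.

    Candidates are 0, 1 and midpoints of consecutive distinct fractions;
    positive class is non_informative (fraction below threshold); ties go to
    the larger threshold.  Returns (threshold, f_measure).
    """
    fractions = np.asarray(fractions, dtype=float)
    positive = np.array([lab == "non_informative" for lab in labels])
    distinct = np.unique(fractions)
    candidates = [0.0] + [
        (a + b) / 2 for a, b in zip(distinct[:-1], distinct[1:])
    ] + [1.0]
    best_t, best_f = 0.0, -1.0
    for t in candidates:
        pred = fractions < t
        tp = int(np.sum(pred & positive))
        fp = int(np.sum(pred & ~positive))
        fn = int(np.sum(~pred & positive))
        if tp + fp == 0 or tp + fn == 0:
            f = 0.0
        else:
            p, r = tp / (tp + fp), tp / (tp + fn)
            f = 0.0 if p + r == 0 else 2 * p * r / (p + r)
        if f >= best_f:
            best_t, best_f = t, f
    return best_t, best_f


def count_disk_pixels(shape: tuple[int, int], disks) -> np.ndarray:
    """Rasterize (row, col, radius) disks into a boolean mask by pixel test."""
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    mask = np.zeros(shape, dtype=bool)
    for cy, cx, r in disks:
        mask |= np.hypot(yy - cy, xx - cx) <= r
    return mask
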
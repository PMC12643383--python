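"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the library routines the package itself uses:
component counting is an explicit flood fill, box counting slices out every
grid box and tests occupancy directly, and Otsu's threshold is an
exhaustive search over all histogram-bin candidates.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def flood_fill_count(mask: np.ndarray) -> int:
    """Count connected components by explicit stack-based flood fill.

    Uses full connectivity (8 in 2D, 26 in 3D), matching the mask
    convention under test.
    """
    mask = np.asarray(mask, dtype=bool)
    visited = np.zeros(mask.shape, dtype=bool)
    offsets = [d for d in itertools.product((-1, 0, 1), repeat=mask.ndim)
               if any(d)]
    count = 0
    for start in zip(*np.nonzero(mask)):
        if visited[start]:
            continue
        count += 1
        stack = [start]
        visited[start] = True
        while stack:
            pos = stack.pop()
            for off in offsets:
                nb = tuple(p + o for p, o in zip(pos, off))
                if all(0 <= n < s for n, s in zip(nb, mask.shape)) \
                        and mask[nb] and not visited[nb]:
                    visited[nb] = True
                    stack.append(nb)
    return count


def exhaustive_box_counts(mask: np.ndarray, sizes, n_offsets: int) -> list[int]:
    """Minimum box counts over offsets, by slicing out every grid box."""
    mask = np.asarray(mask, dtype=bool)
    shape = mask.shape
    counts = []
    for size in sizes:
        best = None
        for k in range(n_offsets):
            off = (k * size) // n_offsets
            n = 0
            ranges = [range(-off, s, size) for s in shape]
            for corner in itertools.product(*ranges):
                sl = tuple(slice(max(c, 0), c + size) for c in corner)
                if mask[sl].any():
                    n += 1
            best = n if best is None else min(best, n)
        counts.append(best)
    return counts


def exhaustive_fd(mask: np.ndarray, n_scales: int = 20, n_offsets: int = 5) -> float:
    """Fractal dimension from exhaustive box counts + least-squares fit."""
    max_box = 2 ** int(math.floor(math.log2(min(mask.shape))))
    sizes = np.unique(np.rint(np.geomspace(2, max_box, n_scales)).astype(int))[::-1]
    counts = exhaustive_box_counts(mask, sizes, n_offsets)
    slope = np.polyfit(np.log(sizes), np.log(counts), 1)[0]
    return float(-slope)


def exhaustive_otsu(image: np.ndarray) -> float:
    """Otsu threshold by exhaustive search over 256 histogram-bin candidates.

    Maximizes the between-class variance w0*w1*(mu0-mu1)^2 over every
    possible split of a 256-bin histogram of the image's value range.
    """
    image = np.asarray(image, dtype=float).ravel()
    hist, edges = np.histogram(image, bins=256)
    centers = (edges[:-1] + edges[1:]) / 2
    total = hist.sum()
    best_t, best_var = centers[0], -1.0
    for i in range(1, 256):
        w0 = hist[:i].sum()
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (hist[:i] * centers[:i]).sum() / w0
        mu1 = (hist[i:] * centers[i:]).sum() / w1
        var = w0 * w1 * (mu0 - mu1) ** 2
        if var > best_var:
            best_var, best_t = var, centers[i - 1]
    return float(best_t)
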
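"""Independent brute-force oracles used to check the fast implementations."""

from __future__ import annotations

from typing import List, Tuple

import numpy as np


def circular_peaks_oracle(z, min_prominence: float) -> List[Tuple[int, float, float]]:
    """Peaks of a periodic signal by exhaustive circular walks.

    Treats ``z`` as one period of a cyclic signal. A peak is a sample (or
    plateau, reported at its floored midpoint) strictly above its circular
    neighbors. Prominence follows the topographic definition: walk in both
    directions until a strictly higher sample; the prominence is the
    height minus the higher of the two path minima, and a peak at the
    global maximum height drops to the global minimum. Returns
    ``(index, height, prominence)`` for peaks with prominence strictly
    above ``min_prominence``.
    """
    z = [float(v) for v in z]
    n = len(z)
    gmax, gmin = max(z), min(z)
    candidates = []
    for i in range(n):
        if z[i] <= z[(i - 1) % n]:
            continue
        j = i  # plateau right edge (may wrap)
        while z[(j + 1) % n] == z[i] and j - i < n:
            j += 1
        if j - i >= n:
            return []  # constant signal
        if z[(j + 1) % n] < z[i]:
            candidates.append(((i + j) // 2 % n, z[i]))

    def path_min(p: int, h: float, step: int) -> float:
        m, k = h, p
        while True:
            k = (k + step) % n
            if z[k] > h:
                return m
            m = min(m, z[k])

    out = []
    for p, h in candidates:
        if h == gmax:
            prom = h - gmin
        else:
            prom = h - max(path_min(p, h, -1), path_min(p, h, 1))
        if prom > min_prominence:
            out.append((p, h, prom))
    return sorted(out)


def all_grid_signals(length: int, values) -> np.ndarray:
    """Every signal of the given length over a small value grid."""
    grids = np.meshgrid(*([np.asarray(values)] * length), indexing="ij")
    return np.stack([g.ravel() for g in grids], axis=1)
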
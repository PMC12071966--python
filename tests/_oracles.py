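"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths they check: least squares via
explicit normal equations, and the minimum enclosing circle via exhaustive
search over all 2- and 3-point support sets.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def normal_equations_fit(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Solve OLS by explicitly forming and solving X'X b = X'y."""
    return np.linalg.solve(X.T @ X, X.T @ y)


def brute_force_mec(points) -> tuple[tuple[float, float], float]:
    """Exhaustive minimum enclosing circle: try every pair-diameter and
    triple-circumcircle candidate, keep the smallest that contains all."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    n = len(pts)
    if n == 1:
        return (float(pts[0, 0]), float(pts[0, 1])), 0.0
    best = None
    candidates = []
    for i, j in itertools.combinations(range(n), 2):
        c = (pts[i] + pts[j]) / 2
        candidates.append((c, float(np.linalg.norm(pts[i] - c))))
    for i, j, k in itertools.combinations(range(n), 3):
        a, b, cpt = pts[i], pts[j], pts[k]
        bx, by = b - a
        cx, cy = cpt - a
        d = 2 * (bx * cy - by * cx)
        if d == 0:
            continue
        ux = (cy * (bx * bx + by * by) - by * (cx * cx + cy * cy)) / d
        uy = (bx * (cx * cx + cy * cy) - cx * (bx * bx + by * by)) / d
        center = a + np.array([ux, uy])
        candidates.append((center, math.hypot(ux, uy)))
    for center, radius in candidates:
        if np.all(np.linalg.norm(pts - center, axis=1) <= radius + 1e-9):
            if best is None or radius < best[1]:
                best = ((float(center[0]), float(center[1])), float(radius))
    return best
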
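"""Small planar-geometry helpers shared by scene construction, zone
measurement and radial-cut selection.  All coordinates in µm."""

from __future__ import annotations

import numpy as np


def segment_distance(
    x: np.ndarray, y: np.ndarray, p0: tuple[float, float], p1: tuple[float, float]
) -> np.ndarray:
    """Euclidean distance from points (x, y) to the segment p0–p1."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    dx, dy = p1[0] - p0[0], p1[1] - p0[1]
    seg2 = dx * dx + dy * dy
    if seg2 == 0.0:
        return np.hypot(x - p0[0], y - p0[1])
    t = ((x - p0[0]) * dx + (y - p0[1]) * dy) / seg2
    t = np.clip(t, 0.0, 1.0)
    return np.hypot(x - (p0[0] + t * dx), y - (p0[1] + t * dy))


def principal_axis(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Centroid and unit direction of the first principal component of an
    (n, 2) point set.  Direction sign is fixed to point toward positive x
    (toward positive y on ties) for determinism."""
    points = np.asarray(points, dtype=float)
    center = points.mean(axis=0)
    centered = points - center
    cov = centered.T @ centered
    eigvals, eigvecs = np.linalg.eigh(cov)
    direction = eigvecs[:, int(np.argmax(eigvals))]
    if direction[0] < 0 or (direction[0] == 0 and direction[1] < 0):
        direction = -direction
    return center, direction
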
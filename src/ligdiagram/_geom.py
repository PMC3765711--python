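"""Small 2D/3D geometry helpers shared by layout and scene placement."""

from __future__ import annotations

import numpy as np


def rotate2d(v: np.ndarray, degrees: float) -> np.ndarray:
    t = np.radians(degrees)
    c, s = np.cos(t), np.sin(t)
    return np.array([c * v[0] - s * v[1], s * v[0] + c * v[1]])


def unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-12:
        return np.array([1.0, 0.0])
    return v / n


def angle_deg(a: np.ndarray, vertex: np.ndarray, b: np.ndarray) -> float:
    """Angle a-vertex-b in degrees (works in 2D and 3D)."""
    v1, v2 = a - vertex, b - vertex
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def reflect_point(p: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Reflect 2D point ``p`` across the line through ``a`` and ``b``."""
    d = unit(b - a)
    w = p - a
    return a + 2.0 * np.dot(w, d) * d - w


def segments_cross(p1: np.ndarray, p2: np.ndarray,
                   q1: np.ndarray, q2: np.ndarray,
                   eps: float = 1e-9) -> bool:
    """Proper intersection of open segments; touching at a shared endpoint
    does not count."""
    for a, b in ((p1, q1), (p1, q2), (p2, q1), (p2, q2)):
        if np.linalg.norm(a - b) < eps:
            return False

    def orient(a, b, c):
        v = (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])
        return 0 if abs(v) < eps else (1 if v > 0 else -1)

    o1, o2 = orient(p1, p2, q1), orient(p1, p2, q2)
    o3, o4 = orient(q1, q2, p1), orient(q1, q2, p2)
    if o1 != o2 and o3 != o4 and 0 not in (o1, o2, o3, o4):
        return True
    return False


def best_fit_plane_projection(coords: np.ndarray) -> np.ndarray:
    """Orthographic projection of Nx3 coordinates onto their least-squares
    plane; returns Nx2 coordinates in that plane (centred)."""
    center = coords.mean(axis=0)
    x = coords - center
    # right singular vectors: rows of vt; first two span the plane
    _, _, vt = np.linalg.svd(x, full_matrices=False)
    return x @ vt[:2].T


def largest_gap_directions(existing: list[np.ndarray], k: int) -> list[np.ndarray]:
    """``k`` unit directions evenly spread inside the largest angular gap
    between ``existing`` unit directions (all around origin)."""
    if not existing:
        return [rotate2d(np.array([1.0, 0.0]), 360.0 * i / max(k, 1))
                for i in range(k)]
    angles = sorted(float(np.degrees(np.arctan2(v[1], v[0]))) % 360.0
                    for v in existing)
    gaps = []
    for i, a in enumerate(angles):
        nxt = angles[(i + 1) % len(angles)]
        width = (nxt - a) % 360.0
        if len(angles) == 1:
            width = 360.0
        gaps.append((width, a))
    width, start = max(gaps)
    out = []
    for i in range(k):
        theta = start + width * (i + 1) / (k + 1)
        out.append(rotate2d(np.array([1.0, 0.0]), theta))
    return out
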
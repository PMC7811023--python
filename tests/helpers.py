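"""Shared geometry helpers for the test suite."""

import numpy as np
from scipy.spatial import cKDTree

from polarwrithe import DiscreteCurve


def rot_z(angle: float) -> np.ndarray:
    c, s = np.cos(angle), np.sin(angle)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def rot_x(angle: float) -> np.ndarray:
    c, s = np.cos(angle), np.sin(angle)
    return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])


def random_rotation(rng) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def trefoil(n: int = 2000) -> DiscreteCurve:
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    pts = np.column_stack([
        (2 + np.cos(3 * t)) * np.cos(2 * t),
        (2 + np.cos(3 * t)) * np.sin(2 * t),
        np.sin(3 * t),
    ])
    return DiscreteCurve(pts, closed=True, label="trefoil")


def random_closed_curve(rng, n: int = 1500, order: int = 4) -> DiscreteCurve:
    """Random embedded smooth closed curve (trigonometric polynomial),
    rejection-sampled to be well separated from self-contact and to have a
    usable vertical extent."""
    while True:
        t = np.linspace(0, 2 * np.pi, n, endpoint=False)
        pts = np.zeros((n, 3))
        for k in range(1, order + 1):
            for d in range(3):
                a, b = rng.normal(0, 1.0 / k, 2)
                pts[:, d] += a * np.cos(k * t) + b * np.sin(k * t)
        ext = np.linalg.norm(pts.max(0) - pts.min(0))
        if (pts[:, 2].max() - pts[:, 2].min()) < 0.15 * ext:
            continue
        pairs = cKDTree(pts).query_pairs(0.05 * ext, output_type="ndarray")
        if len(pairs):
            sep = np.abs(pairs[:, 0] - pairs[:, 1])
            sep = np.minimum(sep, n - sep)
            if np.any(sep > n // 20):
                continue
        return DiscreteCurve(pts, closed=True, label="random-closed")
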
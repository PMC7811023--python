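"""Closed-ribbon (Gauss double integral) writhe.

Wr = (1/4pi) * double integral of T(s) x T(t) . (x(s)-x(t)) / |x(s)-x(t)|^3,
evaluated exactly for a polyline as the sum of signed solid angles
(spherical quadrilaterals) over all non-adjacent segment pairs.  Adjacent
segments (sharing a vertex, including the wraparound junction of a closed
curve) contribute exactly zero and are skipped; open curves are evaluated
as-is, with no artificial closure.

Used as the comparison measure and as the closed-curve oracle: for smooth
closed curves the polar writhe and the Gauss writhe agree.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .curves import DiscreteCurve
from .errors import SelfIntersectionError

__all__ = ["GaussResult", "gauss_writhe"]

_CHUNK = 256


@dataclass
class GaussResult:
    wr: float
    n_segment_pairs: int


def _segment_distance(p1, p2, p3, p4) -> float:
    """Minimum distance between segments p1-p2 and p3-p4."""
    d1 = p2 - p1
    d2 = p4 - p3
    r = p1 - p3
    a = d1 @ d1
    e = d2 @ d2
    f = d2 @ r
    c = d1 @ r
    b = d1 @ d2
    denom = a * e - b * b
    s = np.clip((b * f - c * e) / denom, 0.0, 1.0) if denom > 1e-15 else 0.0
    t = (b * s + f) / e if e > 1e-15 else 0.0
    t = np.clip(t, 0.0, 1.0)
    s = np.clip((b * t - c) / a, 0.0, 1.0) if a > 1e-15 else 0.0
    return float(np.linalg.norm(p1 + s * d1 - (p3 + t * d2)))


def gauss_writhe(curve: DiscreteCurve, eps_len: float | None = None) -> GaussResult:
    """Discrete Gauss writhe of a curve (turns).

    The solid angle of each non-adjacent segment pair is computed from the
    four unit normals of the tetrahedron spanned by the segment endpoints;
    the unordered-pair sum is doubled.
    """
    pts = curve.points
    n = pts.shape[0]
    if n < 4:
        raise ValueError("Gauss writhe needs at least 4 points")
    if curve.closed:
        a = pts
        b = np.vstack([pts[1:], pts[:1]])
    else:
        a = pts[:-1]
        b = pts[1:]
    nseg = a.shape[0]
    if eps_len is None:
        eps_len = 1e-9 * max(curve.extent, 1.0)

    total = 0.0
    n_pairs = 0
    for i0 in range(0, nseg, _CHUNK):
        i1 = min(i0 + _CHUNK, nseg)
        for i in range(i0, i1):
            j = np.arange(i + 2, nseg)
            if curve.closed and i == 0 and len(j):
                j = j[j != nseg - 1]  # wraparound-adjacent pair
            if len(j) == 0:
                continue
            p1, p2 = a[i], b[i]
            p3, p4 = a[j], b[j]
            r12 = p2 - p1
            r34 = p4 - p3
            r13 = p3 - p1
            r14 = p4 - p1
            r23 = p3 - p2
            r24 = p4 - p2

            n1 = np.cross(r13, r14)
            n2 = np.cross(r14, r24)
            n3 = np.cross(r24, r23)
            n4 = np.cross(r23, r13)
            norms = [np.linalg.norm(v, axis=1) for v in (n1, n2, n3, n4)]
            ok = np.ones(len(j), dtype=bool)
            for nm in norms:
                ok &= nm > 1e-14
            for v, nm in zip((n1, n2, n3, n4), norms):
                nm_safe = np.where(nm > 1e-14, nm, 1.0)
                v /= nm_safe[:, None]

            def dot(u, v):
                return np.clip(np.sum(u * v, axis=1), -1.0, 1.0)

            omega_star = (np.arcsin(dot(n1, n2)) + np.arcsin(dot(n2, n3))
                          + np.arcsin(dot(n3, n4)) + np.arcsin(dot(n4, n1)))
            vol = np.sum(np.cross(r34, np.broadcast_to(r12, r34.shape))
                         * r13, axis=1)
            # coplanar pairs subtend zero solid angle exactly; zeroing them
            # also suppresses the sqrt(eps) arcsin noise near +-1
            vscale = (np.linalg.norm(r12) * np.linalg.norm(r34, axis=1)
                      * (np.linalg.norm(r13, axis=1) + 1e-300))
            coplanar = np.abs(vol) < 1e-10 * vscale
            sign = np.where(coplanar, 0.0, np.sign(vol))
            omega = np.where(ok, omega_star * sign, 0.0)

            # a (near-)crossing has |omega*| -> 2pi whether or not the pair
            # is coplanar; verify the actual segment distance there
            near = ok & (np.abs(omega_star) > 2.0 * np.pi - 0.2)
            if np.any(near):
                for jj in j[near]:
                    if _segment_distance(p1, p2, a[jj], b[jj]) < eps_len:
                        raise SelfIntersectionError(
                            f"segments {i} and {int(jj)} intersect"
                        )
            total += float(np.sum(omega))
            n_pairs += len(j)
    # unordered pairs doubled; omega is the solid angle, Wr = sum omega/4pi * 2
    return GaussResult(wr=2.0 * total / (4.0 * np.pi), n_segment_pairs=n_pairs)
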
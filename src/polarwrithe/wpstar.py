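"""The extended polar writhe W_p* for open curves.

W_p alone changes *continuously* when an interior section of an open curve
sweeps around the region beyond one of its endpoint planes (the end-angle
drift).  W_p* removes that drift by first extending the curve with straight
vertical segments at both ends, long enough that the whole structure is
bound between the planes of the extended end points; the polar writhe of the
extended curve is then invariant under all deformations that do not carry
the curve across an end line, and jumps by exactly +/-2 when such an
over-the-top passage occurs.  Tracking W_p and W_p* together therefore
distinguishes self-crossings (both jump) from end passages (only W_p*
jumps).

The extensions are exactly vertical, so they contribute no local writhe, and
each continues its endpoint's direction of vertical motion, so no new
turning points are created: the extended curve has the same section count as
the original, with elongated terminal sections.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .curves import DiscreteCurve, compute_tangents, split_sections
from .errors import CurveError
from .polar_writhe import WritheResult, polar_writhe

__all__ = ["ExtendedCurve", "extend_curve", "polar_writhe_star"]

DEFAULT_PADDING = 0.05


@dataclass
class ExtendedCurve:
    """An open curve plus its two vertical end extensions."""

    curve: DiscreteCurve
    original: DiscreteCurve
    original_range: tuple[int, int]
    padding: float


def _extension_points(endpoint: np.ndarray, direction: int, z_target: float,
                      step: float) -> np.ndarray:
    """Vertical run of points from z_target toward (excluding) the endpoint."""
    x0, y0, z0 = endpoint
    length = abs(z0 - z_target)
    k = max(int(np.ceil(length / step)), 2)
    zs = np.linspace(z_target, z0, k + 1)[:-1]
    out = np.column_stack([np.full(k, x0), np.full(k, y0), zs])
    return out


def extend_curve(curve: DiscreteCurve, padding: float = DEFAULT_PADDING,
                 eps_z: float | None = None) -> ExtendedCurve:
    """Append straight vertical extensions to both ends of an open curve.

    Each extension points away from the curve's interior in z — opposite to
    the terminal section's orientation at the start, along it at the end —
    and runs past the curve's global z extreme in that direction by
    ``padding`` times the z extent, sampled at the curve's median edge
    length.  The extended end points then bound the whole structure from
    above/below on their respective sides.
    """
    if curve.closed:
        raise CurveError("end extensions apply to open curves only")
    sections = split_sections(curve, compute_tangents(curve), eps_z=eps_z)
    sigma_first = sections[0].sigma
    sigma_last = sections[-1].sigma

    pts = curve.points
    zmin, zmax = float(pts[:, 2].min()), float(pts[:, 2].max())
    pad = padding * max(zmax - zmin, 1e-12)
    step = float(np.median(np.linalg.norm(np.diff(pts, axis=0), axis=1)))

    def target(direction: int) -> float:
        return zmax + pad if direction > 0 else zmin - pad

    d_start = -sigma_first   # extension continues the motion *into* the start
    d_end = sigma_last       # extension continues the motion *out of* the end

    start_ext = _extension_points(pts[0], d_start, target(d_start), step)
    end_ext = _extension_points(pts[-1], d_end, target(d_end), step)[::-1]

    new_pts = np.vstack([start_ext, pts, end_ext])
    n0 = len(start_ext)
    ext = DiscreteCurve(new_pts, closed=False,
                        label=f"{curve.label}+extensions(pad={padding:g})")
    return ExtendedCurve(curve=ext, original=curve,
                         original_range=(n0, n0 + curve.n_points - 1),
                         padding=padding)


def polar_writhe_star(curve: DiscreteCurve, padding: float = DEFAULT_PADDING,
                      **kwargs) -> WritheResult:
    """Extended polar writhe W_p* of an open curve (turns).

    Computed literally as the polar writhe of the extended curve.  Whenever
    no interior point lies beyond the endpoint planes, W_p* equals W_p; a
    configuration in which an interior strand passes exactly through an end
    extension (the over-the-top instant itself) is a self-intersection of the
    extended curve and raises; sample parameter families on either side.
    """
    eps_z = kwargs.pop("eps_z", None)
    ext = extend_curve(curve, padding=padding, eps_z=eps_z)
    return polar_writhe(ext.curve, eps_z=eps_z, **kwargs)
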
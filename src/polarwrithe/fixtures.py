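"""Analytic curve and synthetic-DNA generators.

These generators produce the worked-example geometries used throughout the
package and its tests: twisted paraboloids, the elastic-rod loop-transition
family, uniform helices (closed-form local-writhe oracle), one-parameter
deformation families that realize a self-crossing and an over-the-end
("over-the-top") passage at a known parameter value, and idealized B-DNA
duplexes/minicircles feeding the helical-axis extraction.

All generators are deterministic: identical parameters give identical bytes.
"""

from __future__ import annotations

import numpy as np

from .curves import DiscreteCurve
from .wrline_axis import BasePairTable

__all__ = [
    "make_paraboloid",
    "make_loop_transition",
    "make_helix",
    "make_crossing_family",
    "make_overthetop_family",
    "make_ideal_duplex",
    "CROSSING_LAMBDA_STAR",
    "OVERTHETOP_LAMBDA_STAR",
]

#: parameter value at which one strand of the crossing family passes exactly
#: through another (loop center offset c(lam) = 0.7(1-lam) equals the loop
#: radius 0.35)
CROSSING_LAMBDA_STAR = 0.5
#: parameter value at which the dipping loop of the over-the-top family passes
#: exactly across the vertical line below the start endpoint
OVERTHETOP_LAMBDA_STAR = 0.5


def make_paraboloid(theta: float, h: float, n: int = 2000) -> DiscreteCurve:
    """Twisted paraboloid: a parabolic arc of height ``h`` wound by the
    winding angle ``theta`` about the vertical axis.

    x(t) = ((t-1/2) cos(theta z/h), (t-1/2) sin(theta z/h), z),
    z(t) = 4 h t (1-t),  t uniform on [0, 1].

    Its two z-monotone sections mutually wind by -theta/pi turns.
    """
    if n < 50:
        raise ValueError("paraboloid needs n >= 50 samples")
    t = np.linspace(0.0, 1.0, n)
    z = 4.0 * h * t * (1.0 - t)
    phi = theta * z / h
    r = t - 0.5
    pts = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
    return DiscreteCurve(pts, closed=False,
                         label=f"paraboloid theta={theta:.10g} h={h:.10g} n={n}")


def make_loop_transition(tau: float, n: int = 2001,
                         s_range: tuple[float, float] = (-5.0, 5.0)) -> DiscreteCurve:
    """Elastic-rod equilibrium family transitioning from a helical perversion
    (large tau) to a localized loop (small tau).

    R = 2 sech(s)/(1+tau^2),  Phi = tau s - pi/2,
    z = s - 2 tanh(s)/(1+tau^2),  x = (R cos Phi, R sin Phi, z).

    For tau > 1 the height z(s) is strictly monotone (one section, purely
    local writhe); for tau < 1 a dip appears around s = 0 and the curve
    acquires two turning points (three sections) and non-local writhe.
    """
    if n < 200:
        raise ValueError("loop-transition curve needs n >= 200 samples")
    s = np.linspace(s_range[0], s_range[1], n)
    f = 2.0 / (1.0 + tau * tau)
    R = f / np.cosh(s)
    phi = tau * s - np.pi / 2.0
    z = s - f * np.tanh(s)
    pts = np.column_stack([R * np.cos(phi), R * np.sin(phi), z])
    return DiscreteCurve(pts, closed=False, label=f"loop_transition tau={tau:.10g} n={n}")


def make_helix(a: float, p: float, turns: float, n: int | None = None) -> DiscreteCurve:
    """Uniform helix (a cos t, a sin t, p t) over ``turns`` full turns.

    Closed-form local writhe: turns * (1 - p/sqrt(a^2 + p^2)) for a
    right-handed helix (a > 0, p > 0).
    """
    if n is None:
        n = max(100 * int(np.ceil(turns)), 100)
    if n < 100 * turns:
        raise ValueError("helix needs at least 100 samples per turn")
    t = np.linspace(0.0, 2.0 * np.pi * turns, int(n))
    pts = np.column_stack([a * np.cos(t), a * np.sin(t), p * t])
    return DiscreteCurve(pts, closed=False,
                         label=f"helix a={a:.10g} p={p:.10g} turns={turns:.10g} n={n}")


# ---------------------------------------------------------------------------
# one-parameter deformation families


def _chain(pieces: list[tuple[np.ndarray, np.ndarray]], label: str) -> DiscreteCurve:
    """Concatenate sampled pieces, dropping duplicated junction points."""
    rows = [pieces[0][0]]
    for arr, _ in pieces[1:]:
        rows.append(arr[1:] if np.allclose(arr[0], rows[-1][-1]) else arr)
    pts = np.vstack(rows)
    return DiscreteCurve(pts, closed=False, label=label)


def _line(p0, p1, n) -> np.ndarray:
    u = np.linspace(0.0, 1.0, n)[:, None]
    return np.asarray(p0) * (1 - u) + np.asarray(p1) * u


def _tilted_loop(center: np.ndarray, radius: float, tilt: float, n: int,
                 gap: float = 0.15) -> np.ndarray:
    """Tilted near-circle attached by a small arc gap: phi from pi/2+gap to
    pi/2+2pi-gap, z = center_z + tilt*sin(phi).  Entry is on the descending
    side so the loop continues an incoming descent without a turning point at
    the junction."""
    phi = np.linspace(np.pi / 2 + gap, np.pi / 2 + 2 * np.pi - gap, n)
    cx, cy, cz = center
    return np.column_stack([
        cx + radius * np.cos(phi),
        cy + radius * np.sin(phi),
        cz + tilt * np.sin(phi),
    ])


def make_crossing_family(lam: float, n: int = 1500) -> DiscreteCurve:
    """Open-curve family in which a loop strand passes through the curve's
    own vertical strand at ``lam`` = ``CROSSING_LAMBDA_STAR``.

    The curve rises vertically along the z axis from (0,0,0) to (0,0,2.2),
    arcs over and down into a tilted circular loop (radius 0.35, tilt 0.15)
    centered at (c, 0, 1.1) with c = 0.7(1-lam), then exits downward.  The
    loop point at azimuth pi sits at (c-0.35, 0, 1.1) and passes through the
    vertical strand exactly at c = 0.35, i.e. lam = 0.5.  The polar writhe
    jumps by |2| across this self-crossing and is smooth on either side.
    """
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lam must lie in [0, 1]")
    c = 0.7 * (1.0 - lam)
    gap = 0.15
    entry = np.array([c + 0.35 * np.cos(np.pi / 2 + gap),
                      0.35 * np.sin(np.pi / 2 + gap),
                      1.1 + 0.15 * np.sin(np.pi / 2 + gap)])
    exit_ = np.array([c + 0.35 * np.cos(np.pi / 2 - gap),
                      0.35 * np.sin(np.pi / 2 - gap),
                      1.1 + 0.15 * np.sin(np.pi / 2 - gap)])
    n1 = max(n // 5, 40)          # vertical strand
    n2 = max(n // 8, 30)          # arc up and over
    n3 = max(n // 8, 30)          # descent to the loop
    n5 = max(n // 8, 30)          # exit
    n4 = max(n - (n1 + n2 + n3 + n5) + 4, 200)  # the loop itself
    pieces = [
        (_line([0.0, 0.0, 0.0], [0.0, 0.0, 2.2], n1), None),
        (_line([0.0, 0.0, 2.2], [0.9, 0.35, 2.8], n2), None),
        (_line([0.9, 0.35, 2.8], entry, n3), None),
        (_tilted_loop(np.array([c, 0.0, 1.1]), 0.35, 0.15, n4, gap), None),
        (_line(exit_, [1.5, 0.5, 0.2], n5), None),
    ]
    return _chain(pieces, f"crossing_family lam={lam:.10g} n={n}")


def make_overthetop_family(lam: float, n: int = 1500) -> DiscreteCurve:
    """Open-curve family in which an interior loop is carried below and then
    directly across the vertical line beneath the curve's *start* endpoint.

    The endpoints (0,0,1) and (1,0.8,3.2) are fixed for all ``lam``.  A tilted
    loop (radius 0.35, tilt 0.15) centered at (0.7(1-lam), 0, 1.6-1.6*lam)
    starts between the endpoint planes (lam = 0, where W_p* = W_p), descends
    below the lower endpoint as lam grows, and passes exactly across the
    downward end extension used by the W_p* construction at lam = 0.5,
    producing a |2| jump in W_p* while W_p changes continuously.
    """
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lam must lie in [0, 1]")
    c = 0.7 * (1.0 - lam)
    zc = 1.6 - 1.6 * lam
    gap = 0.15
    entry = np.array([c + 0.35 * np.cos(np.pi / 2 + gap),
                      0.35 * np.sin(np.pi / 2 + gap),
                      zc + 0.15 * np.sin(np.pi / 2 + gap)])
    exit_ = np.array([c + 0.35 * np.cos(np.pi / 2 - gap),
                      0.35 * np.sin(np.pi / 2 - gap),
                      zc + 0.15 * np.sin(np.pi / 2 - gap)])
    n1 = max(n // 5, 40)          # ascent from the start endpoint
    n2 = max(n // 6, 30)          # descent toward the loop
    n4 = max(n // 6, 30)          # exit up to the end endpoint
    n3 = max(n - (n1 + n2 + n4) + 3, 200)  # the loop itself
    pieces = [
        (_line([0.0, 0.0, 1.0], [-1.2, 0.0, 3.0], n1), None),
        (_line([-1.2, 0.0, 3.0], entry, n2), None),
        (_tilted_loop(np.array([c, 0.0, zc]), 0.35, 0.15, n3, gap), None),
        (_line(exit_, [1.0, 0.8, 3.2], n4), None),
    ]
    return _chain(pieces, f"overthetop_family lam={lam:.10g} n={n}")


# ---------------------------------------------------------------------------
# idealized DNA duplexes


def make_ideal_duplex(n_bp: int, twist_deg: float = 36.0, rise: float = 3.38,
                      radius: float = 9.4, closed: bool = False,
                      lk: int | None = None,
                      phase_deg: float = 154.0) -> BasePairTable:
    """Two C1' strands on a straight cylinder (open) or a torus (closed
    minicircle) with the stated per-base-pair twist, rise and radius.

    For a closed minicircle the twist is fixed by the linking number:
    ``lk`` full strand revolutions are distributed over ``n_bp`` steps around
    a planar circular axis of circumference ``n_bp * rise``.  The two strands
    are offset by the inter-strand phase (154 deg, B-DNA-like minor/major
    groove asymmetry).
    """
    if n_bp < 3:
        raise ValueError("need at least 3 base pairs")
    j = np.arange(n_bp)
    phase = np.deg2rad(phase_deg)
    if closed:
        if lk is None:
            raise ValueError("closed duplex requires an integer linking number lk")
        r_c = n_bp * rise / (2.0 * np.pi)
        psi = 2.0 * np.pi * j / n_bp
        phi = 2.0 * np.pi * lk * j / n_bp
        e_r = np.column_stack([np.cos(psi), np.sin(psi), np.zeros(n_bp)])
        e_z = np.array([0.0, 0.0, 1.0])

        def strand(off: float) -> np.ndarray:
            rad = r_c + radius * np.cos(phi + off)
            return rad[:, None] * e_r + (radius * np.sin(phi + off))[:, None] * e_z

        a, b = strand(0.0), strand(phase)
    else:
        phi = np.deg2rad(twist_deg) * j
        z = rise * j
        a = np.column_stack([radius * np.cos(phi), radius * np.sin(phi), z])
        b = np.column_stack([radius * np.cos(phi + phase),
                             radius * np.sin(phi + phase), z])
    return BasePairTable(strand_a=a, strand_b=b, closed=closed,
                         label=(f"ideal_duplex n_bp={n_bp} twist={twist_deg:.10g} "
                                f"rise={rise:.10g} radius={radius:.10g} "
                                f"closed={closed} lk={lk}"))
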
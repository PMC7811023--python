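"""Discrete space curves: data model, I/O, tangents and z-monotone splitting.

A curve is an ordered polyline in 3D.  The topology measures in this package
are all defined relative to a fixed vertical direction, taken to be the +z
axis of the input coordinates.  The central geometric primitive here is the
decomposition of a curve into maximal *z-monotone sections* separated by
*turning points* (heights at which the vertical motion reverses); the local
and non-local writhe are then per-section and per-section-pair functionals.

Turning points are located to sub-vertex precision by cubic interpolation of
z as a function of vertex index, and each section carries the interpolated
turning point as a shared endpoint so that sections tile the curve exactly.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline, PchipInterpolator

from .errors import CurveError, DegenerateAxisError

__all__ = [
    "DiscreteCurve",
    "TangentField",
    "CurveSection",
    "SectionSet",
    "load_curves",
    "save_curves",
    "compute_tangents",
    "split_sections",
    "section_xy_at_height",
]

#: relative tolerance used when merging duplicate consecutive vertices
EPS_LEN_REL = 1e-9
#: relative tolerance (fraction of the z extent) below which a height step is
#: treated as flat when locating turning points
EPS_Z_REL = 1e-9


@dataclass
class DiscreteCurve:
    """An ordered 3D polyline, open or closed.

    For a closed curve the first point is *not* repeated at the end; the
    wraparound edge is implicit.
    """

    points: np.ndarray
    closed: bool = False
    label: str = ""

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise CurveError(f"curve points must be (n, 3), got {pts.shape}")
        if pts.shape[0] < 3:
            raise CurveError(f"curve needs at least 3 points, got {pts.shape[0]}")
        if not np.all(np.isfinite(pts)):
            raise CurveError("curve contains non-finite coordinates")
        seps = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        scale = max(self._extent_of(pts), 1.0)
        if np.any(seps <= EPS_LEN_REL * scale):
            raise CurveError(
                "consecutive curve points coincide; merge duplicates first "
                "(load_curves does this automatically)"
            )
        if self.closed and np.linalg.norm(pts[0] - pts[-1]) <= EPS_LEN_REL * scale:
            raise CurveError(
                "closed curve must not repeat its first point at the end; "
                "drop the final point (the wraparound edge is implicit)"
            )
        self.points = pts

    @staticmethod
    def _extent_of(pts: np.ndarray) -> float:
        return float(np.linalg.norm(pts.max(axis=0) - pts.min(axis=0)))

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    @property
    def z(self) -> np.ndarray:
        return self.points[:, 2]

    @property
    def extent(self) -> float:
        """Diagonal of the bounding box (overall length scale)."""
        return self._extent_of(self.points)

    @property
    def z_extent(self) -> float:
        return float(self.z.max() - self.z.min())

    def reversed(self) -> "DiscreteCurve":
        return DiscreteCurve(self.points[::-1].copy(), self.closed, self.label)

    def transformed(self, rotation: np.ndarray | None = None,
                    translation: np.ndarray | None = None) -> "DiscreteCurve":
        pts = self.points
        if rotation is not None:
            pts = pts @ np.asarray(rotation, dtype=float).T
        if translation is not None:
            pts = pts + np.asarray(translation, dtype=float)
        return DiscreteCurve(pts, self.closed, self.label)


@dataclass
class TangentField:
    """Unit tangents and cumulative arclength for a curve.

    ``edge_tangents`` are the normalized finite differences
    T_j = (x_{j+1} - x_j)/|x_{j+1} - x_j| (including the wraparound edge for
    closed curves); ``tangents`` are per-vertex unit tangents formed by
    normalizing the average of the adjacent edge tangents (one-sided at the
    ends of an open curve).
    """

    tangents: np.ndarray
    arclengths: np.ndarray
    edge_tangents: np.ndarray
    edge_lengths: np.ndarray

    def __post_init__(self) -> None:
        norms = np.linalg.norm(self.tangents, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise CurveError("vertex tangents are not unit vectors")
        if np.any(np.diff(self.arclengths) <= 0):
            raise CurveError("arclengths must be strictly increasing")


@dataclass
class CurveSection:
    """A maximal z-monotone piece of a curve.

    ``points`` includes the interpolated turning points as first/last rows
    where the section boundary falls between vertices.  ``index_range`` is the
    (first, last) *parent vertex* index covered (inclusive); together the
    sections of one curve tile its vertex sequence exactly once.
    """

    points: np.ndarray
    sigma: int
    z_min: float
    z_max: float
    index_range: tuple[int, int]
    parent: DiscreteCurve | None = field(default=None, repr=False)
    _interp_x: PchipInterpolator | None = field(default=None, repr=False, compare=False)
    _interp_y: PchipInterpolator | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.sigma not in (-1, 1):
            raise CurveError("section sigma must be +1 or -1")
        if not self.z_min < self.z_max:
            raise CurveError("section must span a nonzero height range")

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    def _build_interpolators(self) -> None:
        pts = self.points if self.sigma > 0 else self.points[::-1]
        z = pts[:, 2]
        # enforce strictly increasing z for interpolation; near-plateau
        # vertices absorbed into the section are dropped here
        kept = [0]
        for k in range(1, len(z) - 1):
            if z[k] > z[kept[-1]]:
                kept.append(k)
        while len(kept) > 1 and z[kept[-1]] >= z[-1]:
            kept.pop()
        kept.append(len(z) - 1)
        idx = np.asarray(kept)
        zz, xx, yy = z[idx], pts[idx, 0], pts[idx, 1]
        # natural cubic splines are linear in the data, so the interpolated
        # section transforms exactly under rotations of the frame
        if len(zz) >= 4:
            self._interp_x = CubicSpline(zz, xx, bc_type="natural",
                                         extrapolate=False)
            self._interp_y = CubicSpline(zz, yy, bc_type="natural",
                                         extrapolate=False)
        else:
            self._interp_x = PchipInterpolator(zz, xx, extrapolate=False)
            self._interp_y = PchipInterpolator(zz, yy, extrapolate=False)

    def xy_at_heights(self, z: np.ndarray) -> np.ndarray:
        """Vectorized (x, y) of the section at the given heights."""
        if self._interp_x is None:
            self._build_interpolators()
        z = np.asarray(z, dtype=float)
        zc = np.clip(z, self.z_min, self.z_max)
        x = self._interp_x(zc)
        y = self._interp_y(zc)
        return np.column_stack([x, y])


@dataclass
class SectionSet:
    """Ordered z-monotone sections of one curve."""

    sections: list[CurveSection]
    curve: DiscreteCurve

    @property
    def n(self) -> int:
        return len(self.sections)

    def __iter__(self):
        return iter(self.sections)

    def __getitem__(self, i):
        return self.sections[i]


# ---------------------------------------------------------------------------
# tangents


def compute_tangents(curve: DiscreteCurve) -> TangentField:
    """Per-edge and per-vertex unit tangents plus cumulative arclength."""
    pts = curve.points
    if curve.closed:
        edges = np.diff(np.vstack([pts, pts[:1]]), axis=0)
    else:
        edges = np.diff(pts, axis=0)
    lens = np.linalg.norm(edges, axis=1)
    if np.any(lens == 0):
        raise CurveError("zero-length edge in curve")
    etan = edges / lens[:, None]

    n = curve.n_points
    vtan = np.empty((n, 3))
    if curve.closed:
        prev = np.roll(etan, 1, axis=0)
        avg = prev + etan
    else:
        avg = np.empty((n, 3))
        avg[0] = etan[0]
        avg[-1] = etan[-1]
        avg[1:-1] = etan[:-1] + etan[1:]
    norms = np.linalg.norm(avg, axis=1)
    if np.any(norms < 1e-12):
        raise CurveError("curve doubles back on itself exactly; vertex tangent undefined")
    vtan = avg / norms[:, None]

    s = np.concatenate([[0.0], np.cumsum(lens)])[:n]
    return TangentField(tangents=vtan, arclengths=s, edge_tangents=etan, edge_lengths=lens)


# ---------------------------------------------------------------------------
# splitting into z-monotone sections


def _z_spline(curve: DiscreteCurve):
    """Cubic splines of x, y, z versus vertex index (periodic if closed)."""
    pts = curve.points
    if curve.closed:
        idx = np.arange(curve.n_points + 1, dtype=float)
        data = np.vstack([pts, pts[:1]])
        bc = "periodic"
    else:
        idx = np.arange(curve.n_points, dtype=float)
        data = pts
        bc = "natural"
    return [CubicSpline(idx, data[:, k], bc_type=bc) for k in range(3)], idx[-1]


def _turning_indices(curve: DiscreteCurve, eps_z: float) -> list[float]:
    """Fractional vertex indices of turning points (cyclic for closed)."""
    z = curve.z
    if curve.closed:
        dz = np.diff(np.concatenate([z, z[:1]]))
    else:
        dz = np.diff(z)
    sgn = np.sign(dz)
    sgn[np.abs(dz) <= eps_z] = 0

    nz = np.nonzero(sgn)[0]
    if len(nz) == 0:
        raise DegenerateAxisError(
            "curve height is constant everywhere relative to the z axis; "
            "choose a different reference axis"
        )

    spl, period = _z_spline(curve)
    dspl = spl[2].derivative()
    try:
        stat = dspl.roots(extrapolate=False)
    except Exception:  # pragma: no cover - scipy always supports this
        stat = np.array([])

    n_edges = len(dz)
    turns: list[float] = []

    # walk consecutive nonzero-sign edges (cyclically for closed curves)
    order = list(nz)
    pairs = list(zip(order[:-1], order[1:]))
    if curve.closed:
        pairs.append((order[-1], order[0] + n_edges))
    for e0, e1 in pairs:
        s0 = sgn[e0 % n_edges]
        s1 = sgn[e1 % n_edges]
        if s0 == s1:
            continue
        if e1 - e0 > 1:
            # plateau of near-flat edges flanked by opposite signs: split at
            # its midpoint (deterministic tie-break)
            turns.append(((e0 + 1) + e1) / 2.0 % (period if curve.closed else np.inf))
            continue
        # sign flip across vertex e0+1: true extremum in (e0, e0+2)
        lo, hi = float(e0), float(e0 + 2)
        u = None
        if len(stat):
            cand = stat
            if curve.closed:
                cand = np.concatenate([stat, stat + period])
            inside = cand[(cand > lo) & (cand < hi)]
            if len(inside):
                u = float(inside[np.argmin(np.abs(inside - (e0 + 1)))])
        if u is None:
            u = float(e0 + 1)
        turns.append(u % period if curve.closed else u)

    return sorted(turns)


def split_sections(curve: DiscreteCurve, tangents: TangentField | None = None,
                   eps_z: float | None = None) -> SectionSet:
    """Split a curve at its turning points into z-monotone sections.

    Turning points are located by cubic interpolation of z along the vertex
    index and become shared, interpolated endpoints of adjacent sections.  An
    open curve with no turning point yields a single section.  For a closed
    curve the (even) section list starts at the lowest turning point.
    """
    if eps_z is None:
        eps_z = EPS_Z_REL * max(curve.z_extent, EPS_Z_REL * max(curve.extent, 1.0))
    if curve.z_extent <= max(eps_z, 0.0) or curve.z_extent == 0.0:
        raise DegenerateAxisError(
            "curve height is constant everywhere relative to the z axis; "
            "choose a different reference axis"
        )
    turns = _turning_indices(curve, eps_z)
    spl, period = _z_spline(curve)

    def point_at(u: float) -> np.ndarray:
        return np.array([spl[0](u), spl[1](u), spl[2](u)])

    n = curve.n_points
    pts = curve.points
    sections: list[CurveSection] = []

    def build(u0: float, u1: float) -> CurveSection:
        """Section between fractional indices u0 < u1 (u1 may exceed the
        period for closed curves)."""
        first = int(np.ceil(u0 - 1e-9))
        last = int(np.floor(u1 + 1e-9))
        rows = []
        if u0 < first - 1e-9:
            rows.append(point_at(u0 % period if curve.closed else u0))
        interior = np.arange(first, last + 1)
        rows.append(pts[interior % n] if curve.closed else pts[interior])
        if u1 > last + 1e-9:
            rows.append(point_at(u1 % period if curve.closed else u1))
        arr = np.vstack([np.atleast_2d(r) for r in rows])
        z0, z1 = arr[0, 2], arr[-1, 2]
        sigma = 1 if z1 >= z0 else -1
        return CurveSection(
            points=arr, sigma=sigma,
            z_min=float(min(z0, z1)), z_max=float(max(z0, z1)),
            index_range=(int(first), int(last)), parent=curve,
        )

    if not curve.closed:
        bounds = [0.0] + [u for u in turns if 1e-9 < u < n - 1 - 1e-9] + [float(n - 1)]
        for u0, u1 in zip(bounds[:-1], bounds[1:]):
            sections.append(build(u0, u1))
    else:
        if len(turns) == 0:
            raise DegenerateAxisError("closed curve with no turning points is degenerate")
        # start at the lowest turning point
        zs = [float(spl[2](u)) for u in turns]
        start = int(np.argmin(zs))
        turns = turns[start:] + [u + period for u in turns[:start]]
        turns.append(turns[0] + period)
        for u0, u1 in zip(turns[:-1], turns[1:]):
            sections.append(build(u0, u1))

    # drop degenerate slivers (can arise from plateau midpoints)
    sections = [s for s in sections if s.z_max - s.z_min > eps_z]
    if not sections:
        raise DegenerateAxisError("no usable z-monotone sections found")
    return SectionSet(sections=sections, curve=curve)


def section_xy_at_height(section: CurveSection, z: float,
                         eps_z: float | None = None) -> tuple[float, float]:
    """The unique (x, y) point of a z-monotone section at the given height."""
    if eps_z is None:
        eps_z = 1e-9 * max(section.z_max - section.z_min, 1.0)
    if z < section.z_min - eps_z or z > section.z_max + eps_z:
        raise CurveError(
            f"height {z} outside section range [{section.z_min}, {section.z_max}]"
        )
    xy = section.xy_at_heights(np.array([z]))[0]
    return float(xy[0]), float(xy[1])


# ---------------------------------------------------------------------------
# file I/O


def _merge_duplicates(pts: np.ndarray, origin: str) -> np.ndarray:
    scale = max(float(np.linalg.norm(pts.max(axis=0) - pts.min(axis=0))), 1.0)
    seps = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    dup = seps <= EPS_LEN_REL * scale
    if np.any(dup):
        warnings.warn(f"{origin}: merged {int(dup.sum())} duplicate consecutive point(s)")
        keep = np.concatenate([[True], ~dup])
        pts = pts[keep]
    return pts


def _frames_to_curves(frames: list[np.ndarray], origin: str,
                      closed: bool = False) -> list[DiscreteCurve]:
    curves = []
    for k, arr in enumerate(frames, start=1):
        arr = _merge_duplicates(np.asarray(arr, dtype=float), f"{origin} frame {k}")
        if arr.shape[0] < 3:
            raise CurveError(f"{origin}: frame {k} has fewer than 3 points")
        curves.append(DiscreteCurve(arr, closed=closed, label=f"{origin}#{k}"))
    return curves


def _parse_xyz(text: str, origin: str) -> list[np.ndarray]:
    lines = text.splitlines()
    # auto-detect leading-count dialect: first non-blank line is one integer
    first = next((ln for ln in lines if ln.strip()), None)
    if first is None:
        raise CurveError(f"{origin}: empty file")
    toks = first.split()
    count_mode = len(toks) == 1 and toks[0].lstrip("+-").isdigit()

    frames: list[list[list[float]]] = []
    if count_mode:
        i = 0
        while i < len(lines):
            if not lines[i].strip():
                i += 1
                continue
            try:
                cnt = int(lines[i].split()[0])
            except ValueError:
                raise CurveError(f"{origin}: line {i + 1}: expected a point count")
            rows = []
            j = i + 1
            while len(rows) < cnt and j < len(lines):
                if lines[j].strip():
                    rows.append(_parse_point(lines[j], j + 1, origin))
                j += 1
            if len(rows) != cnt:
                raise CurveError(f"{origin}: frame starting line {i + 1}: "
                                 f"expected {cnt} points, found {len(rows)}")
            frames.append(rows)
            i = j
    else:
        rows: list[list[float]] = []
        for j, ln in enumerate(lines, start=1):
            if not ln.strip():
                if rows:
                    frames.append(rows)
                    rows = []
                continue
            rows.append(_parse_point(ln, j, origin))
        if rows:
            frames.append(rows)
    return [np.asarray(f, dtype=float) for f in frames]


def _parse_point(line: str, lineno: int, origin: str) -> list[float]:
    toks = line.split()
    if len(toks) < 3:
        raise CurveError(f"{origin}: line {lineno}: expected 3 coordinates")
    try:
        return [float(toks[0]), float(toks[1]), float(toks[2])]
    except ValueError as exc:
        raise CurveError(f"{origin}: line {lineno}: non-numeric token ({exc})")


def _parse_csv(path_or_buf, origin: str) -> list[np.ndarray]:
    try:
        df = pd.read_csv(path_or_buf)
    except Exception as exc:
        raise CurveError(f"{origin}: cannot parse CSV ({exc})")
    cols = {c.strip().lower(): c for c in df.columns}
    for req in ("x", "y", "z"):
        if req not in cols:
            raise CurveError(f"{origin}: CSV must have columns x,y,z[,frame]")
    for req in ("x", "y", "z"):
        if not pd.api.types.is_numeric_dtype(df[cols[req]]):
            raise CurveError(f"{origin}: non-numeric values in column '{req}'")
    if "frame" in cols:
        frames = [g[[cols["x"], cols["y"], cols["z"]]].to_numpy(dtype=float)
                  for _, g in df.groupby(cols["frame"], sort=True)]
    else:
        frames = [df[[cols["x"], cols["y"], cols["z"]]].to_numpy(dtype=float)]
    return frames


def _parse_pdb(path, atom_names: tuple[str, ...], origin: str) -> list[np.ndarray]:
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("curve", str(path))
    frames = []
    for model in structure:
        rows = [atom.coord.astype(float)
                for chain in model for res in chain for atom in res
                if atom.get_name() in atom_names]
        if rows:
            frames.append(np.asarray(rows, dtype=float))
    if not frames:
        raise CurveError(f"{origin}: no atoms named {atom_names} found")
    return frames


def load_curves(path, fmt: str | None = None, closed: bool = False,
                atom_name: str = "C1'") -> list[DiscreteCurve]:
    """Read one curve per frame from an xyz, csv or pdb file.

    ``fmt`` is inferred from the file extension when omitted.  The xyz dialect
    is whitespace-separated "x y z" rows with frames delimited either by blank
    lines or by a leading per-frame count line (auto-detected).  For PDB input
    the curve is the ordered set of atoms matching ``atom_name`` (C1' and C1*
    spellings both accepted by default) with MODEL records delimiting frames.
    """
    path = Path(path)
    if fmt is None:
        ext = path.suffix.lower().lstrip(".")
        fmt = {"xyz": "xyz", "txt": "xyz", "dat": "xyz",
               "csv": "csv", "pdb": "pdb", "ent": "pdb"}.get(ext, "xyz")
    origin = path.name
    if fmt == "xyz":
        frames = _parse_xyz(path.read_text(), origin)
    elif fmt == "csv":
        frames = _parse_csv(path, origin)
    elif fmt == "pdb":
        names = (atom_name, atom_name.replace("'", "*")) if "'" in atom_name \
            else (atom_name, atom_name.replace("*", "'"))
        frames = _parse_pdb(path, names, origin)
    else:
        raise CurveError(f"unknown curve format: {fmt!r}")
    if not frames:
        raise CurveError(f"{origin}: no frames found")
    return _frames_to_curves(frames, origin, closed=closed)


def save_curves(curves, path, fmt: str | None = None) -> None:
    """Write curves to xyz (blank-line separated frames) or csv."""
    if isinstance(curves, DiscreteCurve):
        curves = [curves]
    path = Path(path)
    if fmt is None:
        fmt = "csv" if path.suffix.lower() == ".csv" else "xyz"
    if fmt == "xyz":
        buf = io.StringIO()
        for k, c in enumerate(curves):
            if k:
                buf.write("\n")
            for p in c.points:
                buf.write(f"{p[0]:.17g} {p[1]:.17g} {p[2]:.17g}\n")
        path.write_text(buf.getvalue())
    elif fmt == "csv":
        parts = []
        for k, c in enumerate(curves, start=1):
            df = pd.DataFrame(c.points, columns=["x", "y", "z"])
            df["frame"] = k
            parts.append(df)
        pd.concat(parts).to_csv(path, index=False, float_format="%.17g")
    else:
        raise CurveError(f"unknown curve format: {fmt!r}")
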
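"""Helical-axis extraction from per-base-pair C1' coordinates (WrLINE).

A naive DNA axis built from base-pair C1' midpoints inherits the helical
periodicity of the backbone and therefore carries spurious local writhe.  The
WrLINE construction removes it by averaging dinucleotide-step midpoints over
exactly one full helical turn around each step, using the local base-pair
step twists to decide how many steps a turn spans and to weight the
outermost pair of steps fractionally so the averaging window covers 2*pi of
twist exactly.

Modes
-----
``closed``
    wraps indices around the circle (minicircles); one axis point per base
    pair.
``autodelete``
    open molecules; axis points are produced only where a full helical turn
    fits inside the molecule, so the axis has fewer points than base pairs.
``deleteatoms``
    open molecules computed as if closed; end-effect points (whose window
    wrapped across the artificial junction) are flagged for removal rather
    than silently deleted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .curves import DiscreteCurve
from .errors import CurveError

__all__ = [
    "BasePairTable",
    "AxisCurve",
    "bp_midpoints",
    "dinucleotide_midpoints",
    "step_twists",
    "wrline_axis",
    "load_bp_table",
    "save_bp_table_pdb",
]


@dataclass
class BasePairTable:
    """Per-base-pair C1' coordinates of the two strands of a duplex.

    Row j of ``strand_a`` and ``strand_b`` are the paired C1' atoms of base
    pair j (complementary strands in antiparallel order).
    """

    strand_a: np.ndarray
    strand_b: np.ndarray
    closed: bool = False
    label: str = ""

    def __post_init__(self) -> None:
        a = np.asarray(self.strand_a, dtype=float)
        b = np.asarray(self.strand_b, dtype=float)
        if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
            raise CurveError("strand coordinate arrays must both be (N, 3)")
        if not self.closed and a.shape[0] < 12:
            raise CurveError("open duplex needs at least 12 base pairs "
                             "(a full helical turn must exist somewhere)")
        if a.shape[0] < 3:
            raise CurveError("need at least 3 base pairs")
        self.strand_a, self.strand_b = a, b

    @property
    def n_bp(self) -> int:
        return self.strand_a.shape[0]

    def transformed(self, rotation=None, translation=None) -> "BasePairTable":
        def tf(x):
            if rotation is not None:
                x = x @ np.asarray(rotation, dtype=float).T
            if translation is not None:
                x = x + np.asarray(translation, dtype=float)
            return x
        return BasePairTable(tf(self.strand_a), tf(self.strand_b),
                             self.closed, self.label)


@dataclass
class AxisCurve:
    """Extracted helical axis with per-point provenance."""

    curve: DiscreteCurve
    step_indices: np.ndarray
    mode: str
    flagged: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    @property
    def n_points(self) -> int:
        return self.curve.n_points


def bp_midpoints(table: BasePairTable) -> np.ndarray:
    """Midpoint of the two C1' atoms of each base pair (the naive axis)."""
    return 0.5 * (table.strand_a + table.strand_b)


def dinucleotide_midpoints(table: BasePairTable) -> np.ndarray:
    """Midpoint of the 4 C1' atoms of each 2-base-pair (dinucleotide) step.

    Closed tables wrap (N values); open tables yield N-1 values.
    """
    m = bp_midpoints(table)
    if table.closed:
        return 0.5 * (m + np.roll(m, -1, axis=0))
    return 0.5 * (m[:-1] + m[1:])


def _bp_vectors(table: BasePairTable) -> np.ndarray:
    return table.strand_b - table.strand_a


def _central_diff(pts: np.ndarray, wrap: bool) -> np.ndarray:
    if wrap:
        d = np.roll(pts, -1, axis=0) - np.roll(pts, 1, axis=0)
    else:
        d = np.empty_like(pts)
        d[1:-1] = pts[2:] - pts[:-2]
        d[0] = pts[1] - pts[0]
        d[-1] = pts[-1] - pts[-2]
    return d


def _twists_about(r: np.ndarray, v: np.ndarray, axis_dirs: np.ndarray,
                  wrap: bool) -> np.ndarray:
    """Twist angles of consecutive bp vectors about the given local axis
    directions."""
    axis = axis_dirs.copy()
    norms = np.linalg.norm(axis, axis=1)
    if np.any(norms < 1e-9):
        bad = int(np.argmin(norms))
        raise CurveError(f"degenerate local axis at dinucleotide step {bad} "
                         "(consecutive midpoints coincide)")
    axis /= norms[:, None]

    if wrap:
        v0, v1 = v, np.roll(v, -1, axis=0)
    else:
        v0, v1 = v[:-1], v[1:]

    def proj(w, u):
        return w - (np.sum(w * u, axis=1))[:, None] * u

    p0 = proj(v0, axis)
    p1 = proj(v1, axis)
    n0 = np.linalg.norm(p0, axis=1)
    n1 = np.linalg.norm(p1, axis=1)
    if np.any(n0 < 1e-9) or np.any(n1 < 1e-9):
        raise CurveError("base-pair vector parallel to the local axis; "
                         "twist undefined")
    cosang = np.clip(np.sum(p0 * p1, axis=1) / (n0 * n1), -1.0, 1.0)
    return np.arccos(cosang)


def _smooth_axis_dirs(r: np.ndarray, theta: np.ndarray, wrap: bool) -> np.ndarray:
    """De-coiled local axis directions from the one-helical-turn weighted
    average of the midpoints.  Where a full turn does not fit (the ends of an
    open molecule) the nearest eligible direction is propagated."""
    n = len(r)
    smooth = np.full_like(r, np.nan)
    eligible = []
    for i in range(n):
        win = _window(i, theta, wrap)
        if win is None:
            continue
        m, w = win
        idx = np.arange(i - m, i + m + 1)
        weights = np.ones(len(idx))
        if m > 0:
            weights[0] = weights[-1] = w
        smooth[i] = (weights[:, None] * r[idx % n]).sum(axis=0) / weights.sum()
        eligible.append(i)
    if len(eligible) < 2:
        raise CurveError("too few full-turn windows to refine the axis")
    if wrap:
        return _central_diff(smooth, wrap=True)
    e = np.asarray(eligible)
    he = smooth[e]
    de = _central_diff(he, wrap=False)
    dirs = np.empty_like(r)
    dirs[: e[0] + 1] = de[0]
    dirs[e[-1]:] = de[-1]
    for k, i in enumerate(e):
        dirs[i] = de[k]
    # interior gaps cannot occur (eligibility is contiguous), ends are filled
    return dirs


def step_twists(table: BasePairTable, degrees: bool = False,
                refine: bool = True) -> np.ndarray:
    """Base-pair step twist per dinucleotide step.

    The angle between the C1'->C1' vectors of consecutive base pairs, each
    projected onto the plane perpendicular to the local axis direction.  A
    first pass estimates the axis by central differences of the dinucleotide
    midpoints; because those midpoints still coil around the true axis, the
    estimate is refined (``refine=True``) by re-projecting against the
    direction of the one-turn-smoothed axis, which removes the coil-tilt
    bias.  Values lie in (0, pi); twist handedness is not resolved.
    """
    if table.n_bp < 3:
        raise CurveError("step twists need at least 3 base pairs")
    r = dinucleotide_midpoints(table)
    v = _bp_vectors(table)
    wrap = table.closed
    theta = _twists_about(r, v, _central_diff(r, wrap), wrap)
    if refine:
        try:
            dirs = _smooth_axis_dirs(r, theta, wrap)
            theta = _twists_about(r, v, dirs, wrap)
        except CurveError:
            pass  # fall back to the single-pass estimate
    return np.rad2deg(theta) if degrees else theta


def _window(i: int, theta: np.ndarray, wrap: bool) -> tuple[int, float] | None:
    """Smallest half-width m such that the twists over steps i-m..i+m sum to
    at least one full turn, and the fractional weight w for the outermost
    pair making the coverage exactly 2*pi."""
    n = len(theta)
    total = theta[i]
    m = 0
    while total < 2.0 * np.pi:
        m += 1
        lo, hi = i - m, i + m
        if not wrap and (lo < 0 or hi >= n):
            return None
        if wrap and 2 * m + 1 > n:
            return None
        total += theta[lo % n] + theta[hi % n]
    if m == 0:
        return 0, 1.0
    inner = total - theta[(i - m) % n] - theta[(i + m) % n]
    w = (2.0 * np.pi - inner) / (theta[(i - m) % n] + theta[(i + m) % n])
    return m, float(w)


def wrline_axis(table: BasePairTable, mode: str = "autodelete",
                drop_flagged: bool = False) -> AxisCurve:
    """Extract the smoothed helical axis from a base-pair table.

    For each eligible dinucleotide midpoint r_i the axis point h_i is the
    normalized weighted average of r_{i-m}..r_{i+m}, unit weights inside and
    the fractional weight w on the outermost pair, where (m, w) close the
    window's twist coverage to exactly one helical turn.
    """
    if mode not in ("closed", "autodelete", "deleteatoms"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "closed" and not table.closed:
        raise CurveError("mode='closed' requires a closed base-pair table")
    if mode != "closed" and table.closed:
        raise CurveError(f"mode={mode!r} applies to open structures only")

    if mode == "deleteatoms":
        # compute as if covalently closed, flag the end-effect points
        work = BasePairTable(table.strand_a, table.strand_b, closed=True,
                             label=table.label)
    else:
        work = table
    r = dinucleotide_midpoints(work)
    theta = step_twists(work)
    n = len(r)
    wrap = work.closed

    points, prov, flagged = [], [], []
    for i in range(n):
        win = _window(i, theta, wrap)
        if win is None:
            continue
        m, w = win
        idx = np.arange(i - m, i + m + 1)
        weights = np.ones(len(idx))
        if m > 0:
            weights[0] = weights[-1] = w
        h = (weights[:, None] * r[idx % n]).sum(axis=0) / weights.sum()
        points.append(h)
        prov.append(i)
        if mode == "deleteatoms" and (i - m < 0 or i + m >= n):
            flagged.append(len(points) - 1)

    if len(points) < 3:
        raise CurveError(
            "no index admits a full helical turn on both sides; use a longer "
            "molecule or mode='deleteatoms'"
        )
    points = np.asarray(points)
    prov = np.asarray(prov)
    flagged_arr = np.asarray(flagged, dtype=int)
    if mode == "deleteatoms" and drop_flagged and len(flagged_arr):
        keep = np.setdiff1d(np.arange(len(points)), flagged_arr)
        points, prov = points[keep], prov[keep]
        flagged_arr = np.array([], dtype=int)
    curve = DiscreteCurve(points, closed=(mode == "closed"),
                          label=f"wrline_axis mode={mode} of {table.label}")
    return AxisCurve(curve=curve, step_indices=prov, mode=mode, flagged=flagged_arr)


# ---------------------------------------------------------------------------
# I/O


def load_bp_table(path, fmt: str | None = None, closed: bool = False,
                  atom_name: str = "C1'",
                  chains: tuple[str, str] | None = None) -> list[BasePairTable]:
    """Read per-base-pair C1' tables from a PDB file or a CSV table.

    PDB: the first two chains containing matching atoms are taken as the two
    strands (override with ``chains``); base pair j pairs residue j of strand
    A with residue N+1-j of strand B (antiparallel).  MODEL records delimit
    frames.  CSV: columns a_x,a_y,a_z,b_x,b_y,b_z (one row per base pair,
    single frame).
    """
    path = Path(path)
    if fmt is None:
        fmt = "pdb" if path.suffix.lower() in (".pdb", ".ent") else "csv"
    if fmt == "csv":
        df = pd.read_csv(path)
        cols = ["a_x", "a_y", "a_z", "b_x", "b_y", "b_z"]
        if not all(c in df.columns for c in cols):
            raise CurveError(f"{path.name}: CSV needs columns {','.join(cols)}")
        a = df[["a_x", "a_y", "a_z"]].to_numpy(dtype=float)
        b = df[["b_x", "b_y", "b_z"]].to_numpy(dtype=float)
        return [BasePairTable(a, b, closed=closed, label=path.name)]

    from Bio.PDB import PDBParser

    names = {atom_name, atom_name.replace("'", "*")}
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("dna", str(path))
    tables = []
    for model in structure:
        per_chain: dict[str, list[np.ndarray]] = {}
        for chain in model:
            coords = [atom.coord.astype(float)
                      for res in chain for atom in res
                      if atom.get_name() in names]
            if coords:
                per_chain[chain.id] = coords
        if chains is not None:
            ids = list(chains)
        else:
            ids = list(per_chain)[:2]
        if len(ids) < 2 or any(c not in per_chain for c in ids):
            raise CurveError(f"{path.name}: need two chains with {atom_name} atoms")
        a = np.asarray(per_chain[ids[0]])
        b = np.asarray(per_chain[ids[1]])[::-1]  # antiparallel pairing
        if a.shape != b.shape:
            raise CurveError(f"{path.name}: strands have unequal lengths")
        tables.append(BasePairTable(a, b, closed=closed, label=path.name))
    if not tables:
        raise CurveError(f"{path.name}: no usable models found")
    return tables


def save_bp_table_pdb(table: BasePairTable, path) -> None:
    """Write a base-pair table as a minimal two-chain PDB of C1' atoms."""
    from Bio.PDB import PDBIO, StructureBuilder

    sb = StructureBuilder.StructureBuilder()
    sb.init_structure("dna")
    sb.init_model(0)
    n = table.n_bp
    for cid, coords in (("A", table.strand_a), ("B", table.strand_b[::-1])):
        sb.init_chain(cid)
        sb.init_seg("    ")
        for j, xyz in enumerate(coords, start=1):
            sb.init_residue("DA" if cid == "A" else "DT", " ", j, " ")
            sb.init_atom("C1'", np.asarray(xyz, dtype=float), 0.0, 1.0, " ",
                         "C1'", j, element="C")
    io = PDBIO()
    io.set_structure(sb.get_structure())
    io.save(str(path))
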
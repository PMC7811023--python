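# Methods

## Model

A curve is an ordered polyline `x_0 … x_{n-1}` in 3D, open or closed (closed
curves carry an implicit wraparound edge; the first point is not repeated).
All topology measures are taken relative to a fixed vertical direction — the
+z axis of the input coordinates.  This is the right frame for systems that
are physically anchored between two planes (tweezer-stretched DNA aligned
with ẑ, rod ends clamped between plates); for other data the CLI offers
pre-rotation flags (`--rotate-x/--rotate-y`), and a curve whose height is
constant everywhere is rejected with a request to choose a different
reference axis rather than silently analyzed.

### Curve splitting

Turning points are heights at which dz reverses sign along the curve.  They
are located to sub-vertex precision by cubic-spline interpolation of z
against the vertex index (natural boundary conditions at open ends, periodic
for closed curves): stationary points of the spline are matched to the edges
where the discrete Δz changes sign, and x, y are interpolated at the same
fractional index.  Runs of edges with |Δz| below ε_z (default 1e-9 of the
z extent) are absorbed into the current section; a flat run flanked by
opposite signs splits at its midpoint — a deterministic tie-break for exact
plateaus.  Each section carries the interpolated turning points as shared
endpoints, so the sections tile the curve exactly; for closed curves the
(always even) section list starts at the lowest turning point.

### Local writhe

Per section, the vertical-rotation integrand is integrated in arclength
rather than height: with dz = (ẑ·T) ds the integrand becomes
σ (1 − |ẑ·T|) dα, where α is the azimuth of the tangent and σ the section
orientation.  This form is finite at turning points (where dT/dz diverges)
and is accumulated discretely over consecutive edge tangents: per pair, the
azimuth step wrapped into (−π, π] times the midpoint of the weight
1 − |ẑ·T|.  The rule is second-order accurate on smooth curves (the
3-turn unit helix at 10⁴ samples recovers the closed form
N(1 − p/√(a²+p²)) to 9e-5), remains bounded at polyline corners, and
assigns exactly zero to vertical edges — the geodesic from the tangent
sphere's pole has constant azimuth — which makes the straight end
extensions of the W_p* construction exact zeros by construction rather than
numerically.

### Non-local writhe

Every unordered pair of sections with a non-empty mutual height range
contributes 2 σ_i σ_j ΔΘ_ij/2π, where Θ_ij(z) is the planar angle of the
vector from section i to section j at height z.  Θ is sampled on a common
z-grid of max(32, 4 × overlapping vertices) points; consecutive differences
are wrapped into (−π, π] and summed (branch-cut tracking), so entire
windings are counted — the wrapped sum telescopes, meaning the result
depends only on the endpoint angles and the winding count, not on interior
sampling error.  The grid is inset from the overlap ends by a relative
1e-7: adjacent sections meet at a shared turning point where the joining
vector vanishes and its angle, though convergent, is undefined at the point
itself.  Section positions at grid heights come from natural cubic splines
of x and y against z; splines are linear in the data, so results are
exactly equivariant under rotations about ẑ (verified to 1e-9).  If two
sections pass within ε_len (default 1e-9 of the bounding-box diagonal) of
each other at a shared height, the winding angle is undefined and the curve
is reported as self-intersecting rather than assigned an arbitrary value.

Candidate pairs are found by sweeping the sections in order of ascending
z_min; any exact interval-intersection method gives identical results.

### Gauss writhe

For comparison with closed-ribbon analyses, Wr is evaluated as the exact
discrete Gauss integral: per non-adjacent segment pair, the signed solid
angle of the spherical quadrilateral spanned by the endpoint directions
(four arcsines plus an orientation sign), summed over unordered pairs and
doubled.  Adjacent segments — which share a vertex and are therefore
coplanar — contribute exactly zero and are skipped.  Coplanar pairs are
zeroed explicitly via the normalized volume of the endpoint tetrahedron
(threshold 1e-10): this removes √ε arcsine noise (a planar circle evaluates
to 0 at 1e-12 rather than 1e-7) and is what makes exact crossings
detectable — an intersecting pair is coplanar with |Ω*| → 2π, so pairs with
|Ω*| > 2π − 0.2 get an explicit segment-distance check and raise when
closer than ε_len.  Open curves are evaluated as-is; no closure is ever
constructed.

### W_p*: end extensions

W_p* is computed literally: each end of an open curve is prolonged by a
straight vertical segment that continues the endpoint's direction of
vertical motion (a curve leaving its start upward is extended downward
below it, and symmetrically at the far end), long enough to pass the
curve's global z extreme on that side by `padding` (default 5%) of the z
extent, sampled at the curve's median edge length.  Continuing the vertical
motion means no turning point is created at the junction: the extended
curve has the same section structure with elongated terminal sections, and
whenever no interior point lies beyond the endpoint planes, W_p* = W_p
*exactly* (tested to 1e-6; the local parts agree to machine precision
always).  Results are padding-invariant (tested at 1% vs 20%).  The instant
at which an interior strand passes exactly through an extension is a
self-intersection of the extended curve and raises; parameter families are
sampled on either side of it.

If both endpoints sit at the same height with the whole body above them,
both extensions point downward — well-defined under this rule, though we
know of no published configuration of that shape to compare against.

### Jump detection

Frame-to-frame changes of |Δ| > 1 (default threshold) in a trajectory
series are flagged: topological events change W_p or W_p* by exactly ±2,
while geometric frame-to-frame drift in practice stays far below 1.  A jump
in W_p* without a matching jump in W_p classifies as an over-the-top end
passage; a jump in W_p as a self-crossing.  Frames that fail to evaluate
(e.g. a degenerate flat frame) are recorded as missing with the reason
logged, and the series continues.

### WrLINE axis extraction

Input is a per-base-pair table of paired C1' coordinates.  Dinucleotide
midpoints r_i (mean of the 4 C1' atoms of base pairs j, j+1) still coil
about the true helical axis at roughly a quarter of the backbone radius;
the axis point h_i is therefore the weighted average of r_{i−m} … r_{i+m},
unit weights inside and a fractional weight w on the outermost pair, where
m is the smallest half-width for which the summed base-pair step twists
reach 2π and w closes the coverage to exactly one helical turn.  (The
combination rule — normalized weighted mean with fractional outermost
weights — is this package's concrete reading of the construction, validated
by recovery tests rather than against any external implementation.)

Step twists are the angles between consecutive C1'→C1' base-pair vectors
projected perpendicular to the local axis direction.  A single pass using
the central difference of the r_i as the axis direction inherits the coil
tilt and overestimates twist by up to ~3.6° at 48°/bp; a refinement pass
re-projects against the direction of the one-turn-smoothed axis, after
which construction twists of 24/36/48° are recovered to better than 0.03°
(`refine=False` gives the single-pass value).  End handling for open
molecules: `autodelete` emits axis points only where a full turn fits
(hence fewer points than base pairs); `deleteatoms` computes as if closed
and *flags* the end-effect points — they are removed only on explicit
request, since silently deleting data invites misuse.

Known bias: window-averaging a *curved* axis pulls points inward by the
chord-versus-arc factor, ≈ R(1 − sinc(Ψ/2)) for window arc Ψ — about
0.5 Å for a 108-bp minicircle with Lk = 14.  This is inherent to one-turn
averaging, affects the radius only (the recovered minicircle axis is flat
to 0.005 Å and carries |W_p| < 1e-4 after tilting out of the degenerate
horizontal plane), and is why the minicircle recovery test uses a 0.75 Å
band while the straight-duplex test demands 0.1 Å collinearity.

## Synthetic fixtures and what they do (not) show

The built-in generators supply every geometry the tests use: twisted
paraboloids x(t) = ((t−½)cos(θz/h), (t−½)sin(θz/h), 4ht(1−t)) whose
non-local writhe is −θ/π analytically; the elastic-rod loop-transition
family R = 2 sech(s)/(1+τ²), Φ = τs − π/2, z = s − 2 tanh(s)/(1+τ²) on
s ∈ [−5, 5], which develops turning points exactly when τ < 1; uniform
helices as a closed-form local-writhe oracle; idealized B-DNA duplexes
(radius 9.4 Å, rise 3.38 Å, inter-strand phase 154°, chosen as standard
B-form geometry) on a cylinder or a torus; and two one-parameter
deformation families with an analytically known event parameter λ* = 0.5 —
a loop carried through the curve's own vertical strand (self-crossing) and
a loop carried below and across the vertical line beneath an endpoint
(over-the-top).  The families are piecewise-analytic polylines; jump
magnitudes are parametrization-independent, which is exactly what the tests
assert.  All generators are deterministic: identical parameters give
identical bytes.

These fixtures are noise-free, perfectly paired and ideally regular.
Passing tests therefore demonstrate the correctness and convergence of the
geometry/topology machinery, not robustness to thermal fluctuations,
missing atoms, or irregular base pairing in real MD trajectories; for real
data the input-validation errors (coincident strands, degenerate frames,
unpaired chains) are the first line of defence.

## Problem sizes and numerical defaults

Analytic examples are evaluated at 2000–2001 samples per curve (the
loop-transition sweep: 200 frames of 2001 points), deformation families at
1500–2000 samples, the closed-curve equivalence suite on a 2000-point
trefoil plus 20 random 1500-point embedded closed curves, and duplexes at
60 bp (open) / 108 bp (minicircle).  At these sizes every reported value is
converged well past its test tolerance (winding values to ~1e-6, W_p vs Wr
to ~4e-3 worst-case) and the full suite plus the acceptance script run in
well under a minute.  Defaults: winding grid max(32, 4 × overlap vertices);
grid end inset 1e-7; ε_z = 1e-9 × z extent; ε_len = 1e-9 × bounding
diagonal; W_p* padding 0.05; jump threshold 1.0.  All are exposed as
function arguments and CLI flags and echoed into output metadata.

## Known limitations

* The vertical reference axis is a modelling choice; W_p is invariant under
  rotations about ẑ and translations but not under arbitrary rotations
  (unlike Wr).  Heavily tilted inputs should be pre-rotated.
* Twist is never computed from a secondary ribbon curve; in applications it
  is obtained as Lk − W_p.
* Knot types are not identified, and compensating ±2 jump pairs in W_p*
  (an equal number of positive and negative passages) can mask a change of
  entanglement; the series output keeps every event so such cases remain
  visible.
* The loop-transition family switches from purely local to mixed writhe
  when τ crosses 1 (between frames 143 and 144 of the standard 200-step
  sweep, where the non-local component turns on at ≈ 0.14); this boundary
  is analytic, not a resolution artifact.
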
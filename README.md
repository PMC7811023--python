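# polarwrithe

Topology of open and closed ribbon and curve structures: the **polar writhe**
decomposition for DNA axes, biopolymers, elastic rods and flux ropes.

## The problem

For a closed ribbon the Călugăreanu theorem `Lk = Tw + Wr` splits the
conserved linking number into the twist of the ribbon about its axis and the
writhe (self-entanglement) of the axis itself — the basis of DNA supercoiling
analysis.  The classical Gauss-integral writhe, however, does not form an
invariant sum with the twist for *open* curves such as stretched DNA in
tweezer experiments, and the artificial end closures commonly used to work
around this contaminate the measurement.

The **polar writhe** `W_p` is the open-and-closed-curve writhe measure that
does form an invariant sum `Lk = Tw + W_p` (with `Lk` the net winding) when
the curve's ends are held between two horizontal planes.  It decomposes
exactly as

```
W_p = W_pl + W_pnl
```

* `W_pl` (**local**): split the curve at its turning points (where the
  vertical motion dz reverses) into z-monotone sections; per section,
  integrate the rotation of the unit tangent **T** about the vertical,

  `W_pl = (1/2π) Σ_i ∫ ẑ·(T_i × dT_i/dz) / (1 + |ẑ·T_i|) dz`.

  This measures "spring-like" helical coiling; right-handed coiling is
  positive.

* `W_pnl` (**non-local**): for every unordered pair of sections *i, j*
  sharing a mutual height range, measure the net rotation ΔΘ_ij of the
  horizontal vector joining them over that range,

  `W_pnl = Σ_{i<j} 2 σ_i σ_j ΔΘ_ij / 2π`,

  with σ = ±1 the up/down orientation of each section.  This counts loops,
  buckling and plectonemes: a plectonemed DNA axis has `|W_pnl|` roughly
  equal to its number of interwound loops.

For closed curves `W_p` equals the Gauss writhe `Wr` (computed here too, as
an exact solid-angle sum over segment pairs, for comparison and
cross-checking).  A self-crossing of the curve changes `W_p` by exactly ±2,
which turns the per-frame series over a trajectory into a topology-event
detector.  The extended measure `W_p*` — the polar writhe of the curve
prolonged by straight vertical end segments — additionally jumps by ±2 when
an interior loop passes directly over a curve end point ("over-the-top"
knotting moves) while staying flat otherwise, so comparing `W_p` and `W_p*`
series distinguishes self-crossings (both jump) from end passages (only
`W_p*` jumps).

The package also implements **WrLINE helical-axis extraction**: a DNA axis
built naively from base-pair C1' midpoints inherits the helical periodicity
of the backbone and spurious local writhe; WrLINE removes it by averaging
dinucleotide-step midpoints over exactly one helical turn, using local
base-pair step twists to size and fractionally weight the window.  Closed
minicircles and open helices (`autodelete` / `deleteatoms` end handling) are
both supported.

## Worked example

```python
import numpy as np
from polarwrithe import fixtures, polar_writhe

curve = fixtures.make_paraboloid(theta=np.pi, h=1.0, n=2000)
res = polar_writhe(curve)
print(f"sections={res.n_sections}  Wpl={res.wpl:+.4f}  "
      f"Wpnl={res.wpnl:+.4f}  Wp={res.wp:+.4f}")
```

prints

```
sections=2  Wpl=+0.5174  Wpnl=-1.0000  Wp=-0.4826
```

The twisted paraboloid (apex height 1, wound by θ = π) splits at its apex
into an upward and a downward section.  The two sections mutually wind by
−θ/π = −1 full turn (`Wpnl`), the helical coiling of the strands contributes
+0.52 turns of local writhe, and the total polar writhe is their sum.

The same decomposition from the shell, plus an axis extraction:

```sh
polarwrithe generate paraboloid --theta 3.14159265 --h 1 --n 2000 --out parab.xyz
polarwrithe writhe parab.xyz --measure wr --out series.tsv

polarwrithe generate ideal_duplex --n-bp 60 --twist-deg 36 --out dna.pdb
polarwrithe axis dna.pdb --mode autodelete --out axis.xyz
polarwrithe writhe axis.xyz
```

`series.tsv` holds one row per frame with columns `frame  Wpl  Wpnl  Wp
[Wr  Wp_star]`; a companion `.events.tsv` lists detected topological jumps
with a self-crossing / over-the-top classification.

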
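# Methods

## Dihedral computation

A torsion over four points p1..p4 is computed with the atan2 form
(y = (n1×n2)·b̂2, x = n1·n2, with n1 = b1×b2, n2 = b2×b3 the plane
normals of the two bonded triples), which is numerically stable at 0°
and 180°.  The sign follows the IUPAC convention: looking along the
central bond p2→p3, the angle is positive when the far bond is rotated
clockwise from the near one.  Results are normalised to (−180°, 180°]
with −180° reported as +180°, so the trans conformation has a single
representation.  Degenerate geometry (coincident points, collinear
triples, vector norms below 1e−10) yields an *undefined* angle, not an
exception: undefined angles are first-class values throughout, because a
partially defined element must still be filterable on its defined
positions.

Per residue, φ uses C of the preceding residue and ψ uses N of the
following one; both are undefined at chain termini and across breaks.
χ1 is N–CA–CB–γ with the γ atom chosen by the standard heavy-atom
convention (CG for most residues, CG1 for ile/val, OG for ser, OG1 for
thr, SG for cys; none for gly/ala).  Hydrogen positions are never used.

Two residues are continuous when the author numbering advances by one
(an insertion-code step at the same number also counts, since numbering
alone is unreliable where insertion codes appear) **and** the C–N
distance is ≤ 2.5 Å — generous against the ~1.33 Å peptide bond yet far
below any genuine gap.

## Structure reading

PDB parsing is delegated to gemmi and reduced to an ordered
chain/residue/atom model.  Only ATOM records of the 20 standard amino
acids are kept; waters, ligands and non-standard residues such as MSE
are dropped rather than translated, keeping the dihedral semantics
simple.  Chains split on chain identifier and on TER records (gemmi's
raw reader labels post-TER segments with a distinct subchain, which is
used directly; `setup_entities` is deliberately *not* called because its
entity heuristics would also split around skipped residues).  Alternate
locations resolve to the highest-occupancy atom, ties broken by the
lexicographically smallest altloc; out-of-range occupancies are clamped
to [0, 1] with a warning.  Multi-model files use model 1 only.

## Synthetic backbones

The fixture builder places N/CA/C sequentially by internal-to-Cartesian
(NeRF) construction using fixed ideal geometry: bonds N–CA 1.458 Å,
CA–C 1.525 Å, C–N 1.329 Å; angles N–CA–C 111.0°, CA–C–N 117.2°,
C–N–CA 121.7°; ω = 180° unless prescribed per bond.  Only the
dihedrals, not the covalent geometry, carry scientific meaning here, so
the bond constants are fixed conventions.  The first residue sits in a
canonical frame (N at the origin, CA on +x, C in the xy-plane) for
reproducibility.  CB is placed from the improper torsion N–C–CA–CB =
−122.6° (L-configuration); a γ atom can be placed at a prescribed χ1
for pucker tests.  Building then re-measuring recovers every interior
angle to better than 1e−6° (in practice ~1e−13°), which is the basis of
most downstream tests.

What the fixtures do **not** emulate: real side-chain rotamers beyond
χ1, non-ideal covalent geometry, thermal noise, missing atoms and
occupancy pathologies beyond what individual tests construct.  Passing
tests demonstrate the correctness of the computations and queries, not
the statistical properties of any curated structure collection; counts
obtained on user data depend entirely on that data.

## Ramachandran regions and pucker

The four default regions are rectangular φ/ψ boxes: αL (φ 20..140,
ψ −40..90), αR (φ −140..−20, ψ −90..40), βL (φ 20..160, ψ −180..−80),
βR (φ −160..−20, ψ 80..180), all in degrees.  Interval bounds are
half-open [min, max): "between" is ambiguous at the edges, and the
half-open convention makes the partition exact — the defaults are
pairwise disjoint, verified exhaustively on a 1° grid.  The table is a
user-editable TSV; a ζ region is left to the user because no agreed
rectangular bounds exist for it (a commented example line is shipped).

Proline pucker is classified from χ1 alone: DOWN for χ1 ∈ (0°, 60°], UP
for χ1 ∈ [−60°, 0°), undefined otherwise.  Which sign is called UP is a
declared convention, swappable via `down_positive`; the boundary is a
parameter (default 60°).

## Queries

**Templates** constrain φ and/or ψ per position; an element matches when
every constrained angle is defined and within the tolerance half-width
(default 40°) of its target by circular difference.  An undefined angle
at a constrained position never matches — conservatively, an unplotted
point cannot be selected.  χ1 is not constrainable by template; χ1
sub-populations are selected by marquee on the φχ1 plane instead.  The
shipped example templates put type I β-turn targets at the αR region
centre (−80°, −25°) for positions 2 and 3, and type II targets at the βR
centre (−90°, 130°) for position 2 and the αL centre (80°, 25°) for
position 3.

**Marquees** remap both coordinates into their 360° axis windows
(origin + (angle − origin) mod 360) and test a rectangle or an
inscribed ellipse, all boundaries inclusive — pixel-level semantics of
an interactive tool are unrecoverable, so a clean mathematical contract
is declared instead.  Inversion flips the decision only for fully
defined pairs.  A composite φψ+φχ1 selection is expressed as two
marquees combined by AND on their masks.

**Selection statistics** are the arithmetic means of the window
coordinates and the ordinary least-squares slope of y on x
(scipy linregress); the slope is undefined when all x coincide.  Means
are window-arithmetic, matching the display-coordinate behaviour of a
regression on a plot; a circular (resultant-direction) mean is offered
separately as an extension, undefined when the resultant length falls
below 1e−12.

## Element tables

The `#SMV1` format is this package's own: a header line with the version
and element length, a column-header line, then one tab-separated row per
element with provenance (source, chain, author start number + insertion
code), sequence, and φ/ψ/χ1 per position fixed to 2 decimals (`NA` for
undefined).  Two decimals exceed the experimental meaning of a dihedral
while keeping files compact and the writer canonical: write → read →
write is byte-identical, which the tests assert.  Malformed input is
rejected with the offending line number.

## Plotting

Plots are static matplotlib renderings: one panel per position (n−1 for
the anti-φψ view), axes defaulting to [−180°, 180°] except the χ1 axis
of the composite view, which defaults to [−120°, 240°) so the trans
rotamer is not split across the seam.  Selected points draw over
unselected ones; both colours are configurable.  Optional grey
constraint lines are rendered from a template file.  Point subsampling
keeps ⌈m/k⌉ points chosen by a seeded generator, making thinned plots
reproducible; the choice of uniform seeded subsampling is this package's
own.

## Problem sizes and numerical tolerances

The test suite and the acceptance script run entirely on generated
fixtures: 1000 random backbones for the round-trip check (tolerance
1e−6°), 10 000 random quadruples against an independent
projection-based torsion oracle (1e−9°), the full 361×361 1° grid for
the region partition, 1000 elements × 100 random marquees against a
brute-force selection oracle (exact agreement), and 50 chains with
planted overlapping type I and type II turns recovered by extract+match
(exact recovery, no spurious matches, noise placed ≥ 90° from every
template target).  These sizes keep the whole suite under ten seconds
on one CPU while exercising every code path at meaningful scale.

## Known limitations

- Only χ1 among side-chain torsions; no ω reporting (peptide-bond
  geometry is examined via the anti-φψ pairs instead).
- Region boxes are rectangles; density-based or residue-specific
  Ramachandran analysis is out of scope.
- No hydrogen-bond-based motif definitions.
- The reader accepts PDB only (no mmCIF) and keeps the first model of
  NMR-style files.
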
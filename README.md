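# ramaquery

Scriptable, reproducible queries on small peptide structural elements in
dihedral-angle space.

## The problem

Many recurring protein motifs — β-turns, 3₁₀ helices, polyproline
stretches, helix caps — are best characterised not by their Cartesian
coordinates but by the backbone dihedral angles (φ, ψ) and the first
side-chain torsion (χ1) of a handful of consecutive residues.  Analysing
such motifs means extracting every short contiguous peptide (an *n-mer*,
2–9 residues) from a set of structures, plotting per-position Ramachandran
distributions, and carving out conformational sub-populations: "the turns
whose position 4 is in the left-handed β region", "the prolines with the
UP ring pucker", "the elements with glycine at position 3".

Interactive tools do this with a mouse.  `ramaquery` re-casts the same
operations as deterministic, composable queries for structural biologists
who want the analysis in a script or a pipeline:

- **Extraction** — read PDB files, compute φ = C(i−1)–N–CA–C,
  ψ = N–CA–C–N(i+1) and χ1 = N–CA–CB–γ per residue, and slide an n-residue
  window over every chain, discarding windows that span a chain break.
- **Conformational classification** — named Ramachandran regions as
  half-open φ/ψ boxes (defaults: αR, αL, βR, βL), and proline ring pucker
  (UP/DOWN) from the sign of χ1.
- **Queries** — dihedral templates (per-position φ/ψ targets with a ±40°
  default half-width, compared by circular difference), sequence
  include/exclude patterns, and rectangular or elliptical *marquee*
  selections evaluated inside shiftable 360° axis windows so clusters that
  wrap around ±180° stay contiguous.  Every query returns a boolean mask;
  masks compose with ordinary logic.
- **Summaries and plots** — per-position composition, window-arithmetic
  means and OLS slope of a selection, anti-φψ pairs (ψᵢ vs φᵢ₊₁, the
  angles flanking the peptide bond), superimposed per-position layers, and
  static φψ / φχ1 / composite / anti-φψ scatter plots.
- **Synthetic fixtures** — an internal-coordinate (NeRF) builder that
  constructs backbones with any prescribed dihedrals and writes them as
  PDB, so the whole pipeline is testable without downloading structures.

## Worked example

Build a synthetic chain that carries two overlapping type I β-turns
followed by a type II turn, then recover them:

```sh
$ ramaquery extract --pdb turns.pdb --n 4 --out elements.tsv
INFO extract: 1 chains -> 6 4-mers

$ ramaquery match --elements elements.tsv \
      --template src/ramaquery/data/turn_type1.txt --out-mask type1.idx
INFO match: 6 elements -> 3 matched

$ cat type1.idx
0
1
2

$ ramaquery select --elements elements.tsv --pos 2 --shape ellipse \
      --x0 -140 --x1 -20 --y0 -90 --y1 40 --out-mask alphaR.idx
INFO select: 6 elements -> 4 selected

$ ramaquery stats --elements elements.tsv --pos 2 --mask alphaR.idx
-79.28	-25.52	1.0247	4
```

The three matched windows are the overlapping type I turns planted at
starts 1–3 (the template constrains positions 2 and 3 to the αR region
centre (−80°, −25°) within ±40°).  The elliptical marquee over the αR
region of position 2 picks up 4 elements; their mean (φ, ψ) of
(−79.3°, −25.5°) sits at the planted centre, and 1.02 is the OLS slope of
ψ on φ within the selection, with n = 4 points.  `ramaquery export`
writes the selected elements either with provenance
(`source  chain  start  seq`) or as plain sequence strings.

The element table (`elements.tsv`) is a versioned tab-separated text
format (`#SMV1`) that the tool both writes and reloads, so successive
refinements can be chained and audited; `ramaquery plot` and
`ramaquery superimpose` render the corresponding scatter views to
PNG/SVG.

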
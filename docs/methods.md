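# Methods

This note records the models, rules and numerical choices behind
`ligdiagram`, and what the synthetic test data does and does not
exercise.

## Structure model

PDB parsing is delegated to gemmi and flattened into a small explicit
model (atoms, LINK records, CONECT adjacency, HELIX/SHEET intervals).
Policies where the PDB format leaves room:

* only MODEL 1 of multi-model (NMR) files is read;
* only the first alternate location of each atom is kept;
* waters are recognised by residue name ∈ {HOH, WAT, DOD};
* elements missing from columns 77–78 are inferred from the atom name
  (PDB convention, two-letter metals included);
* hydrogens are parsed but ignored by all geometry — every criterion
  below is defined on heavy atoms.

Bond orders come from chemical-component definitions (mmCIF
`_chem_comp_atom`/`_chem_comp_bond` loops), read from a local directory;
orders are normalised to {single, double, triple, aromatic}.

## Ligand detection

Candidates are non-water HETATM residues. A HETATM residue flanked on
both sides (seq ± 1, same chain) by polymer residues is treated as a
modified polymer residue and skipped; such residues remain reachable
through the user-specified composite range selection. Candidates merge
into one composite ligand when joined by a LINK record, a CONECT
record, or an inter-residue heavy-atom pair closer than 1.9 Å (2.4 Å
when either atom is sulfur — covalent-distance surrogate chosen because
S–S and S–C bonds are longer). The merge is a union–find with sorted
tie-breaking, so the result is independent of record order. A
single-atom residue whose element is in {Na, K, Mg, Ca, Mn, Fe, Co,
Ni, Cu, Zn, Mo, Cd, Hg} is a metal-ion ligand. Polymer residues LINKed
to a ligand are recorded as explicit residues with their anchor atom
pair.

## Ring perception

SSSR is computed as an exact minimum cycle basis: Horton candidate
cycles (shortest-path cycles through every vertex–edge pair) are
scanned smallest-first with greedy GF(2) independence until
E − V + C cycles are found. Ties are broken by atom serial, so output
is deterministic. The test suite checks the result against an
independent brute-force enumerator (all simple cycles, greedy minimal
basis) and against the cyclomatic count on every fixture. Rings with
≥ 10 atoms are flagged macro-cycles: common small rings have ≤ 8
atoms, while cyclic-peptide backbones are well past 10, so the
threshold has a wide safe margin.

## Structural partition

Ring atoms belong to their rings (fusion atoms to several). Among the
remaining atoms, maximal simple paths of ≥ 3 non-terminal C/N/O/S atoms
become chains, extracted longest-first (exhaustive longest-path search
on the small chain subgraph, lexicographic tie-break). Degree-1 atoms
are terminal; whatever is left is isolated. Substituent heavy atoms of
degree 1 are therefore always "terminal", a classification the source
material leaves open; classifying by degree keeps the rule local and
deterministic.

## 2D layout

Drawing rules: acyclic bonds have a fixed drawn length (default 1.5 Å,
chosen so the 0.4 Å conflict threshold stays meaningful relative to
bond length); chain interior angles are exactly 120°; each n-ring is a
regular polygon (central angle 360°/n) with side equal to the drawn
bond length, or to the shared edge when fused onto an already placed
ring. Placement recurses over structural elements depth-first, starting
with the macro-cycle if present (drawn first as one regular polygon),
else the longest chain, else the largest ring; ties go to the element
containing the smallest atom serial. When no atom of an element is
fixed yet, its initial orientation comes from the orthographic
projection of the ligand's 3D coordinates onto their least-squares
plane (SVD), so free rings and chains keep the pose's orientation.
Chains are drawn as strict zig-zags: the first turn side follows the
projected conformation, then sides alternate. A single terminal atom
at a chain end continues the 120° zig-zag; multiple terminals on one
parent are spread evenly inside the largest free angular gap.

Conflicts are non-bonded atom pairs closer than 0.4 Å (strict
inequality; bonded pairs are excluded — a drawn bond shorter than the
threshold is not an overlap). Resolution flips acyclic branches: for
every bridge bond, the smaller side (excluding the axis atom) is
reflected across the bond axis — the 2D realisation of a 0↔180° torsion
flip. A flip is accepted only on a strict decrease of the conflict
count, which guarantees monotone progress; passes repeat until no flip
is accepted, with a hard limit of 10 passes as a termination guard.
Ring interiors are never altered because bridge bonds are by definition
outside every cycle.

Explicit residues are laid out independently by the same algorithm and
rigid-placed on a circle around their ligand anchor atom with radius
equal to the true 3D anchor distance. All 36 rotations in 10° steps
from a seeded random start are scored by (bond crossings + atom
overlaps), equally weighted since no relative weighting is specified;
the minimum wins, earliest candidate on ties.

## Interaction criteria

* Donor/acceptor typing from the component definition: O with an H →
  donor + acceptor; O without H (carbonyl, carboxylate, ether) →
  acceptor; N with ≥ 1 H → donor; N without H → acceptor; S → weak
  donor + acceptor, included. Without a definition (standard polymer
  residues, novel ligands), N and O are permissively both — the tool
  degrades gracefully rather than silently losing interactions.
* Hydrogen bond: cross (ligand/environment) donor–acceptor pair within
  3.3 Å for which **some** heavy neighbour *aa* of the acceptor gives
  ∠(D, A, aa) < 90° (existential reading); the smallest-angle *aa* is
  stored. The criterion is applied symmetrically — ligand as donor and
  ligand as acceptor. Acceptors with no heavy neighbour (isolated
  ions) are accepted on distance alone. The 3.3 Å default reuses the
  stated water radius; both cutoffs are user-adjustable.
* Nearby residue: minimum heavy-atom distance ≤ 4.0 Å (default),
  inclusive boundary; waters and ligand members excluded; sorted by
  distance.
* Water bridges: breadth-first enumeration of simple paths (no water
  revisited) over the water-oxygen contact graph with edges ≤ 3.3 Å,
  including terminal ligand–water and water–residue edges; paths carry
  1–4 waters. Bridges are always computed but rendered only on request.

## Scene assembly

All interaction types use one placement search: 72 candidates in 5°
steps on the circle of radius = real 3D distance around the ligand-side
anchor, scored lexicographically by (crossings, close contacts < 0.4 Å),
ties to the earliest candidate from the seeded random start. Hydrogen
bonds are placed first (lines cross most easily), then nearby-residue
ovals, then water bridges; earlier elements are obstacles for later
ones and are never moved. A nearby residue that already has a hydrogen
bond is drawn once, at the bond partner's position. Water bridges are
placed link by link with the same search. Ovals are approximated as
1.2 Å circles for obstacle scoring. Labels: centroid circle of radius
max distance + 0.5 Å, 36 candidates at 10°, minimising elements within
2 Å.

All random starts come from seeded generators (default seed 0), so the
whole pipeline — through to SVG bytes — is reproducible.

## Rendering

SVG is the single geometric source of truth, emitted with deterministic
ids and attribute order. PNG output rasterizes the same primitive
subset with Pillow; pixel dimensions scale linearly with DPI (base
96 dpi, 40 px/Å). Double/triple bonds are parallel strokes, aromatic
bonds a solid plus an inner dashed stroke; hydrogen bonds are blue
dashed lines or donor→acceptor arrows with optional distances;
water bridges are green with the water count labelled "n H2O"; nearby
residues are ovals labelled NAMESEQ(CHAIN). The Shapely-like amino-acid
palette is approximated from the RasMol documentation values and fully
overridable; every scheme maps unknown residue names to a fallback
colour.

## Synthetic data

The fixture generator emulates, with exactly controlled geometry, the
situations the pipeline must handle: linear chains, rings, fused
rings, a 10-residue cyclic pseudo-peptide closed by LINK records,
shell residues at exact minimum distances, donor/acceptor pairs at
prescribed distance and acceptor-neighbour angle, water chains of 1–6
bridging waters, and covalently LINKed residues. Critical placements
are axis-aligned so requested distances survive the PDB format's
3-decimal coordinate columns exactly; arbitrary angles are reproduced
to ~0.02° (the resolution the format permits). Pseudo-residues carry
3–5 heavy atoms plus component definitions whose hydrogens encode
donor roles.

What the fixtures do **not** model: realistic protein folds, crowded
binding sites with hundreds of nearby atoms, hydrogens, alternate
conformers beyond the first, or chemically complete amino acids.
Passing tests therefore demonstrate correctness of the geometric
criteria and search procedures, not aesthetic quality on dense real
sites, where layout clarity depends on the conflict-resolution
heuristics more than on any threshold.

## Problem sizes

Tests and the acceptance script run on fixtures of 2–70 atoms; ring
perception oracles use graphs of ≤ 14 atoms where brute-force cycle
enumeration is exact; bisections run to 1e-6 Å / 1e-4°. The whole
suite completes in a few seconds on one CPU.

## Known limitations

* mmCIF coordinate input, gzip, and live component-dictionary fetching
  are out of scope; component files are read from a local directory
  (the CLI's `--components`), which is also the hook for a user-side
  fetcher.
* Aromaticity is taken from component bond orders, never perceived.
* No hydrophobic-contact, π-stacking or salt-bridge special-casing;
  the interaction vocabulary is hydrogen bonds, nearby residues and
  water bridges.
* The GUI-style interactive repositioning of the original concept is
  replaced by programmatic equivalents (seeds, `--hide`, config).
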
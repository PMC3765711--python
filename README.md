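# ligdiagram

2D diagrams of biomacromolecule–ligand interactions, generated
automatically from PDB coordinate files.

Schematic 2D diagrams of a ligand in its binding site — the ligand drawn
with clean chemical-depiction geometry, surrounded by its hydrogen
bonds, nearby residues and water-mediated contacts — are a standard way
to communicate binding modes. `ligdiagram` produces such diagrams from
the command line or from Python, for structural biologists and
medicinal chemists who want publication-ready SVG/PNG figures or a
machine-readable interaction table from a crystal structure.

## What it computes

**Ligand detection.** HETATM residues (excluding waters) are candidate
ligands; residues joined by LINK/CONECT records or heavy-atom pairs at
covalent distance (< 1.9 Å, 2.4 Å involving S) merge into composite
ligands, so multi-residue ligands such as cyclic peptides come out as a
single entity. Lone atoms of metallic elements are metal-ion ligands.
Polymer residues covalently LINKed to the ligand ("explicit residues")
are drawn with it.

**Ligand layout.** The ligand is an undirected labelled graph (nodes =
heavy atoms, edges = bonds, with orders taken from chemical-component
definitions). It is partitioned into structural elements: rings (the
smallest set of smallest rings, i.e. a minimum cycle basis), chains of
≥ 3 connected non-terminal C/N/O/S atoms, terminal atoms and isolated
atoms. Elements are placed recursively — macro-cycle (ring of ≥ 10
atoms) first when present, else the longest chain, else the largest
ring — with interior chain angles of exactly 120°, every *n*-ring a
regular polygon with central angle 360°/*n*, and the orthographic
projection of the 3D conformation supplying initial orientations.
Atom clashes (two atoms closer than 0.4 Å) are reduced by flipping
acyclic branches across their bond axis (a 0 → 180° torsion flip in
2D), accepting only flips that strictly reduce the conflict count.

**Interaction detection** (heavy atoms only):

* *Hydrogen bond*: donor D and acceptor A within 3.3 Å (configurable)
  such that some neighbour *aa* of the acceptor gives
  ∠(D, A, aa) < 90°.
* *Nearby residue*: polymer residue with ≥ 1 heavy atom within 4 Å
  (default) of any ligand atom, reported with its minimum distance.
* *Water bridge*: a simple path from a ligand donor/acceptor to a
  residue donor/acceptor through 1–4 water oxygens, every step ≤ 3.3 Å.

**Placement.** Each interacting element sits on a circle around its
ligand-side anchor whose radius is the true 3D distance; candidate
positions every 5° are scored by bond crossings, ties broken by close
contacts (< 0.4 Å), starting from a seeded random angle. Hydrogen
bonds are placed first, then residue ovals, then water bridges.
Residue name labels run the same search on a circle of radius
max(distance(centroid, atom)) + 0.5 Å in 10° steps, minimising diagram
elements within 2 Å.

**Output.** Deterministic SVG (canonical), PNG at configurable DPI, and
a flat tab-separated interaction table. Oval colour schemes:
hydrophobicity, Shapely-like amino-acid colours, charge, or secondary
structure from HELIX/SHEET records.

## Worked example

The bundled fixture generator builds a synthetic binding site around a
propanol-like ligand — one ALA shell residue with its closest atom at
exactly 3.9 Å, a LYS donor 3.0 Å from the ligand hydroxyl at a 60°
acceptor-neighbour angle, two water bridges, and a covalently LINKed
CYS:

```sh
ligdiagram fixtures make --kind full_site --out demo/
ligdiagram list demo/full_site.pdb
```

```
ligand  SLG A:401  (4 atoms)  [explicit: CYS1(C)]
```

One ligand is detected; the CYS connected through the LINK record is
reported as an explicit residue, not a ligand member.

```sh
ligdiagram interactions demo/full_site.pdb
```

```
type	ligand_atom	partner	chain	distance_A
hydrogen_bond	O1	LYS1 NZ	D	3.00
nearby_residue	C1	CYS1 SG	C	1.80
nearby_residue	C3	LYS1 NZ	D	2.60
nearby_residue	C1	ALA1 CB	E	3.90
water_bridge	O1	SER1 OG	S	2.80,2.80 (total 5.60)
water_bridge	O1	SER2 OG	S	2.80,2.80,2.80 (total 8.40)
```

The hydrogen bond is the designed LYS NZ → ligand O1 pair at 3.00 Å
(accepted because the 60° angle is below the 90° bound); the ALA shell
appears at exactly its constructed 3.90 Å minimum distance; the two
water bridges report their per-step and total distances. Drawing the
diagram, with water bridges shown and hydrogen bonds as arrows with
distances:

```sh
ligdiagram draw demo/full_site.pdb --components demo/ \
    --waters --arrows --distances --out demo/site.svg
```

`--format png` rasterizes the same geometry; `--color-scheme charge`,
`--plain`, `--atom-labels`, `--hide RES`, `--residue-cutoff`,
`--hbond-cutoff` and `--seed` customise the result. Repeating
`--ligand CHAIN:SEQ[-SEQ]` draws several diagrams to numbered files;
a `CHAIN:SEQ-SEQ` range selects a user-defined composite ligand.

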
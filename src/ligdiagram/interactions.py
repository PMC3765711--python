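"""Geometric detection of ligand-environment interactions.

Three interaction classes are detected, all on heavy atoms only:

* **Hydrogen bonds** — for every cross (ligand/environment)
  donor-acceptor pair within the distance cutoff, the bond is accepted
  when some neighbour ``aa`` of the acceptor subtends an angle
  (D, A, aa) below 90 degrees; the criterion is applied in both
  directions (ligand donor or ligand acceptor).
* **Water-mediated hydrogen bonds** — simple paths from a ligand
  donor/acceptor atom to a residue donor/acceptor atom through 1 to 4
  bridging water oxygens, every step within the water radius (3.3 A).
* **Nearby residues** — biomacromolecule residues with at least one
  heavy atom within the residue cutoff (4 A by default) of any ligand
  atom, reported with their minimum distance.

Donor/acceptor roles come from the residue's component definition when
available (hydroxyl O: donor+acceptor; carbonyl/carboxylate O: acceptor;
N with hydrogens: donor; N without: acceptor; S: both, weakly).  Without
a component definition N and O are treated permissively as both.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx
import numpy as np

from ._geom import angle_deg
from .ligand_detect import LigandInstance, _covalent_cut
from .pdb_io import Atom, ComponentDefinition, Structure


@dataclass
class InteractionConfig:
    residue_cutoff: float = 4.0      # nearby-residue cutoff, Angstrom
    hbond_cutoff: float = 3.3        # donor-acceptor distance cutoff
    water_radius: float = 3.3        # max per-step water path distance
    max_bridge_waters: int = 4
    hbond_angle_max: float = 90.0    # (D, A, aa) acceptance bound, degrees

    def __post_init__(self) -> None:
        for name in ("residue_cutoff", "hbond_cutoff", "water_radius"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.max_bridge_waters < 1:
            raise ValueError("max_bridge_waters must be >= 1")


@dataclass
class HydrogenBond:
    donor: Atom
    acceptor: Atom
    acceptor_neighbour: Atom | None
    distance: float
    angle: float | None
    ligand_side: str  # 'donor' | 'acceptor'

    @property
    def ligand_atom(self) -> Atom:
        return self.donor if self.ligand_side == "donor" else self.acceptor

    @property
    def partner_atom(self) -> Atom:
        return self.acceptor if self.ligand_side == "donor" else self.donor


@dataclass
class WaterBridge:
    ligand_atom: Atom
    residue_atom: Atom
    waters: list[Atom]
    step_distances: list[float]

    @property
    def total_distance(self) -> float:
        return float(sum(self.step_distances))


@dataclass
class NearbyResidue:
    residue_id: tuple[str, str, int]
    min_distance: float
    closest_atom_pair: tuple[Atom, Atom]  # (ligand atom, residue atom)


@dataclass
class InteractionSet:
    hbonds: list[HydrogenBond] = field(default_factory=list)
    water_bridges: list[WaterBridge] = field(default_factory=list)
    nearby_residues: list[NearbyResidue] = field(default_factory=list)


# --------------------------------------------------------------- helpers

def environment_atoms(structure: Structure,
                      ligand: LigandInstance) -> list[Atom]:
    """Heavy biomacromolecule atoms: not ligand, not water, not hydrogen."""
    member = ligand.atom_serials()
    return [a for a in structure.atoms
            if a.serial not in member and not a.is_water
            and not a.is_hydrogen and not a.is_het]


def water_oxygens(structure: Structure) -> list[Atom]:
    return [a for a in structure.atoms if a.is_water and a.element == "O"]


def _residue_neighbours(atoms: list[Atom]) -> dict[int, list[Atom]]:
    """Intra-residue covalent neighbours inferred from distances."""
    out: dict[int, list[Atom]] = {a.serial: [] for a in atoms}
    by_res: dict[tuple, list[Atom]] = {}
    for a in atoms:
        by_res.setdefault(a.residue_id, []).append(a)
    for group in by_res.values():
        for a, b in combinations(group, 2):
            if np.linalg.norm(a.coords - b.coords) < _covalent_cut(
                    a.element, b.element):
                out[a.serial].append(b)
                out[b.serial].append(a)
    return out


# ---------------------------------------------------- donors / acceptors

def assign_donors_acceptors(
        atoms: list[Atom],
        components: dict[str, ComponentDefinition] | None = None,
) -> dict[int, tuple[bool, bool]]:
    """Flag heavy atoms as hydrogen-bond (donor, acceptor).

    Only N, O and S can carry a flag.  The component definition of the
    atom's residue decides the role; with no definition available the
    assignment is permissive (both roles) so that novel ligands and
    standard polymer residues degrade gracefully.
    """
    components = components or {}
    flags: dict[int, tuple[bool, bool]] = {}
    for a in atoms:
        if a.is_hydrogen or a.element not in ("N", "O", "S"):
            flags[a.serial] = (False, False)
            continue
        comp = components.get(a.residue_name)
        if comp is None or a.name not in comp.atoms:
            flags[a.serial] = (a.element in ("N", "O", "S"), True)
            continue
        n_h = comp.hydrogen_count(a.name)
        if a.element == "O":
            flags[a.serial] = (n_h > 0, True)
        elif a.element == "N":
            flags[a.serial] = (n_h > 0, n_h == 0)
        else:  # S: weak donor/acceptor, included
            flags[a.serial] = (True, True)
    return flags


# ------------------------------------------------------- nearby residues

def find_nearby_residues(ligand: LigandInstance, structure: Structure,
                         config: InteractionConfig | None = None,
                         ) -> list[NearbyResidue]:
    """Polymer residues with a heavy atom within the cutoff of the ligand."""
    config = config or InteractionConfig()
    env = environment_atoms(structure, ligand)
    lig = [a for a in ligand.atoms if not a.is_hydrogen]
    if not env or not lig:
        return []
    lig_pts = np.array([a.coords for a in lig])
    best: dict[tuple, tuple[float, Atom, Atom]] = {}
    for a in env:
        d = np.linalg.norm(lig_pts - a.coords, axis=1)
        i = int(np.argmin(d))
        dmin = float(d[i])
        cur = best.get(a.residue_id)
        if cur is None or dmin < cur[0]:
            best[a.residue_id] = (dmin, lig[i], a)
    out = [NearbyResidue(residue_id=rid, min_distance=d,
                         closest_atom_pair=(la, ra))
           for rid, (d, la, ra) in best.items()
           if d <= config.residue_cutoff]
    out.sort(key=lambda r: (r.min_distance, r.residue_id))
    return out


# --------------------------------------------------------- hydrogen bonds

def find_hydrogen_bonds(ligand_atoms: list[Atom],
                        env_atoms: list[Atom],
                        components: dict[str, ComponentDefinition] | None = None,
                        config: InteractionConfig | None = None,
                        ligand_neighbours: dict[int, list[Atom]] | None = None,
                        ) -> list[HydrogenBond]:
    """Donor/acceptor pairs across the ligand/environment boundary.

    A pair within the distance cutoff becomes a bond when at least one
    heavy neighbour ``aa`` of the acceptor gives angle(D, A, aa) below
    the angular bound; the neighbour with the smallest angle is stored.
    Acceptors with no heavy neighbour (isolated ions) are accepted on
    distance alone.
    """
    config = config or InteractionConfig()
    lig = [a for a in ligand_atoms if not a.is_hydrogen]
    env = [a for a in env_atoms if not a.is_hydrogen and not a.is_water]
    flags = assign_donors_acceptors(lig + env, components)
    neigh = _residue_neighbours(env)
    if ligand_neighbours is not None:
        neigh.update({s: list(v) for s, v in ligand_neighbours.items()})
    else:
        neigh.update(_residue_neighbours(lig))

    out: list[HydrogenBond] = []
    seen: set[tuple[int, int]] = set()
    for ligand_side, donors, acceptors in (
            ("donor", lig, env), ("acceptor", env, lig)):
        for d_atom in donors:
            if not flags[d_atom.serial][0]:
                continue
            for a_atom in acceptors:
                if not flags[a_atom.serial][1]:
                    continue
                key = (d_atom.serial, a_atom.serial)
                if key in seen:
                    continue
                dist = float(np.linalg.norm(d_atom.coords - a_atom.coords))
                if dist > config.hbond_cutoff:
                    continue
                aas = neigh.get(a_atom.serial, [])
                best_aa, best_angle = None, None
                for aa in aas:
                    ang = angle_deg(d_atom.coords, a_atom.coords, aa.coords)
                    if ang < config.hbond_angle_max and (
                            best_angle is None or ang < best_angle):
                        best_aa, best_angle = aa, ang
                if aas and best_aa is None:
                    continue
                seen.add(key)
                out.append(HydrogenBond(
                    donor=d_atom, acceptor=a_atom,
                    acceptor_neighbour=best_aa, distance=dist,
                    angle=best_angle, ligand_side=ligand_side))
    out.sort(key=lambda h: (h.distance, h.donor.serial, h.acceptor.serial))
    return out


# ---------------------------------------------------------- water bridges

def find_water_bridges(ligand_atoms: list[Atom],
                       env_atoms: list[Atom],
                       waters: list[Atom],
                       components: dict[str, ComponentDefinition] | None = None,
                       config: InteractionConfig | None = None,
                       ) -> list[WaterBridge]:
    """Simple water paths joining ligand and residue donor/acceptor atoms.

    Edges of the search graph are water-water, ligand-water and
    water-residue pairs within the water radius; returned paths contain
    between one and ``max_bridge_waters`` distinct waters, sorted per
    (ligand atom, residue atom) pair by length then total distance.
    """
    config = config or InteractionConfig()
    lig = [a for a in ligand_atoms if not a.is_hydrogen]
    env = [a for a in env_atoms if not a.is_hydrogen and not a.is_water]
    flags = assign_donors_acceptors(lig + env, components)
    lig_da = [a for a in lig if any(flags[a.serial])]
    env_da = [a for a in env if any(flags[a.serial])]
    if not (lig_da and env_da and waters):
        return []

    r = config.water_radius
    wg = nx.Graph()
    for w in waters:
        wg.add_node(("w", w.serial), atom=w)
    for w1, w2 in combinations(waters, 2):
        d = float(np.linalg.norm(w1.coords - w2.coords))
        if d <= r:
            wg.add_edge(("w", w1.serial), ("w", w2.serial), dist=d)
    for a in lig_da:
        for w in waters:
            d = float(np.linalg.norm(a.coords - w.coords))
            if d <= r:
                wg.add_edge(("l", a.serial), ("w", w.serial), dist=d)
                wg.nodes[("l", a.serial)]["atom"] = a
    for a in env_da:
        for w in waters:
            d = float(np.linalg.norm(a.coords - w.coords))
            if d <= r:
                wg.add_edge(("r", a.serial), ("w", w.serial), dist=d)
                wg.nodes[("r", a.serial)]["atom"] = a

    out: list[WaterBridge] = []
    for lnode in sorted(n for n in wg.nodes if n[0] == "l"):
        for rnode in sorted(n for n in wg.nodes if n[0] == "r"):
            for path in nx.all_simple_paths(
                    wg, lnode, rnode, cutoff=config.max_bridge_waters + 1):
                inner = path[1:-1]
                if not inner or any(n[0] != "w" for n in inner):
                    continue
                steps = [wg.edges[path[i], path[i + 1]]["dist"]
                         for i in range(len(path) - 1)]
                out.append(WaterBridge(
                    ligand_atom=wg.nodes[lnode]["atom"],
                    residue_atom=wg.nodes[rnode]["atom"],
                    waters=[wg.nodes[n]["atom"] for n in inner],
                    step_distances=steps))
    out.sort(key=lambda b: (b.ligand_atom.serial, b.residue_atom.serial,
                            len(b.waters), b.total_distance))
    return out


# ------------------------------------------------------------ full sweep

def detect_interactions(ligand: LigandInstance, structure: Structure,
                        components: dict[str, ComponentDefinition] | None = None,
                        config: InteractionConfig | None = None,
                        ) -> InteractionSet:
    """Run all three detectors for one ligand."""
    config = config or InteractionConfig()
    env = environment_atoms(structure, ligand)
    lig = [a for a in ligand.atoms if not a.is_hydrogen]
    return InteractionSet(
        hbonds=find_hydrogen_bonds(lig, env, components, config),
        water_bridges=find_water_bridges(lig, env, water_oxygens(structure),
                                         components, config),
        nearby_residues=find_nearby_residues(ligand, structure, config),
    )
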
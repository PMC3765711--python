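"""Ligand graph construction, ring perception and structural partition.

A ligand is an undirected labelled graph: nodes are heavy atoms (keyed by
serial), edges are chemical bonds carrying an order.  Intra-residue bonds
and orders come from the residue's chemical-component definition, mapped
by atom name, with an element-labelled subgraph-isomorphism fallback for
renamed atoms; inter-residue bonds come from LINK/CONECT records or
covalent-distance inference and are single bonds.

Ring perception computes the smallest set of smallest rings (SSSR), i.e.
a minimum cycle basis, from the Horton candidate set with greedy GF(2)
independence selection — exact and deterministic (ties broken by atom
serial).  Rings of at least ``MACROCYCLE_SIZE`` atoms are macro-cycles and
are given priority during 2D layout.

The partition classifies every ligand atom as ring member, chain member
(maximal paths of >=3 connected non-terminal C/N/O/S atoms outside
rings), terminal (degree 1) or isolated.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import networkx as nx
import numpy as np

from .ligand_detect import LigandInstance, _covalent_cut
from .pdb_io import Atom, ComponentDefinition, Structure

MACROCYCLE_SIZE = 10
CHAIN_ELEMENTS = frozenset({"C", "N", "O", "S"})


class GraphBuildError(ValueError):
    """Raised when a residue cannot be mapped onto a component."""


@dataclass
class Ring:
    atoms: list[int]            # serials in cycle order
    is_macrocycle: bool = False

    def __len__(self) -> int:
        return len(self.atoms)

    def edges(self) -> list[frozenset[int]]:
        n = len(self.atoms)
        return [frozenset((self.atoms[i], self.atoms[(i + 1) % n]))
                for i in range(n)]


@dataclass
class StructuralElement:
    kind: str                   # ring | chain | isolated_atom | terminal_atom
    atoms: list[int]            # serials, ordered
    is_macrocycle: bool = False


class MolecularGraph:
    """Thin wrapper around an :class:`networkx.Graph` of one ligand."""

    def __init__(self) -> None:
        self.g = nx.Graph()
        self._atoms: dict[int, Atom] = {}

    def add_atom(self, atom: Atom) -> None:
        self._atoms[atom.serial] = atom
        self.g.add_node(atom.serial, name=atom.name, element=atom.element)

    def add_bond(self, s1: int, s2: int, order: str) -> None:
        if s1 == s2:
            raise GraphBuildError(f"self-loop on atom serial {s1}")
        self.g.add_edge(s1, s2, order=order)

    def atom(self, serial: int) -> Atom:
        return self._atoms[serial]

    def atoms(self) -> list[Atom]:
        return [self._atoms[s] for s in sorted(self._atoms)]

    def neighbors(self, serial: int) -> list[int]:
        return sorted(self.g.neighbors(serial))

    def degree(self, serial: int) -> int:
        return self.g.degree[serial]

    def bond_order(self, s1: int, s2: int) -> str:
        return self.g.edges[s1, s2]["order"]

    def has_bond(self, s1: int, s2: int) -> bool:
        return self.g.has_edge(s1, s2)

    @property
    def n_atoms(self) -> int:
        return self.g.number_of_nodes()

    @property
    def n_bonds(self) -> int:
        return self.g.number_of_edges()


# ----------------------------------------------------------- graph build

def _distance_bonds(atoms: list[Atom]) -> list[tuple[int, int]]:
    """Covalent bonds inferred from interatomic distances."""
    out = []
    for a, b in combinations(atoms, 2):
        cut = _covalent_cut(a.element, b.element)
        if np.linalg.norm(a.coords - b.coords) < cut:
            out.append((a.serial, b.serial))
    return out


def _map_residue_to_component(atoms: list[Atom],
                              comp: ComponentDefinition) -> dict[str, int]:
    """Map component atom names to atom serials.

    Tries the direct name mapping first; on failure (renamed atoms) falls
    back to an element-labelled subgraph isomorphism between the
    component's heavy-atom graph and the residue's distance-bond graph.
    """
    heavy = comp.heavy_atoms()
    by_name = {a.name: a for a in atoms}
    if all(a.name in heavy for a in atoms):
        return {a.name: a.serial for a in atoms}

    comp_g = nx.Graph()
    for name, el in heavy.items():
        comp_g.add_node(name, element=el)
    for a1, a2, _ in comp.heavy_bonds():
        comp_g.add_edge(a1, a2)
    res_g = nx.Graph()
    for a in atoms:
        res_g.add_node(a.serial, element=a.element)
    for s1, s2 in _distance_bonds(atoms):
        res_g.add_edge(s1, s2)

    gm = nx.algorithms.isomorphism.GraphMatcher(
        comp_g, res_g,
        node_match=lambda c, r: c["element"] == r["element"])
    # residue may be a sub-structure of the full component (missing atoms)
    for mapping in gm.subgraph_monomorphisms_iter():
        if len(mapping) == len(atoms):
            return dict(sorted(mapping.items()))
    raise GraphBuildError(
        f"cannot map residue {atoms[0].residue_id} onto component "
        f"{comp.comp_id}")


def build_graph(ligand: LigandInstance,
                components: dict[str, ComponentDefinition] | None = None,
                structure: Structure | None = None,
                allow_distance_fallback: bool = True) -> MolecularGraph:
    """Build the labelled bond graph of one ligand."""
    components = components or {}
    mg = MolecularGraph()
    heavy_atoms = [a for a in ligand.atoms if not a.is_hydrogen]
    for a in heavy_atoms:
        mg.add_atom(a)

    residues: dict[tuple, list[Atom]] = {}
    for a in heavy_atoms:
        residues.setdefault(a.residue_id, []).append(a)

    for rid, atoms in residues.items():
        comp = components.get(rid[0])
        if comp is None:
            if not allow_distance_fallback:
                raise GraphBuildError(
                    f"no component definition for residue {rid[0]!r}")
            for s1, s2 in _distance_bonds(atoms):
                mg.add_bond(s1, s2, "single")
            continue
        name_to_serial = _map_residue_to_component(atoms, comp)
        for a1, a2, order in comp.heavy_bonds():
            if a1 in name_to_serial and a2 in name_to_serial:
                mg.add_bond(name_to_serial[a1], name_to_serial[a2], order)

    member = ligand.atom_serials()
    if structure is not None:
        for link in structure.links:
            a1 = structure.find_link_atom(link.atom1)
            a2 = structure.find_link_atom(link.atom2)
            if (a1 is not None and a2 is not None
                    and a1.serial in member and a2.serial in member
                    and not mg.has_bond(a1.serial, a2.serial)):
                mg.add_bond(a1.serial, a2.serial, "single")
        for serial, partners in structure.conect.items():
            for p in partners:
                if (serial < p and serial in member and p in member
                        and not mg.has_bond(serial, p)):
                    mg.add_bond(serial, p, "single")
    # inter-residue covalent inference (distinct residues only)
    if len(residues) > 1:
        for a, b in combinations(heavy_atoms, 2):
            if a.residue_id == b.residue_id or mg.has_bond(a.serial, b.serial):
                continue
            if np.linalg.norm(a.coords - b.coords) < _covalent_cut(
                    a.element, b.element):
                mg.add_bond(a.serial, b.serial, "single")
    return mg


def graph_from_atoms(atoms: list[Atom]) -> MolecularGraph:
    """Distance-bonded graph of a free-standing atom group (all orders
    single); used for explicit residues, which have no component file."""
    mg = MolecularGraph()
    for a in atoms:
        if not a.is_hydrogen:
            mg.add_atom(a)
    for s1, s2 in _distance_bonds([a for a in atoms if not a.is_hydrogen]):
        mg.add_bond(s1, s2, "single")
    return mg


# ------------------------------------------------------------------ SSSR

def _edge_index(graph: nx.Graph) -> dict[frozenset, int]:
    return {frozenset(e): i for i, e in enumerate(sorted(
        (tuple(sorted(e)) for e in graph.edges)))}


def _cycle_vector(cycle: list[int], eidx: dict[frozenset, int]) -> int:
    v = 0
    n = len(cycle)
    for i in range(n):
        v ^= 1 << eidx[frozenset((cycle[i], cycle[(i + 1) % n]))]
    return v


def _canonical_cycle(cycle: list[int]) -> tuple[int, ...]:
    """Rotate/reflect so the cycle starts at its smallest serial and walks
    toward its smaller neighbour."""
    n = len(cycle)
    i = cycle.index(min(cycle))
    fwd = [cycle[(i + k) % n] for k in range(n)]
    rev = [cycle[(i - k) % n] for k in range(n)]
    return tuple(fwd if fwd[1] <= rev[1] else rev)


def _horton_candidates(graph: nx.Graph) -> list[tuple[int, ...]]:
    """Horton candidate cycles: for every node x and edge (u, v), the cycle
    SP(x,u) + (u,v) + SP(v,x) when the two shortest paths are disjoint."""
    sp = dict(nx.all_pairs_shortest_path(graph))
    seen: set[tuple[int, ...]] = set()
    out = []
    edges = sorted(tuple(sorted(e)) for e in graph.edges)
    for x in sorted(graph.nodes):
        paths = sp[x]
        for u, v in edges:
            if u not in paths or v not in paths:
                continue
            pu, pv = paths[u], paths[v]
            if set(pu) & set(pv) != {x}:
                continue
            cycle = pu + pv[::-1][:-1]
            if len(cycle) < 3:
                continue
            canon = _canonical_cycle(cycle)
            if canon not in seen:
                seen.add(canon)
                out.append(canon)
    return out


def perceive_sssr(graph: MolecularGraph | nx.Graph) -> list[Ring]:
    """Smallest set of smallest rings as an exact minimum cycle basis.

    Returns E - V + C rings, ordered by (size, member serials); candidate
    cycles are considered smallest-first with ties broken by serial so the
    result is deterministic.
    """
    g = graph.g if isinstance(graph, MolecularGraph) else graph
    n_rings = (g.number_of_edges() - g.number_of_nodes()
               + nx.number_connected_components(g))
    if n_rings <= 0:
        return []
    eidx = _edge_index(g)
    candidates = _horton_candidates(g)
    candidates.sort(key=lambda c: (len(c), c))
    basis: list[tuple[int, ...]] = []
    vectors: list[int] = []  # row-reduced GF(2) vectors
    for cyc in candidates:
        v = _cycle_vector(list(cyc), eidx)
        for row in vectors:
            v = min(v, v ^ row, key=int.bit_count) if False else v
        # Gaussian elimination by leading bit
        w = v
        for row in vectors:
            if w ^ row < w:
                w ^= row
        if w:
            vectors.append(w)
            vectors.sort(reverse=True)
            basis.append(cyc)
            if len(basis) == n_rings:
                break
    rings = [Ring(atoms=list(c)) for c in basis]
    rings.sort(key=lambda r: (len(r.atoms), sorted(r.atoms)))
    return rings


def detect_macrocycles(rings: list[Ring],
                       threshold: int = MACROCYCLE_SIZE) -> list[Ring]:
    """Flag rings of ``threshold`` or more atoms as macro-cycles."""
    for r in rings:
        r.is_macrocycle = len(r.atoms) >= threshold
    return rings


# -------------------------------------------------------------- partition

def _longest_path(g: nx.Graph) -> list[int]:
    """Longest simple path by exhaustive DFS (chain subgraphs are tiny);
    deterministic: prefers longer paths, then lexicographically smaller."""
    best: list[int] = []

    def dfs(path: list[int], visited: set[int]) -> None:
        nonlocal best
        last = path[-1]
        extended = False
        for nb in sorted(g.neighbors(last)):
            if nb not in visited:
                extended = True
                visited.add(nb)
                path.append(nb)
                dfs(path, visited)
                path.pop()
                visited.remove(nb)
        if not extended:
            cand = path[:]
            if (len(cand), [-x for x in cand]) > (len(best), [-x for x in best]):
                if len(cand) > len(best) or (len(cand) == len(best)
                                             and cand < best):
                    best = cand
            elif not best:
                best = cand
        if len(path) > len(best):
            best = path[:]

    for start in sorted(g.nodes):
        dfs([start], {start})
    return best


def partition(graph: MolecularGraph, rings: list[Ring]) -> list[StructuralElement]:
    """Partition ligand atoms into rings, chains, terminal and isolated
    atoms.  Ring-fusion atoms appear in several ring elements; every other
    atom appears exactly once."""
    g = graph.g
    elements: list[StructuralElement] = []
    ring_atoms: set[int] = set()
    for r in rings:
        elements.append(StructuralElement(kind="ring", atoms=list(r.atoms),
                                          is_macrocycle=r.is_macrocycle))
        ring_atoms.update(r.atoms)

    terminal = {s for s in g.nodes if g.degree[s] == 1 and s not in ring_atoms}
    chain_pool = {s for s in g.nodes
                  if s not in ring_atoms and s not in terminal
                  and graph.atom(s).element in CHAIN_ELEMENTS}

    sub = g.subgraph(chain_pool).copy()
    while sub.number_of_nodes() >= 3:
        path = _longest_path(sub)
        if len(path) < 3:
            break
        elements.append(StructuralElement(kind="chain", atoms=path))
        sub.remove_nodes_from(path)

    covered = ring_atoms | terminal | {
        a for e in elements if e.kind == "chain" for a in e.atoms}
    for s in sorted(g.nodes):
        if s not in covered:
            elements.append(StructuralElement(kind="isolated_atom", atoms=[s]))
    for s in sorted(terminal):
        elements.append(StructuralElement(kind="terminal_atom", atoms=[s]))
    return elements
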
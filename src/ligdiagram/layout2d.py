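"""2D coordinate generation for ligand atoms.

The drawing rules follow standard chemical-depiction conventions: interior
angles in acyclic chains are exactly 120 degrees, every ring is drawn as a
regular polygon (central angle 360/n), acyclic bonds have a fixed drawn
length, and where nothing is fixed yet the orthographic projection of the
3D conformation onto its least-squares plane supplies the initial
orientation, so the diagram stays recognisably similar to the crystal
pose.

Elements are placed recursively, macro-cycle first when present, else the
longest chain, else the largest ring.  Afterwards, overlaps (two atoms
closer than the conflict distance) are reduced by flipping acyclic
branches across their bond axis — the 2D realisation of a 0-to-180 degree
torsion flip — accepting only flips that strictly reduce the conflict
count.  Explicit (covalently linked) residues are laid out independently
and rigid-placed on a circle whose radius is the true 3D anchor distance,
scanning candidate rotations in 10-degree steps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from ._geom import (best_fit_plane_projection, largest_gap_directions,
                    reflect_point, rotate2d, segments_cross, unit)
from .molgraph import MolecularGraph, StructuralElement


@dataclass
class LayoutConfig:
    bond_length: float = 1.5          # drawn acyclic bond length, Angstrom
    chain_angle: float = 120.0        # interior angle in chains, degrees
    conflict_distance: float = 0.4    # two atoms closer than this conflict
    explicit_residue_step: float = 10.0  # circle-search step, degrees
    flip_passes: int = 10             # conflict-resolution pass limit
    seed: int = 0

    def __post_init__(self) -> None:
        if self.bond_length <= 0:
            raise ValueError("bond_length must be positive")
        if not 0 < self.conflict_distance < self.bond_length:
            raise ValueError("conflict_distance must lie in (0, bond_length)")


@dataclass
class Layout2D:
    positions: dict[int, np.ndarray] = field(default_factory=dict)

    def copy(self) -> "Layout2D":
        return Layout2D({s: p.copy() for s, p in self.positions.items()})

    def pos(self, serial: int) -> np.ndarray:
        return self.positions[serial]

    def array(self, serials: list[int]) -> np.ndarray:
        return np.array([self.positions[s] for s in serials])


@dataclass
class PlacementCandidate:
    angle: float
    position: np.ndarray
    score: tuple


@dataclass
class ExplicitPlacement:
    """Search record for one explicit-residue placement."""
    chosen_angle: float
    chosen_score: tuple
    candidates: list[PlacementCandidate]


# ------------------------------------------------------------- main layout

def layout_ligand(graph: MolecularGraph, elements: list[StructuralElement],
                  config: LayoutConfig | None = None) -> Layout2D:
    """Compute 2D coordinates for all ligand atoms."""
    config = config or LayoutConfig()
    g = graph.g
    serials = sorted(g.nodes)
    coords3 = np.array([graph.atom(s).coords for s in serials])
    proj_arr = best_fit_plane_projection(coords3) if len(serials) > 1 \
        else np.zeros((1, 2))
    proj = {s: proj_arr[i] for i, s in enumerate(serials)}

    layout = Layout2D()
    components = [sorted(c) for c in nx.connected_components(g)]
    components.sort(key=lambda c: c[0])
    offset = 0.0
    for comp in components:
        comp_set = set(comp)
        comp_elements = [e for e in elements if e.atoms[0] in comp_set]
        sub = Layout2D()
        _layout_component(graph, comp_elements, comp_set, proj, config, sub)
        xs = [p[0] for p in sub.positions.values()]
        ys = [p[1] for p in sub.positions.values()]
        shift = np.array([offset - min(xs), 0.0]) if xs else np.zeros(2)
        for s, p in sub.positions.items():
            layout.positions[s] = p + shift
        if xs:
            offset += (max(xs) - min(xs)) + 2.0 * config.bond_length
        del ys
    return layout


def _element_sort_key(e: StructuralElement):
    kind_rank = {"ring": 0, "chain": 1, "isolated_atom": 2, "terminal_atom": 3}
    return (kind_rank[e.kind], min(e.atoms))


def _start_element(elements: list[StructuralElement]) -> StructuralElement:
    macro = [e for e in elements if e.kind == "ring" and e.is_macrocycle]
    if macro:
        return max(macro, key=lambda e: (len(e.atoms), -min(e.atoms)))
    chains = [e for e in elements if e.kind == "chain"]
    if chains:
        return max(chains, key=lambda e: (len(e.atoms), -min(e.atoms)))
    rings = [e for e in elements if e.kind == "ring"]
    if rings:
        return max(rings, key=lambda e: (len(e.atoms), -min(e.atoms)))
    return min(elements, key=_element_sort_key)


def _elements_adjacent(g: nx.Graph, e1: StructuralElement,
                       e2: StructuralElement) -> bool:
    s1, s2 = set(e1.atoms), set(e2.atoms)
    if s1 & s2:
        return True
    return any(g.has_edge(a, b) for a in s1 for b in s2)


def _layout_component(graph: MolecularGraph, elements, comp_set, proj,
                      config, layout: Layout2D) -> None:
    g = graph.g
    if not elements:
        return
    # DFS over structural elements
    start = _start_element(elements)
    visited: set[int] = set()
    order: list[StructuralElement] = []
    stack = [start]
    idx = {id(e): i for i, e in enumerate(elements)}
    while stack:
        e = stack.pop()
        if id(e) in visited:
            continue
        visited.add(id(e))
        order.append(e)
        neighbours = [o for o in elements if id(o) not in visited
                      and _elements_adjacent(g, e, o)]
        neighbours.sort(key=_element_sort_key, reverse=True)
        stack.extend(neighbours)
    for e in elements:  # disconnected-within-component safety net
        if id(e) not in visited:
            order.append(e)
    del idx

    state = _LayoutState(graph=graph, proj=proj, config=config, layout=layout)
    for e in order:
        if e.kind == "ring":
            state.place_ring(e.atoms)
        elif e.kind == "chain":
            state.place_chain(e.atoms)
        elif e.kind == "terminal_atom":
            state.place_terminal(e.atoms[0])
        else:
            state.place_isolated(e.atoms[0])
    # safety net: attach anything still unplaced
    for s in sorted(comp_set):
        if s not in layout.positions:
            placed_nb = [n for n in graph.neighbors(s) if n in layout.positions]
            if placed_nb:
                state.attach_atom(s, placed_nb[0])
            else:
                layout.positions[s] = proj[s].copy()


@dataclass
class _LayoutState:
    graph: MolecularGraph
    proj: dict[int, np.ndarray]
    config: LayoutConfig
    layout: Layout2D

    # --- helpers -----------------------------------------------------

    def placed(self, s: int) -> bool:
        return s in self.layout.positions

    def placed_neighbor_dirs(self, s: int) -> list[np.ndarray]:
        p = self.layout.pos(s)
        return [unit(self.layout.pos(n) - p)
                for n in self.graph.neighbors(s) if self.placed(n)]

    def turn_sign(self, prev_dir: np.ndarray, at: int, to: int) -> float:
        """Zig-zag turn side, taken from the 3D projection when it is
        informative, otherwise +1."""
        pd = self.proj
        if at in pd and to in pd:
            v = pd[to] - pd[at]
            cross = prev_dir[0] * v[1] - prev_dir[1] * v[0]
            if abs(cross) > 1e-9:
                return 1.0 if cross > 0 else -1.0
        return 1.0

    def attach_atom(self, s: int, parent: int, group: list[int] | None = None):
        """Place atom ``s`` (and optional same-parent ``group``) bonded to
        an already placed ``parent``."""
        group = group or [s]
        L = self.config.bond_length
        dirs = self.placed_neighbor_dirs(parent)
        turn = 180.0 - self.config.chain_angle
        if len(dirs) == 1 and len(group) == 1:
            # continue the zig-zag: interior angle = chain_angle exactly
            incoming = -dirs[0]
            sign = self.turn_sign(incoming, parent, s)
            d = rotate2d(incoming, sign * turn)
            self.layout.positions[s] = self.layout.pos(parent) + L * d
            return
        for atom, d in zip(group, largest_gap_directions(dirs, len(group))):
            self.layout.positions[atom] = self.layout.pos(parent) + L * d

    # --- element placement -------------------------------------------

    def place_chain(self, atoms: list[int]) -> None:
        cfg = self.config
        L = cfg.bond_length
        turn = 180.0 - cfg.chain_angle
        chain = list(atoms)
        placed_in = [a for a in chain if self.placed(a)]
        if len(placed_in) >= 2:
            chain = [a for a in chain if not self.placed(a)]
            for a in chain:
                parent = next((n for n in self.graph.neighbors(a)
                               if self.placed(n)), None)
                if parent is not None:
                    self.attach_atom(a, parent)
            return
        if placed_in:
            # orient chain from the placed atom outward
            i = chain.index(placed_in[0])
            if i > len(chain) // 2:
                chain.reverse()
                i = len(chain) - 1 - i
            chain = chain[i:]
            start_pos = self.layout.pos(chain[0])
            dirs = self.placed_neighbor_dirs(chain[0])
            if dirs:
                sign = self.turn_sign(-dirs[0], chain[0],
                                      chain[1] if len(chain) > 1 else chain[0])
                d = rotate2d(-dirs[0], sign * turn)
            else:
                d = unit(self.proj[chain[1]] - self.proj[chain[0]]) \
                    if len(chain) > 1 else np.array([1.0, 0.0])
        else:
            anchor_parent = None
            for a in (chain[0], chain[-1]):
                nb = [n for n in self.graph.neighbors(a) if self.placed(n)]
                if nb:
                    anchor_parent = (a, nb[0])
                    break
            if anchor_parent is None:
                mid = next((a for a in chain
                            for n in self.graph.neighbors(a)
                            if self.placed(n)), None)
                if mid is not None:
                    nb = [n for n in self.graph.neighbors(mid)
                          if self.placed(n)]
                    anchor_parent = (mid, nb[0])
            if anchor_parent is not None:
                a, parent = anchor_parent
                if a == chain[-1]:
                    chain.reverse()
                elif a != chain[0]:
                    i = chain.index(a)
                    chain = chain[i:] + chain[:i][::-1]  # walk out both ways
                self.attach_atom(a, parent)
                start_pos = self.layout.pos(chain[0])
                d = rotate2d(unit(start_pos - self.layout.pos(parent)),
                             self.turn_sign(unit(start_pos
                                                 - self.layout.pos(parent)),
                                            chain[0],
                                            chain[1] if len(chain) > 1
                                            else chain[0]) * turn)
            else:
                start_pos = self.proj[chain[0]].copy()
                d = unit(self.proj[chain[1]] - self.proj[chain[0]]) \
                    if len(chain) > 1 else np.array([1.0, 0.0])
            self.layout.positions[chain[0]] = start_pos
        # strict zig-zag: turns alternate; the first turn side comes from
        # the projected conformation
        prev_sign = None
        for k in range(1, len(chain)):
            a_prev, a = chain[k - 1], chain[k]
            if self.placed(a):
                d = unit(self.layout.pos(a) - self.layout.pos(a_prev))
                continue
            self.layout.positions[a] = self.layout.pos(a_prev) + L * d
            if k < len(chain) - 1:
                if prev_sign is None:
                    sign = self.turn_sign(d, a, chain[k + 1])
                else:
                    sign = -prev_sign
                d = rotate2d(d, sign * turn)
                prev_sign = sign

    def _proj_cross(self, prev_dir, at, to) -> float:
        v = self.proj[to] - self.proj[at]
        return float(prev_dir[0] * v[1] - prev_dir[1] * v[0])

    def place_ring(self, atoms: list[int]) -> None:
        cfg = self.config
        n = len(atoms)
        placed_in = [a for a in atoms if self.placed(a)]
        adjacent_placed = self._placed_adjacent_pair(atoms, placed_in)
        if adjacent_placed is not None:
            i, j = adjacent_placed
            pa, pb = self.layout.pos(atoms[i]), self.layout.pos(atoms[j])
            self._complete_polygon(atoms, i, j, pa, pb)
            return
        if placed_in:
            v = placed_in[0]
            radius = cfg.bond_length / (2.0 * np.sin(np.pi / n))
            dirs = self.placed_neighbor_dirs(v)
            out = -unit(np.sum(dirs, axis=0)) if dirs else np.array([1.0, 0.0])
            center = self.layout.pos(v) + radius * out
            self._polygon_from_center(atoms, atoms.index(v), center)
            return
        # ring attached by a bond, or free-floating
        attach = None
        for idx, a in enumerate(atoms):
            for nbp in self.graph.neighbors(a):
                if self.placed(nbp):
                    attach = (idx, nbp)
                    break
            if attach:
                break
        radius = cfg.bond_length / (2.0 * np.sin(np.pi / n))
        if attach is not None:
            idx, parent = attach
            self.attach_atom(atoms[idx], parent)
            v = atoms[idx]
            out = unit(self.layout.pos(v) - self.layout.pos(parent))
            center = self.layout.pos(v) + radius * out
            self._polygon_from_center(atoms, idx, center)
        else:
            centroid = np.mean([self.proj[a] for a in atoms], axis=0)
            phase = np.arctan2(*(self.proj[atoms[0]] - centroid)[::-1])
            ccw = self._proj_ring_orientation(atoms)
            ang = phase + ccw * 2.0 * np.pi * np.arange(n) / n
            for k, a in enumerate(atoms):
                self.layout.positions[a] = centroid + radius * np.array(
                    [np.cos(ang[k]), np.sin(ang[k])])

    def _proj_ring_orientation(self, atoms: list[int]) -> float:
        pts = [self.proj[a] for a in atoms]
        area = 0.0
        for i in range(len(pts)):
            x1, y1 = pts[i]
            x2, y2 = pts[(i + 1) % len(pts)]
            area += x1 * y2 - x2 * y1
        return 1.0 if area >= 0 else -1.0

    def _placed_adjacent_pair(self, atoms, placed_in):
        n = len(atoms)
        for i in range(n):
            j = (i + 1) % n
            if atoms[i] in placed_in and atoms[j] in placed_in:
                return (i, j)
        return None

    def _polygon_from_center(self, atoms, idx0, center) -> None:
        """Place ring vertices on the circle around ``center`` given that
        vertex ``idx0`` is already placed; orientation from projection."""
        n = len(atoms)
        p0 = self.layout.pos(atoms[idx0])
        radius = np.linalg.norm(p0 - center)
        phase = np.arctan2(p0[1] - center[1], p0[0] - center[0])
        ccw = self._proj_ring_orientation(atoms)
        for k in range(1, n):
            a = atoms[(idx0 + k) % n]
            if self.placed(a):
                continue
            t = phase + ccw * 2.0 * np.pi * k / n
            self.layout.positions[a] = center + radius * np.array(
                [np.cos(t), np.sin(t)])

    def _complete_polygon(self, atoms, i, j, pa, pb) -> None:
        """Complete a regular polygon sharing the placed edge i-j (fused
        rings); the new ring is placed on the side away from the placed
        atoms' centroid."""
        n = len(atoms)
        mid = (pa + pb) / 2.0
        edge = np.linalg.norm(pb - pa)
        apothem = edge / (2.0 * np.tan(np.pi / n))
        normal = unit(rotate2d(pb - pa, 90.0))
        others = [self.layout.pos(s) for s in self.layout.positions
                  if s not in (atoms[i], atoms[j])]
        ref = np.mean(others, axis=0) if others else mid + normal
        side = 1.0 if np.dot(mid - ref, normal) >= 0 else -1.0
        center = mid + side * apothem * normal
        radius = edge / (2.0 * np.sin(np.pi / n))
        # walk the ring from vertex i, direction chosen so vertex j is next
        phase = np.arctan2(pa[1] - center[1], pa[0] - center[0])
        phase_j = np.arctan2(pb[1] - center[1], pb[0] - center[0])
        step = 2.0 * np.pi / n
        delta = (phase_j - phase) % (2.0 * np.pi)
        ccw = 1.0 if abs(delta - step) < abs(delta - (2 * np.pi - step)) \
            else -1.0
        for k in range(1, n):
            a = atoms[(i + k) % n]
            if self.placed(a):
                continue
            t = phase + ccw * step * k
            self.layout.positions[a] = center + radius * np.array(
                [np.cos(t), np.sin(t)])

    def place_terminal(self, s: int) -> None:
        if self.placed(s):
            return
        parents = [n for n in self.graph.neighbors(s) if self.placed(n)]
        if not parents:
            self.layout.positions[s] = self.proj[s].copy()
            return
        parent = parents[0]
        # gather unplaced terminal siblings so they are spread together
        siblings = sorted(n for n in self.graph.neighbors(parent)
                          if not self.placed(n)
                          and self.graph.degree(n) == 1)
        self.attach_atom(s, parent, group=siblings if s in siblings else [s])

    def place_isolated(self, s: int) -> None:
        if self.placed(s):
            return
        parents = [n for n in self.graph.neighbors(s) if self.placed(n)]
        if parents:
            self.attach_atom(s, parents[0])
        else:
            self.layout.positions[s] = self.proj[s].copy()


# ------------------------------------------------------------- conflicts

def detect_conflicts(layout: Layout2D, graph: MolecularGraph,
                     config: LayoutConfig | None = None) -> list[tuple[int, int]]:
    """All non-bonded atom pairs closer than the conflict distance."""
    config = config or LayoutConfig()
    serials = sorted(layout.positions)
    pts = layout.array(serials)
    out = []
    thr = config.conflict_distance
    for i in range(len(serials)):
        d = np.linalg.norm(pts[i + 1:] - pts[i], axis=1)
        for k in np.nonzero(d < thr)[0]:
            s1, s2 = serials[i], serials[i + 1 + k]
            if not graph.has_bond(s1, s2):
                out.append((s1, s2))
    return out


def _rotatable_bonds(graph: MolecularGraph) -> list[tuple[int, int, list[int]]]:
    """Bridge bonds with the branch (smaller side) that a flip would move."""
    g = graph.g
    out = []
    for u, v in sorted(nx.bridges(g)):
        h = g.copy()
        h.remove_edge(u, v)
        side_v = nx.node_connected_component(h, v)
        side_u = nx.node_connected_component(h, u)
        if len(side_v) <= len(side_u):
            branch = sorted(side_v - {v})
            out.append((u, v, branch))
        else:
            branch = sorted(side_u - {u})
            out.append((v, u, branch))
    return [b for b in out if b[2]]


def resolve_conflicts(layout: Layout2D, graph: MolecularGraph,
                      config: LayoutConfig | None = None) -> Layout2D:
    """Reduce overlaps by flipping acyclic branches across bond axes.

    A flip is accepted only when it strictly decreases the number of
    conflicts; passes repeat until no flip is accepted (bounded by
    ``config.flip_passes``).  The final conflict count never exceeds the
    initial one.
    """
    config = config or LayoutConfig()
    current = layout.copy()
    bonds = _rotatable_bonds(graph)
    best_count = len(detect_conflicts(current, graph, config))
    for _ in range(config.flip_passes):
        improved = False
        for u, v, branch in bonds:
            a, b = current.pos(u), current.pos(v)
            if np.linalg.norm(b - a) < 1e-9:
                continue
            trial = current.copy()
            for s in branch:
                trial.positions[s] = reflect_point(trial.pos(s), a, b)
            count = len(detect_conflicts(trial, graph, config))
            if count < best_count:
                current, best_count = trial, count
                improved = True
        if not improved:
            break
    return current


# ----------------------------------------------------- explicit residues

def place_explicit_residue(layout: Layout2D, graph: MolecularGraph,
                           residue_layout: Layout2D,
                           residue_bonds: list[tuple[int, int]],
                           anchor: tuple[int, int], distance3d: float,
                           config: LayoutConfig | None = None,
                           rng: np.random.Generator | None = None,
                           trace: bool = False,
                           ) -> tuple[Layout2D, ExplicitPlacement]:
    """Rigid-place an independently laid-out residue around the ligand.

    The residue's anchor atom is constrained to the circle of radius
    ``distance3d`` (the true 3D distance) around the ligand anchor atom;
    every rotation in ``explicit_residue_step`` degree increments from a
    seeded random start is scored by (bond crossings + atom overlaps) and
    the minimum wins, ties going to the earliest candidate.
    """
    config = config or LayoutConfig()
    if distance3d <= 0:
        raise ValueError("distance3d must be positive")
    rng = rng or np.random.default_rng(config.seed)
    lig_anchor, res_anchor = anchor
    center = layout.pos(lig_anchor)
    step = config.explicit_residue_step
    n_cand = int(round(360.0 / step))
    theta0 = float(rng.uniform(0.0, 360.0))

    lig_serials = sorted(layout.positions)
    lig_pts = layout.array(lig_serials)
    lig_segments = [(layout.pos(a), layout.pos(b))
                    for a, b in graph.g.edges]

    res_serials = sorted(residue_layout.positions)
    res_rel = {s: residue_layout.pos(s) - residue_layout.pos(res_anchor)
               for s in res_serials}

    candidates: list[PlacementCandidate] = []
    best = None
    for i in range(n_cand):
        theta = (theta0 + i * step) % 360.0
        target = center + distance3d * rotate2d(np.array([1.0, 0.0]), theta)
        pos = {s: target + res_rel[s] for s in res_serials}
        crossings = 0
        segs = [(center, target)]
        segs += [(pos[a], pos[b]) for a, b in residue_bonds]
        for p1, p2 in segs:
            for q1, q2 in lig_segments:
                if segments_cross(p1, p2, q1, q2):
                    crossings += 1
        overlaps = 0
        thr = config.conflict_distance
        for s in res_serials:
            d = np.linalg.norm(lig_pts - pos[s], axis=1)
            overlaps += int(np.count_nonzero(d < thr))
        score = (crossings + overlaps, i)
        cand = PlacementCandidate(angle=theta, position=target,
                                  score=(crossings, overlaps))
        candidates.append(cand)
        if best is None or score < best[0]:
            best = (score, theta, pos, cand)
    _, theta, pos, chosen = best
    merged = layout.copy()
    for s in res_serials:
        merged.positions[s] = pos[s]
    record = ExplicitPlacement(chosen_angle=theta,
                               chosen_score=chosen.score,
                               candidates=candidates if trace else [])
    return merged, record
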
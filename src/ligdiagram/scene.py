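"""Diagram assembly: placing interactions and labels around the ligand.

Every interacting element is placed by the same rotational search: it
sits on a circle around its ligand-side anchor whose radius is the true
3D distance, candidate positions are enumerated in 5-degree steps from a
seeded random start, and the candidate minimising the number of bond
crossings wins, ties going first to the candidate with fewest close
contacts (atoms within 0.4 A), then to the earliest candidate.  Hydrogen
bonds are placed first (their connector lines cross most easily), then
nearby-residue ovals, then any water bridges, each seeing all earlier
elements as obstacles.

Residue-name labels run the same search on a circle around the residue
centroid with radius max(distance(centroid, atom)) + 0.5 A, in 10-degree
steps, minimising the number of diagram elements within 2 A.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._geom import rotate2d, segments_cross
from .interactions import (InteractionConfig, InteractionSet,
                           detect_interactions)
from .layout2d import (Layout2D, LayoutConfig, layout_ligand,
                       place_explicit_residue, resolve_conflicts)
from .ligand_detect import LigandInstance
from .molgraph import (MolecularGraph, detect_macrocycles, graph_from_atoms,
                       build_graph, partition, perceive_sssr)
from .pdb_io import Atom, ComponentDefinition, Structure

INTERACTION_STEP_DEG = 5.0
LABEL_STEP_DEG = 10.0
LABEL_RADIUS_PAD = 0.5      # Angstrom added to the max centroid distance
LABEL_NEARBY_DIST = 2.0     # element counts as nearby below this distance
CLOSE_CONTACT_DIST = 0.4
OVAL_RADIUS = 1.2           # obstacle radius used for residue ovals


@dataclass
class SceneConfig:
    interaction_step: float = INTERACTION_STEP_DEG
    label_step: float = LABEL_STEP_DEG
    label_nearby_distance: float = LABEL_NEARBY_DIST
    close_contact_distance: float = CLOSE_CONTACT_DIST
    oval_radius: float = OVAL_RADIUS
    seed: int = 0


@dataclass
class PlacedElement:
    kind: str                    # hbond_partner | residue_oval | water_bridge
    anchor: np.ndarray           # 2D anchor the circle is centred on
    position: np.ndarray
    radius_used: float
    candidate_step: float
    score: tuple[int, int]       # (crossings, close contacts)
    payload: object = None       # HydrogenBond | NearbyResidue | WaterBridge
    label: str = ""
    trace: list[tuple[float, np.ndarray, tuple[int, int]]] = field(
        default_factory=list)
    waters_positions: list[np.ndarray] = field(default_factory=list)


@dataclass
class LabelPlacement:
    residue_id: tuple[str, str, int]
    centroid: np.ndarray
    radius: float
    position: np.ndarray
    nearby_count: int
    text: str = ""
    trace: list[tuple[float, np.ndarray, int]] = field(default_factory=list)


@dataclass
class Scene:
    layout: Layout2D
    graph: MolecularGraph
    interactions: InteractionSet
    placed: list[PlacedElement] = field(default_factory=list)
    labels: list[LabelPlacement] = field(default_factory=list)
    explicit_serials: set[int] = field(default_factory=set)

    def segments(self) -> list[tuple[np.ndarray, np.ndarray]]:
        """All drawn line segments: ligand bonds plus placed connectors."""
        segs = [(self.layout.pos(a), self.layout.pos(b))
                for a, b in self.graph.g.edges
                if a in self.layout.positions and b in self.layout.positions]
        for el in self.placed:
            if el.kind == "water_bridge":
                pts = [el.anchor, *el.waters_positions, el.position]
                segs += [(pts[i], pts[i + 1]) for i in range(len(pts) - 1)]
            else:
                segs.append((el.anchor, el.position))
        return segs

    def obstacle_points(self) -> list[np.ndarray]:
        pts = [self.layout.pos(s) for s in sorted(self.layout.positions)]
        for el in self.placed:
            pts.append(el.position)
            pts.extend(el.waters_positions)
        return pts


def _score_candidate(anchor: np.ndarray, position: np.ndarray,
                     segments, obstacles: list[np.ndarray],
                     contact_dist: float) -> tuple[int, int]:
    crossings = 0
    for q1, q2 in segments:
        if segments_cross(anchor, position, q1, q2):
            crossings += 1
    contacts = sum(1 for p in obstacles
                   if np.linalg.norm(p - position) < contact_dist)
    return (crossings, contacts)


def _circle_search(anchor: np.ndarray, radius: float, step: float,
                   theta0: float, segments, obstacles,
                   contact_dist: float, trace: bool,
                   ) -> tuple[np.ndarray, tuple[int, int], list]:
    n = int(round(360.0 / step))
    best = None
    rec = []
    for i in range(n):
        theta = (theta0 + i * step) % 360.0
        pos = anchor + radius * rotate2d(np.array([1.0, 0.0]), theta)
        score = _score_candidate(anchor, pos, segments, obstacles,
                                 contact_dist)
        if trace:
            rec.append((theta, pos, score))
        if best is None or (score, i) < (best[1], best[2]):
            best = (pos, score, i)
    return best[0], best[1], rec


def place_interactions(layout: Layout2D, graph: MolecularGraph,
                       interactions: InteractionSet,
                       config: SceneConfig | None = None,
                       rng: np.random.Generator | None = None,
                       explicit_serials: set[int] | None = None,
                       trace: bool = False) -> Scene:
    """Place hydrogen bonds, then nearby residues, then water bridges."""
    config = config or SceneConfig()
    rng = rng or np.random.default_rng(config.seed)
    scene = Scene(layout=layout, graph=graph, interactions=interactions,
                  explicit_serials=set(explicit_serials or ()))

    hbonded_positions: dict[tuple[str, str, int], np.ndarray] = {}

    for hb in interactions.hbonds:
        lig_atom = hb.ligand_atom
        if lig_atom.serial not in layout.positions:
            continue
        anchor = layout.pos(lig_atom.serial)
        pos, score, rec = _circle_search(
            anchor, hb.distance, config.interaction_step,
            float(rng.uniform(0.0, 360.0)), scene.segments(),
            scene.obstacle_points(), config.close_contact_distance, trace)
        el = PlacedElement(kind="hbond_partner", anchor=anchor, position=pos,
                           radius_used=hb.distance,
                           candidate_step=config.interaction_step,
                           score=score, payload=hb,
                           label=_atom_label(hb.partner_atom), trace=rec)
        scene.placed.append(el)
        hbonded_positions[hb.partner_atom.residue_id] = pos

    for nr in interactions.nearby_residues:
        lig_atom, res_atom = nr.closest_atom_pair
        if lig_atom.serial not in layout.positions:
            continue
        anchor = layout.pos(lig_atom.serial)
        if nr.residue_id in hbonded_positions:
            # unified depiction: the oval sits at the H-bond partner
            pos = hbonded_positions[nr.residue_id]
            el = PlacedElement(kind="residue_oval", anchor=anchor,
                               position=pos,
                               radius_used=float(np.linalg.norm(pos - anchor)),
                               candidate_step=config.interaction_step,
                               score=(0, 0), payload=nr,
                               label=_residue_label(nr.residue_id))
            scene.placed.append(el)
            continue
        pos, score, rec = _circle_search(
            anchor, nr.min_distance, config.interaction_step,
            float(rng.uniform(0.0, 360.0)), scene.segments(),
            scene.obstacle_points(), config.close_contact_distance, trace)
        el = PlacedElement(kind="residue_oval", anchor=anchor, position=pos,
                           radius_used=nr.min_distance,
                           candidate_step=config.interaction_step,
                           score=score, payload=nr,
                           label=_residue_label(nr.residue_id), trace=rec)
        scene.placed.append(el)

    for wb in interactions.water_bridges:
        if wb.ligand_atom.serial not in layout.positions:
            continue
        anchor = layout.pos(wb.ligand_atom.serial)
        water_positions: list[np.ndarray] = []
        prev = anchor
        rec_all: list = []
        last_score = (0, 0)
        for k, step_d in enumerate(wb.step_distances):
            pos, score, rec = _circle_search(
                prev, step_d, config.interaction_step,
                float(rng.uniform(0.0, 360.0)),
                scene.segments(), scene.obstacle_points(),
                config.close_contact_distance, trace)
            rec_all.extend(rec)
            last_score = score
            if k < len(wb.waters):
                water_positions.append(pos)
            prev = pos
        el = PlacedElement(kind="water_bridge", anchor=anchor, position=prev,
                           radius_used=float(wb.step_distances[-1]),
                           candidate_step=config.interaction_step,
                           score=last_score, payload=wb,
                           label=_residue_label(wb.residue_atom.residue_id),
                           trace=rec_all,
                           waters_positions=water_positions)
        scene.placed.append(el)

    return scene


def _atom_label(atom: Atom) -> str:
    name, chain, seq = atom.residue_id
    return f"{name}{seq}({chain}) {atom.name}"


def _residue_label(residue_id: tuple[str, str, int]) -> str:
    name, chain, seq = residue_id
    return f"{name}{seq}({chain})"


def residue_groups_for_labels(scene: Scene,
                              ligand_residues: dict[tuple, list[int]],
                              ) -> dict[tuple, list[int]]:
    """Residue id -> atom serials drawn for it (ligand + explicit)."""
    return {rid: [s for s in serials if s in scene.layout.positions]
            for rid, serials in ligand_residues.items()}


def place_labels(scene: Scene,
                 residue_atoms: dict[tuple, list[int]],
                 config: SceneConfig | None = None,
                 rng: np.random.Generator | None = None,
                 trace: bool = False) -> list[LabelPlacement]:
    """Place one name label per drawn residue by rotational search."""
    config = config or SceneConfig()
    rng = rng or np.random.default_rng(config.seed + 1)
    labels: list[LabelPlacement] = []
    for rid in sorted(residue_atoms, key=lambda r: (r[1], r[2], r[0])):
        serials = [s for s in residue_atoms[rid]
                   if s in scene.layout.positions]
        if not serials:
            continue
        pts = scene.layout.array(serials)
        centroid = pts.mean(axis=0)
        radius = float(np.max(np.linalg.norm(pts - centroid, axis=1))) \
            + LABEL_RADIUS_PAD
        obstacles = scene.obstacle_points() + [l.position for l in labels]
        n = int(round(360.0 / config.label_step))
        theta0 = float(rng.uniform(0.0, 360.0))
        best = None
        rec = []
        for i in range(n):
            theta = (theta0 + i * config.label_step) % 360.0
            pos = centroid + radius * rotate2d(np.array([1.0, 0.0]), theta)
            count = sum(1 for p in obstacles
                        if np.linalg.norm(p - pos)
                        < config.label_nearby_distance)
            if trace:
                rec.append((theta, pos, count))
            if best is None or (count, i) < (best[1], best[2]):
                best = (pos, count, i)
        labels.append(LabelPlacement(
            residue_id=rid, centroid=centroid, radius=radius,
            position=best[0], nearby_count=best[1],
            text=_residue_label(rid), trace=rec))
    scene.labels = labels
    return labels


# ------------------------------------------------------------- pipeline

def build_scene(structure: Structure, ligand: LigandInstance,
                components: dict[str, ComponentDefinition] | None = None,
                interaction_config: InteractionConfig | None = None,
                layout_config: LayoutConfig | None = None,
                scene_config: SceneConfig | None = None) -> Scene:
    """Full diagram assembly for one ligand.

    Runs graph building, ring perception, partition, 2D layout, conflict
    resolution, explicit-residue placement, interaction detection,
    interaction placement and label placement, in that order.
    """
    interaction_config = interaction_config or InteractionConfig()
    layout_config = layout_config or LayoutConfig()
    scene_config = scene_config or SceneConfig(seed=layout_config.seed)

    graph = build_graph(ligand, components, structure)
    rings = detect_macrocycles(perceive_sssr(graph))
    elements = partition(graph, rings)
    layout = layout_ligand(graph, elements, layout_config)
    layout = resolve_conflicts(layout, graph, layout_config)

    rng = np.random.default_rng(layout_config.seed)
    explicit_serials: set[int] = set()
    residue_atoms: dict[tuple, list[int]] = {}
    for rid in ligand.residues:
        residue_atoms.setdefault(rid, [])
    for a in ligand.atoms:
        residue_atoms.setdefault(a.residue_id, []).append(a.serial)

    res_groups = structure.residues()
    for lig_atom, res_atom in ligand.explicit_anchors:
        res_heavy = [a for a in res_groups[res_atom.residue_id]
                     if not a.is_hydrogen]
        res_graph = graph_from_atoms(res_heavy)
        res_rings = detect_macrocycles(perceive_sssr(res_graph))
        res_elements = partition(res_graph, res_rings)
        res_layout = layout_ligand(res_graph, res_elements, layout_config)
        dist3d = float(np.linalg.norm(lig_atom.coords - res_atom.coords))
        layout, _ = place_explicit_residue(
            layout, graph, res_layout,
            [tuple(e) for e in res_graph.g.edges],
            (lig_atom.serial, res_atom.serial), dist3d,
            layout_config, rng)
        # merge the residue into the drawn graph with its connector bond
        for a in res_heavy:
            graph.add_atom(a)
        for u, v in res_graph.g.edges:
            graph.add_bond(u, v, res_graph.bond_order(u, v))
        graph.add_bond(lig_atom.serial, res_atom.serial, "single")
        explicit_serials.update(a.serial for a in res_heavy)
        residue_atoms[res_atom.residue_id] = [a.serial for a in res_heavy]

    interactions = detect_interactions(ligand, structure, components,
                                       interaction_config)
    # explicit residues are drawn with the ligand: drop their oval entries
    drawn = set(residue_atoms)
    interactions.nearby_residues = [
        nr for nr in interactions.nearby_residues if nr.residue_id not in drawn]
    scene = place_interactions(layout, graph, interactions, scene_config,
                               rng, explicit_serials)
    place_labels(scene, residue_atoms, scene_config, rng)
    return scene
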
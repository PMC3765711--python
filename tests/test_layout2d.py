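from itertools import combinations, product

import numpy as np
import pytest

from ligdiagram import (Layout2D, LayoutConfig, detect_conflicts,
                        layout_ligand, place_explicit_residue,
                        resolve_conflicts)
from ligdiagram.molgraph import MolecularGraph
from ligdiagram.pdb_io import Atom

from conftest import full_layout, interior_angles


def _mk_atom(serial, name="C", element="C", xyz=(0, 0, 0)):
    return Atom(serial=serial, name=f"{name}{serial}", element=element,
                coords=np.asarray(xyz, dtype=float), residue_name="LIG",
                residue_seq=1, chain_id="A", is_het=True)


def _mk_graph(edges, n=None):
    g = MolecularGraph()
    nodes = sorted({s for e in edges for s in e} | set(range(1, (n or 0) + 1)))
    for s in nodes:
        g.add_atom(_mk_atom(s))
    for u, v in edges:
        g.add_bond(u, v, "single")
    return g


class TestLayoutLigand:
    def test_chain_interior_angles_exactly_120(self):
        g, elements, layout = full_layout("linear_chain", n=5)
        angles = interior_angles(layout, [1, 2, 3, 4, 5])
        assert angles == pytest.approx([120.0] * 3, abs=1e-9)

    def test_hexagon_is_regular(self):
        g, elements, layout = full_layout("ring", n=6)
        pts = layout.array(sorted(layout.positions))
        centre = pts.mean(axis=0)
        radial = np.linalg.norm(pts - centre, axis=1)
        assert radial.max() - radial.min() < 1e-6
        # central angles are all 360/6 = 60 degrees
        ang = np.degrees(np.arctan2(*(pts - centre).T[::-1]))
        diffs = np.sort(np.mod(np.diff(np.sort(ang)), 360.0))
        assert diffs == pytest.approx([60.0] * 5, abs=1e-6)

    @pytest.mark.parametrize("kind,params", [
        ("ring", {"n": 5}), ("ring", {"n": 6}), ("ring", {"n": 7}),
        ("fused_rings", {}), ("macrocycle", {})])
    def test_ring_regularity_invariant(self, kind, params):
        g, elements, layout = full_layout(kind, **params)
        for e in elements:
            if e.kind != "ring":
                continue
            pts = layout.array(e.atoms)
            centre = pts.mean(axis=0)
            radial = np.linalg.norm(pts - centre, axis=1)
            assert radial.max() - radial.min() < 1e-6

    def test_acyclic_bond_lengths_uniform(self):
        for kind, params in [("linear_chain", {"n": 7}),
                             ("fused_rings", {})]:
            g, elements, layout = full_layout(kind, **params)
            ring_edges = set()
            for e in elements:
                if e.kind == "ring":
                    n = len(e.atoms)
                    for i in range(n):
                        ring_edges.add(frozenset((e.atoms[i],
                                                  e.atoms[(i + 1) % n])))
            for u, v in g.g.edges:
                if frozenset((u, v)) in ring_edges:
                    continue
                d = np.linalg.norm(layout.pos(u) - layout.pos(v))
                assert d == pytest.approx(1.5, abs=1e-9)

    def test_macrocycle_drawn_as_one_regular_polygon(self):
        g, elements, layout = full_layout("macrocycle")
        (ring,) = [e for e in elements if e.kind == "ring"]
        assert ring.is_macrocycle
        pts = layout.array(ring.atoms)
        centre = pts.mean(axis=0)
        radial = np.linalg.norm(pts - centre, axis=1)
        assert radial.max() - radial.min() < 1e-6
        assert len(pts) == 30

    def test_epo_like_layout_covers_all_atoms(self, epo_like):
        from ligdiagram import (build_graph, detect_macrocycles, partition,
                                perceive_sssr)
        st, comps, lig = epo_like
        g = build_graph(lig, comps, st)
        elements = partition(g, detect_macrocycles(perceive_sssr(g)))
        layout = layout_ligand(g, elements)
        assert set(layout.positions) == set(g.g.nodes)
        assert all(np.all(np.isfinite(p)) for p in layout.positions.values())

    def test_deterministic(self):
        a = full_layout("fused_rings")[2]
        b = full_layout("fused_rings")[2]
        assert set(a.positions) == set(b.positions)
        for s in a.positions:
            assert np.array_equal(a.pos(s), b.pos(s))

    def test_disconnected_components_separated(self):
        g = _mk_graph([(1, 2), (3, 4)])
        from ligdiagram.molgraph import partition, perceive_sssr
        elements = partition(g, perceive_sssr(g))
        layout = layout_ligand(g, elements)
        d = min(np.linalg.norm(layout.pos(i) - layout.pos(j))
                for i in (1, 2) for j in (3, 4))
        assert d > 1.5


class TestDetectConflicts:
    def _two_atom_layout(self, d):
        g = _mk_graph([], n=2)
        layout = Layout2D({1: np.array([0.0, 0.0]), 2: np.array([d, 0.0])})
        return layout, g

    def test_below_threshold_is_conflict(self):
        layout, g = self._two_atom_layout(0.3)
        assert detect_conflicts(layout, g) == [(1, 2)]

    def test_above_threshold_is_not(self):
        layout, g = self._two_atom_layout(0.5)
        assert detect_conflicts(layout, g) == []

    def test_bonded_pairs_excluded(self):
        g = _mk_graph([(1, 2)])
        layout = Layout2D({1: np.array([0.0, 0.0]), 2: np.array([0.1, 0.0])})
        assert detect_conflicts(layout, g) == []

    def test_conflict_free_hexagon(self):
        g, _, layout = full_layout("ring", n=6)
        assert detect_conflicts(layout, g) == []


def _brute_force_min_conflicts(layout, graph, config=None):
    """Oracle: minimum conflict count over all subsets of branch flips,
    with its own reflection arithmetic and bridge search."""
    config = config or LayoutConfig()
    g = graph.g
    flips = []
    for u, v in g.edges:
        h = g.copy()
        h.remove_edge(u, v)
        import networkx as nx
        if nx.has_path(h, u, v):
            continue  # not a bridge
        side_v = nx.node_connected_component(h, v)
        side_u = nx.node_connected_component(h, u)
        axis, side = ((u, v), side_v) if len(side_v) <= len(side_u) \
            else ((v, u), side_u)
        moved = sorted(side - {axis[1]})
        if moved:
            flips.append((axis, moved))

    def reflect(p, a, b):
        d = (b - a) / np.linalg.norm(b - a)
        w = p - a
        return a + 2 * np.dot(w, d) * d - w

    def count(positions):
        n = 0
        ser = sorted(positions)
        for i, j in combinations(ser, 2):
            if graph.has_bond(i, j):
                continue
            if np.linalg.norm(positions[i] - positions[j]) \
                    < config.conflict_distance:
                n += 1
        return n

    best = count(layout.positions)
    for mask in product([0, 1], repeat=len(flips)):
        pos = {s: p.copy() for s, p in layout.positions.items()}
        for bit, ((u, v), moved) in zip(mask, flips):
            if bit:
                for s in moved:
                    pos[s] = reflect(pos[s], pos[u], pos[v])
        best = min(best, count(pos))
    return best


class TestResolveConflicts:
    def _crowded_fixture(self):
        # 1-2-3-4 chain with branch 5 on atom 2; atom 4 folded back onto
        # atom 5; the flip across bond 2-3 frees it completely
        g = _mk_graph([(1, 2), (2, 3), (3, 4), (2, 5)])
        p2 = np.array([1.5, 0.0])
        p3 = p2 + 1.5 * np.array([np.cos(np.radians(60)),
                                  np.sin(np.radians(60))])
        p5 = np.array([0.75, 1.299])
        p4 = p3 + 1.5 * (p5 - p3) / np.linalg.norm(p5 - p3)
        layout = Layout2D({1: np.array([0.0, 0.0]), 2: p2, 3: p3,
                           4: p4, 5: p5})
        return g, layout

    def test_single_flip_removes_all_overlaps(self):
        g, layout = self._crowded_fixture()
        assert len(detect_conflicts(layout, g)) >= 1
        assert _brute_force_min_conflicts(layout, g) == 0
        resolved = resolve_conflicts(layout, g)
        assert detect_conflicts(resolved, g) == []

    def test_conflict_free_layout_unchanged(self):
        g, _, layout = full_layout("ring", n=6)
        resolved = resolve_conflicts(layout, g)
        for s in layout.positions:
            assert np.array_equal(resolved.pos(s), layout.pos(s))

    def test_never_increases_conflicts(self):
        rng = np.random.default_rng(11)
        g = _mk_graph([(1, 2), (2, 3), (3, 4), (2, 5), (3, 6), (6, 7)])
        for _ in range(25):
            pts = rng.uniform(-2.0, 2.0, size=(7, 2))
            layout = Layout2D({s: pts[s - 1] for s in range(1, 8)})
            before = len(detect_conflicts(layout, g))
            after = len(detect_conflicts(resolve_conflicts(layout, g), g))
            assert after <= before

    def test_ring_interiors_never_flipped(self):
        g, _, layout = full_layout("fused_rings")
        resolved = resolve_conflicts(layout, g)
        for s in layout.positions:
            assert np.allclose(resolved.pos(s), layout.pos(s))


def _crossings_and_overlaps(candidate_pos, res_rel, connector_from, layout,
                            graph, thr=0.4):
    """In-test scorer for explicit-residue candidates (oracle)."""
    def seg_cross(p1, p2, q1, q2):
        def orient(a, b, c):
            v = (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])
            return 0 if abs(v) < 1e-9 else (1 if v > 0 else -1)
        if min(np.linalg.norm(a - b) for a, b in
               [(p1, q1), (p1, q2), (p2, q1), (p2, q2)]) < 1e-9:
            return False
        o1, o2 = orient(p1, p2, q1), orient(p1, p2, q2)
        o3, o4 = orient(q1, q2, p1), orient(q1, q2, p2)
        return o1 != o2 and o3 != o4 and 0 not in (o1, o2, o3, o4)

    lig_segs = [(layout.pos(a), layout.pos(b)) for a, b in graph.g.edges]
    pos = {s: candidate_pos + rel for s, rel in res_rel.items()}
    segs = [(connector_from, candidate_pos)]
    crossings = sum(seg_cross(p1, p2, q1, q2)
                    for p1, p2 in segs for q1, q2 in lig_segs)
    overlaps = sum(1 for s in pos
                   for t in layout.positions
                   if np.linalg.norm(pos[s] - layout.pos(t)) < thr)
    return crossings + overlaps


class TestPlaceExplicitResidue:
    def _setup(self):
        g, elements, layout = full_layout("ring", n=6)
        res_g = _mk_graph([(101, 102), (102, 103)])
        # residue laid out as a short chain
        res_layout = Layout2D({101: np.array([0.0, 0.0]),
                               102: np.array([1.5, 0.0]),
                               103: np.array([2.25, 1.3])})
        return g, layout, res_g, res_layout

    def test_anchor_distance_equals_radius(self):
        g, layout, res_g, res_layout = self._setup()
        merged, rec = place_explicit_residue(
            layout, g, res_layout, list(res_g.g.edges), (1, 101), 3.7)
        d = np.linalg.norm(merged.pos(101) - layout.pos(1))
        assert d == pytest.approx(3.7, abs=1e-9)

    def test_candidate_count_and_step(self):
        g, layout, res_g, res_layout = self._setup()
        _, rec = place_explicit_residue(
            layout, g, res_layout, list(res_g.g.edges), (1, 101), 3.7,
            trace=True)
        assert len(rec.candidates) == 36
        angles = [c.angle for c in rec.candidates]
        steps = {round((angles[i + 1] - angles[i]) % 360.0, 6)
                 for i in range(len(angles) - 1)}
        assert steps == {10.0}

    def test_chosen_score_is_candidate_minimum(self):
        g, layout, res_g, res_layout = self._setup()
        _, rec = place_explicit_residue(
            layout, g, res_layout, list(res_g.g.edges), (1, 101), 2.0,
            trace=True)
        scores = [sum(c.score) for c in rec.candidates]
        assert sum(rec.chosen_score) == min(scores)

    def test_nonpositive_distance_rejected(self):
        g, layout, res_g, res_layout = self._setup()
        with pytest.raises(ValueError):
            place_explicit_residue(layout, g, res_layout,
                                   list(res_g.g.edges), (1, 101), 0.0)

    def test_deterministic_under_seed(self):
        g, layout, res_g, res_layout = self._setup()
        runs = []
        for _ in range(2):
            rng = np.random.default_rng(5)
            merged, rec = place_explicit_residue(
                layout, g, res_layout, list(res_g.g.edges), (1, 101), 3.0,
                rng=rng)
            runs.append((rec.chosen_angle,
                         {s: tuple(p) for s, p in merged.positions.items()}))
        assert runs[0] == runs[1]
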
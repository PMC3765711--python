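import networkx as nx
import pytest

from ligdiagram import (FixtureSpec, build_graph, detect_ligands,
                        detect_macrocycles, make_ligand, parse_components,
                        parse_pdb, partition, perceive_sssr)
from ligdiagram.molgraph import MACROCYCLE_SIZE, GraphBuildError

from conftest import EPO_LIKE_COMPONENT, EPO_LIKE_PDB, graph_of


# ------------------------------------------------- brute-force SSSR oracle

def minimal_cycle_basis_sizes(g: nx.Graph) -> list[int]:
    """Independent oracle: smallest-first greedy over ALL simple cycles
    with GF(2) independence — exact minimum cycle basis on small graphs."""
    eidx = {frozenset(e): i for i, e in enumerate(g.edges)}
    cycles = sorted(nx.simple_cycles(g), key=len)

    def vec(cyc):
        v = 0
        for i in range(len(cyc)):
            v ^= 1 << eidx[frozenset((cyc[i], cyc[(i + 1) % len(cyc)]))]
        return v

    target = g.number_of_edges() - g.number_of_nodes() \
        + nx.number_connected_components(g)
    rows, sizes = [], []
    for cyc in cycles:
        w = vec(cyc)
        for r in rows:
            w = min(w, w ^ r)
        if w:
            rows.append(w)
            rows.sort(reverse=True)
            sizes.append(len(cyc))
            if len(sizes) == target:
                break
    return sorted(sizes)


class TestBuildGraph:
    def test_benzene_nodes_and_aromatic_edges(self):
        g = graph_of("ring", n=6, comp_id="BNZ")
        assert g.n_atoms == 6
        assert g.n_bonds == 6
        assert all(g.bond_order(u, v) == "aromatic" for u, v in g.g.edges)

    def test_name_mapping_covers_all_heavy_atoms(self):
        st = parse_pdb(EPO_LIKE_PDB)
        comps = parse_components(EPO_LIKE_COMPONENT)
        lig = detect_ligands(st)[0]
        g = build_graph(lig, comps, st)
        assert g.n_atoms == 11
        assert g.n_bonds == 11
        assert g.bond_order(5, 6) == "double"  # C=O carbonyl

    def test_renamed_atom_recovered_by_isomorphism_fallback(self):
        # rename one benzene carbon: name map fails, the element-labelled
        # subgraph isomorphism must still produce a full mapping
        pdb, comp_text = make_ligand(FixtureSpec("ring",
                                                 {"n": 6, "comp_id": "BNZ"}))
        pdb = pdb.replace(" C3 ", " CX ")
        st = parse_pdb(pdb)
        comps = parse_components(comp_text)
        lig = detect_ligands(st)[0]
        g = build_graph(lig, comps, st)
        assert g.n_atoms == 6
        assert g.n_bonds == 6
        assert all(g.bond_order(u, v) == "aromatic" for u, v in g.g.edges)

    def test_missing_component_distance_fallback_and_error(self):
        pdb, _ = make_ligand(FixtureSpec("ring", {"n": 6}))
        st = parse_pdb(pdb)
        lig = detect_ligands(st)[0]
        g = build_graph(lig, components={}, structure=st)
        assert g.n_bonds == 6  # inferred from 1.5 A geometry
        with pytest.raises(GraphBuildError):
            build_graph(lig, components={}, structure=st,
                        allow_distance_fallback=False)


class TestSSSR:
    def test_benzene_single_six_ring(self):
        rings = perceive_sssr(graph_of("ring", n=6))
        assert [len(r) for r in rings] == [6]

    def test_fused_bicyclic_two_six_rings(self):
        g = graph_of("fused_rings")
        rings = perceive_sssr(g)
        assert [len(r) for r in rings] == [6, 6]
        assert minimal_cycle_basis_sizes(g.g) == [6, 6]

    def test_pyrrolidine_fragment_ring_atoms(self):
        st = parse_pdb(EPO_LIKE_PDB)
        comps = parse_components(EPO_LIKE_COMPONENT)
        g = build_graph(detect_ligands(st)[0], comps, st)
        (ring,) = perceive_sssr(g)
        names = {g.atom(s).name for s in ring.atoms}
        assert names == {"N2", "CD3", "CG3", "CB1", "CA1"}

    def test_ring_count_identity_and_oracle_agreement(self):
        cases = [graph_of("ring", n=6).g, graph_of("fused_rings").g,
                 graph_of("linear_chain", n=5).g]
        # bridged bicyclo graph (two rings sharing a 2-edge bridge)
        bic = nx.Graph()
        bic.add_edges_from([(1, 2), (2, 3), (3, 4), (4, 5), (5, 6), (6, 1),
                            (2, 7), (7, 8), (8, 5)])
        cases.append(bic)
        for g in cases:
            rings = perceive_sssr(g)
            expect = g.number_of_edges() - g.number_of_nodes() \
                + nx.number_connected_components(g)
            assert len(rings) == expect
            assert sorted(len(r) for r in rings) \
                == minimal_cycle_basis_sizes(g)
            # second independent oracle: networkx minimum cycle basis
            assert sorted(len(r) for r in rings) \
                == sorted(len(c) for c in nx.minimum_cycle_basis(g))

    def test_rings_are_cycles_in_the_graph(self):
        for g in (graph_of("fused_rings"), graph_of("macrocycle")):
            for ring in perceive_sssr(g):
                n = len(ring.atoms)
                for i in range(n):
                    assert g.has_bond(ring.atoms[i], ring.atoms[(i + 1) % n])

    def test_deterministic_ordering(self):
        g = graph_of("fused_rings")
        first = [r.atoms for r in perceive_sssr(g)]
        for _ in range(3):
            assert [r.atoms for r in perceive_sssr(g)] == first


class TestMacrocycles:
    def test_cyclic_peptide_flagged(self):
        rings = detect_macrocycles(perceive_sssr(graph_of("macrocycle")))
        assert [r.is_macrocycle for r in rings] == [True]
        assert len(rings[0]) == 30

    def test_benzene_not_flagged(self):
        rings = detect_macrocycles(perceive_sssr(graph_of("ring", n=6)))
        assert rings[0].is_macrocycle is False

    @pytest.mark.parametrize("n,expected", [
        (MACROCYCLE_SIZE - 1, False), (MACROCYCLE_SIZE, True), (12, True)])
    def test_threshold_boundary(self, n, expected):
        rings = detect_macrocycles(perceive_sssr(graph_of("ring", n=n)))
        assert rings[0].is_macrocycle is expected


class TestPartition:
    def test_epo_like_elements(self):
        st = parse_pdb(EPO_LIKE_PDB)
        comps = parse_components(EPO_LIKE_COMPONENT)
        g = build_graph(detect_ligands(st)[0], comps, st)
        rings = detect_macrocycles(perceive_sssr(g))
        elements = partition(g, rings)
        kinds = {}
        for e in elements:
            kinds.setdefault(e.kind, []).append(
                sorted(g.atom(s).name for s in e.atoms))
        assert len(kinds["ring"]) == 1
        (chain,) = kinds["chain"]
        assert "CB" in chain and "CA" in chain
        terminals = {n for grp in kinds["terminal_atom"] for n in grp}
        assert {"O", "CG1", "CG2"} <= terminals

    def test_linear_chain_core_plus_terminals(self):
        g = graph_of("linear_chain", n=5)
        elements = partition(g, perceive_sssr(g))
        by_kind = {}
        for e in elements:
            by_kind.setdefault(e.kind, []).append(e.atoms)
        assert by_kind["chain"] == [[2, 3, 4]]
        assert sorted(a for grp in by_kind["terminal_atom"] for a in grp) \
            == [1, 5]

    def test_single_metal_is_isolated(self):
        text = ("HETATM    1 ZN    ZN M   1       0.000   0.000   0.000"
                "  1.00  0.00          ZN\nEND\n")
        st = parse_pdb(text)
        lig = detect_ligands(st)[0]
        g = build_graph(lig, {}, st)
        elements = partition(g, perceive_sssr(g))
        assert [(e.kind, e.atoms) for e in elements] == [("isolated_atom", [1])]

    def test_coverage_of_all_atoms(self):
        for kind, params in [("ring", {"n": 6}), ("fused_rings", {}),
                             ("macrocycle", {}), ("linear_chain", {"n": 7})]:
            g = graph_of(kind, **params)
            elements = partition(
                g, detect_macrocycles(perceive_sssr(g)))
            covered = set()
            for e in elements:
                covered |= set(e.atoms)
            assert covered == set(g.g.nodes)
            # non-ring elements are pairwise disjoint
            seen = set()
            for e in elements:
                if e.kind == "ring":
                    continue
                assert not (set(e.atoms) & seen)
                seen |= set(e.atoms)
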
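from itertools import permutations

import numpy as np
import pytest

from ligdiagram import (InteractionConfig, detect_interactions,
                        find_hydrogen_bonds, find_nearby_residues,
                        find_water_bridges)
from ligdiagram.interactions import (assign_donors_acceptors,
                                     environment_atoms, water_oxygens)

from conftest import load_site


class TestNearbyResidues:
    def test_default_cutoff_separates_shells(self):
        st, comps, lig = load_site(shells=[("ALA", 3.9), ("SER", 4.1)])
        nearby = find_nearby_residues(lig, st)
        assert [n.residue_id[0] for n in nearby] == ["ALA"]
        assert nearby[0].min_distance == pytest.approx(3.9, abs=1e-6)

    def test_raised_cutoff_reports_both(self):
        st, comps, lig = load_site(shells=[("ALA", 3.9), ("SER", 4.1)])
        nearby = find_nearby_residues(
            lig, st, InteractionConfig(residue_cutoff=4.5))
        assert sorted(n.residue_id[0] for n in nearby) == ["ALA", "SER"]

    def test_empty_environment(self):
        st, comps, lig = load_site()
        assert find_nearby_residues(lig, st) == []

    def test_monotone_in_cutoff(self):
        st, comps, lig = load_site(
            shells=[("ALA", 3.2), ("SER", 3.9), ("GLY", 4.4)])
        prev = set()
        for cutoff in (3.0, 3.5, 4.0, 4.6):
            cur = {n.residue_id for n in find_nearby_residues(
                lig, st, InteractionConfig(residue_cutoff=cutoff))}
            assert prev <= cur
            prev = cur

    def test_distances_match_independent_recomputation(self):
        st, comps, lig = load_site(shells=[("ALA", 3.4), ("CYS", 3.8)])
        for n in find_nearby_residues(lig, st):
            la, ra = n.closest_atom_pair
            d = float(np.linalg.norm(la.coords - ra.coords))
            assert n.min_distance == pytest.approx(d, abs=1e-9)


class TestDonorsAcceptors:
    def test_typing_from_components(self):
        st, comps, lig = load_site(shells=[("ASP", 3.5), ("SER", 3.6)])
        flags = assign_donors_acceptors(st.atoms, comps)
        by_name = {(a.residue_name, a.name): flags[a.serial]
                   for a in st.atoms}
        assert by_name[("ASP", "OD1")] == (False, True)   # carbonyl-like O
        assert by_name[("SER", "OG")] == (True, True)     # hydroxyl O
        assert by_name[("SLG", "O1")] == (True, True)     # ligand hydroxyl
        assert by_name[("SLG", "C1")] == (False, False)   # aliphatic C

    def test_no_component_is_permissive(self):
        st, comps, lig = load_site(waters=[1])
        flags = assign_donors_acceptors(water_oxygens(st), components=None)
        assert all(f == (True, True) for f in flags.values())


class TestHydrogenBonds:
    def _bonds(self, dist, angle, **cfg):
        st, comps, lig = load_site(hbond_geometries=[(dist, angle)])
        env = environment_atoms(st, lig)
        return find_hydrogen_bonds(lig.atoms, env, comps,
                                   InteractionConfig(**cfg) if cfg else None)

    def test_accepted_below_angle_bound(self):
        bonds = self._bonds(3.0, 60.0)
        assert len(bonds) == 1
        hb = bonds[0]
        assert hb.donor.name == "NZ"
        assert hb.acceptor.name == "O1"
        assert hb.acceptor_neighbour.name == "C3"
        assert hb.distance == pytest.approx(3.0, abs=2e-3)
        assert hb.angle == pytest.approx(60.0, abs=0.05)

    def test_rejected_at_or_above_angle_bound(self):
        assert self._bonds(3.0, 120.0) == []

    def test_rejected_beyond_distance_cutoff(self):
        assert self._bonds(3.5, 60.0) == []
        assert len(self._bonds(3.5, 60.0, hbond_cutoff=3.6)) == 1

    def test_duplicate_pairs_reported_once(self):
        bonds = self._bonds(3.0, 45.0)
        keys = [(b.donor.serial, b.acceptor.serial) for b in bonds]
        assert len(keys) == len(set(keys))


class TestWaterBridges:
    def test_bridge_lengths_one_to_four_only(self):
        st, comps, lig = load_site(waters=[1, 2, 3, 4, 5, 6])
        bridges = find_water_bridges(
            lig.atoms, environment_atoms(st, lig), water_oxygens(st), comps)
        # designed (per-SER) bridges: one per serine, lengths 1..4 pass
        per_ser = {}
        for b in bridges:
            rid = b.residue_atom.residue_id
            if b.residue_atom.name == "OG":
                per_ser.setdefault(rid, []).append(len(b.waters))
        direct = {rid: lens for rid, lens in per_ser.items()}
        reported = sorted(min(v) for v in direct.values())
        assert reported == [1, 2, 3, 4]
        assert all(max(v) <= 4 for v in direct.values())

    def test_single_water_at_3p2_accepted(self):
        st, comps, lig = load_site(waters=[1], water_first_leg=3.2)
        bridges = find_water_bridges(
            lig.atoms, environment_atoms(st, lig), water_oxygens(st), comps)
        assert any(len(b.waters) == 1 for b in bridges)

    def test_water_beyond_radius_excluded(self):
        st, comps, lig = load_site(waters=[1], water_first_leg=3.4)
        bridges = find_water_bridges(
            lig.atoms, environment_atoms(st, lig), water_oxygens(st), comps)
        assert bridges == []

    def test_step_distances_within_radius_and_exact(self):
        st, comps, lig = load_site(waters=[2])
        bridges = find_water_bridges(
            lig.atoms, environment_atoms(st, lig), water_oxygens(st), comps)
        for b in bridges:
            assert all(d <= 3.3 for d in b.step_distances)
            chain = [b.ligand_atom, *b.waters, b.residue_atom]
            for (a, c), d in zip(zip(chain, chain[1:]), b.step_distances):
                assert d == pytest.approx(
                    float(np.linalg.norm(a.coords - c.coords)), abs=1e-9)


# --------------------------------------------------- brute-force oracle

def _oracle(st, comps, lig, cfg):
    """Exhaustive pair/path enumeration, independent of the detectors."""
    lig_atoms = [a for a in lig.atoms if a.element != "H"]
    member = {a.serial for a in lig_atoms}
    env = [a for a in st.atoms if a.serial not in member and not a.is_water
           and not a.is_het and a.element != "H"]
    waters = [a for a in st.atoms if a.is_water and a.element == "O"]

    def dist(a, b):
        return float(np.linalg.norm(a.coords - b.coords))

    nearby = {}
    for a in env:
        d = min(dist(a, la) for la in lig_atoms)
        rid = a.residue_id
        nearby[rid] = min(nearby.get(rid, np.inf), d)
    nearby = {rid: d for rid, d in nearby.items()
              if d <= cfg.residue_cutoff}

    def roles(a):
        comp = comps.get(a.residue_name)
        if a.element not in "NOS" or a.element == "":
            return (False, False)
        if comp is None or a.name not in comp.atoms:
            return (True, True)
        nh = comp.hydrogen_count(a.name)
        if a.element == "O":
            return (nh > 0, True)
        if a.element == "N":
            return (nh > 0, nh == 0)
        return (True, True)

    def neighbours(a, pool):
        cut = lambda x, y: 2.4 if "S" in (x.element, y.element) else 1.9
        return [b for b in pool
                if b.residue_id == a.residue_id and b.serial != a.serial
                and dist(a, b) < cut(a, b)]

    hbonds = set()
    for d_pool, a_pool in ((lig_atoms, env), (env, lig_atoms)):
        for D in d_pool:
            if not roles(D)[0]:
                continue
            for A in a_pool:
                if not roles(A)[1] or dist(D, A) > cfg.hbond_cutoff:
                    continue
                aas = neighbours(A, lig_atoms if A in lig_atoms else env)
                ok = not aas
                for aa in aas:
                    v1, v2 = D.coords - A.coords, aa.coords - A.coords
                    ang = np.degrees(np.arccos(np.clip(
                        np.dot(v1, v2) / np.linalg.norm(v1)
                        / np.linalg.norm(v2), -1, 1)))
                    if ang < cfg.hbond_angle_max:
                        ok = True
                if ok:
                    hbonds.add((D.serial, A.serial))

    bridges = set()
    lig_da = [a for a in lig_atoms if any(roles(a))]
    env_da = [a for a in env if any(roles(a))]
    for L in lig_da:
        for R in env_da:
            for k in range(1, cfg.max_bridge_waters + 1):
                for combo in permutations(waters, k):
                    chain = [L, *combo, R]
                    if all(dist(x, y) <= cfg.water_radius
                           for x, y in zip(chain, chain[1:])):
                        bridges.add((L.serial,
                                     tuple(w.serial for w in combo),
                                     R.serial))
    return nearby, hbonds, bridges


class TestBruteForceOracle:
    @pytest.mark.parametrize("kw", [
        dict(shells=[("ALA", 3.9), ("SER", 4.1)]),
        dict(hbond_geometries=[(3.0, 60.0), (3.2, 110.0)]),
        dict(waters=[1, 2]),
        dict(shells=[("ASP", 3.5)], hbond_geometries=[(2.9, 40.0)],
             waters=[2]),
    ])
    def test_detectors_match_exhaustive_enumeration(self, kw):
        st, comps, lig = load_site(**kw)
        assert len(st.atoms) <= 50
        cfg = InteractionConfig()
        iset = detect_interactions(lig, st, comps, cfg)
        nearby, hbonds, bridges = _oracle(st, comps, lig, cfg)
        assert {n.residue_id: n.min_distance for n in iset.nearby_residues} \
            == pytest.approx(nearby)
        assert {(h.donor.serial, h.acceptor.serial)
                for h in iset.hbonds} == hbonds
        assert {(b.ligand_atom.serial,
                 tuple(w.serial for w in b.waters),
                 b.residue_atom.serial)
                for b in iset.water_bridges} == bridges

    def test_no_interaction_involves_hydrogen_or_water(self):
        st, comps, lig = load_site(shells=[("SER", 3.2)], waters=[2])
        iset = detect_interactions(lig, st, comps)
        for h in iset.hbonds:
            assert h.donor.element != "H" and not h.donor.is_water
            assert h.acceptor.element != "H" and not h.acceptor.is_water
        for n in iset.nearby_residues:
            assert n.residue_id[0] not in ("HOH", "WAT", "DOD")
        for b in iset.water_bridges:
            assert not b.ligand_atom.is_water
            assert not b.residue_atom.is_water
            assert all(w.is_water for w in b.waters)
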
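"""Ligand and metal-ion identification in a parsed structure.

Candidate ligand residues are HETATM residues that are not waters and not
modified polymer residues (HETATM groups embedded in a polymer chain).
Candidates joined by LINK records, CONECT records, or heavy-atom pairs at
covalent distance are merged into one composite ligand, so multi-residue
ligands (including cyclic peptides) come out as a single entity.  A lone
atom of a metallic element is reported as a metal-ion ligand.  Polymer
residues covalently LINKed to a ligand are recorded as explicit residues:
they are drawn with the ligand but are not ligand members.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .pdb_io import Atom, Structure

#: common biologically relevant metals
METALS = frozenset({"NA", "K", "MG", "CA", "MN", "FE", "CO", "NI",
                    "CU", "ZN", "MO", "CD", "HG"})

#: inter-residue covalent bond inference thresholds (Angstrom)
COVALENT_DISTANCE = 1.9
COVALENT_DISTANCE_S = 2.4  # if either atom is sulfur

ResidueId = tuple[str, str, int]  # (residue_name, chain_id, residue_seq)


class LigandSelectionError(ValueError):
    """Raised when a user-specified residue range cannot be resolved."""


@dataclass
class LigandInstance:
    residues: list[ResidueId]
    atoms: list[Atom]
    is_metal: bool = False
    explicit_residues: list[ResidueId] = field(default_factory=list)
    #: covalent attachments to explicit residues: (ligand atom, residue atom)
    explicit_anchors: list[tuple[Atom, Atom]] = field(default_factory=list)

    @property
    def label(self) -> str:
        name, chain, seq = self.residues[0]
        if len(self.residues) == 1:
            return f"{name} {chain}:{seq}"
        last = self.residues[-1]
        return f"{name} {chain}:{seq}-{last[2]}"

    def atom_serials(self) -> set[int]:
        return {a.serial for a in self.atoms}


def _covalent_cut(e1: str, e2: str) -> float:
    return COVALENT_DISTANCE_S if "S" in (e1, e2) else COVALENT_DISTANCE


def _residue_heavy(atoms: list[Atom]) -> list[Atom]:
    return [a for a in atoms if not a.is_hydrogen]


def _polymer_flanked(rid: ResidueId, atoms_by_res, polymer_seqs) -> bool:
    """HETATM residue sandwiched in a polymer chain => modified residue."""
    _, chain, seq = rid
    seqs = polymer_seqs.get(chain, set())
    return (seq - 1 in seqs) and (seq + 1 in seqs)


def detect_ligands(structure: Structure) -> list[LigandInstance]:
    """Identify ligands and metal ions; waters never qualify."""
    residues = structure.residues()
    polymer_seqs: dict[str, set[int]] = {}
    for (name, chain, seq), atoms in residues.items():
        if any(not a.is_het for a in atoms):
            polymer_seqs.setdefault(chain, set()).add(seq)

    candidates = [rid for rid, atoms in residues.items()
                  if all(a.is_het for a in atoms)
                  and not atoms[0].is_water
                  and not _polymer_flanked(rid, residues, polymer_seqs)]
    cand_set = set(candidates)
    serial_to_res = {a.serial: a.residue_id for a in structure.atoms}

    # union-find over candidate residues
    parent = {rid: rid for rid in candidates}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb, key=str)] = min(ra, rb, key=str)

    explicit_links: dict[ResidueId, list[tuple[Atom, Atom, ResidueId]]] = {}

    def register_bond(a1: Atom, a2: Atom) -> None:
        r1, r2 = a1.residue_id, a2.residue_id
        if r1 == r2:
            return
        in1, in2 = r1 in cand_set, r2 in cand_set
        if in1 and in2:
            union(r1, r2)
        elif in1 != in2:  # candidate <-> polymer: explicit residue
            lig_res, lig_atom, other_atom, other_res = (
                (r1, a1, a2, r2) if in1 else (r2, a2, a1, r1))
            if other_res in polymer_seqs_residues(polymer_seqs, other_res):
                explicit_links.setdefault(lig_res, []).append(
                    (lig_atom, other_atom, other_res))

    def polymer_seqs_residues(pseqs, rid):
        return {rid} if rid[2] in pseqs.get(rid[1], set()) else set()

    for link in structure.links:
        a1 = structure.find_link_atom(link.atom1)
        a2 = structure.find_link_atom(link.atom2)
        if a1 is not None and a2 is not None:
            register_bond(a1, a2)
    for serial, partners in structure.conect.items():
        for p in partners:
            if serial < p and serial in serial_to_res and p in serial_to_res:
                register_bond(structure.atom_by_serial(serial),
                              structure.atom_by_serial(p))

    # distance-based covalent inference among candidate residues
    cand_atoms = [a for a in structure.atoms
                  if a.residue_id in cand_set and not a.is_hydrogen]
    if cand_atoms:
        coords = np.array([a.coords for a in cand_atoms])
        n = len(cand_atoms)
        d2 = np.sum((coords[:, None, :] - coords[None, :, :]) ** 2, axis=-1)
        for i in range(n):
            for j in range(i + 1, n):
                ai, aj = cand_atoms[i], cand_atoms[j]
                if ai.residue_id == aj.residue_id:
                    continue
                cut = _covalent_cut(ai.element, aj.element)
                if d2[i, j] < cut * cut:
                    union(ai.residue_id, aj.residue_id)

    groups: dict[ResidueId, list[ResidueId]] = {}
    for rid in candidates:
        groups.setdefault(find(rid), []).append(rid)

    out = []
    for root in sorted(groups, key=_res_sort_key):
        members = sorted(groups[root], key=_res_sort_key)
        atoms = [a for rid in members for a in _residue_heavy(residues[rid])]
        is_metal = len(atoms) == 1 and atoms[0].element in METALS
        expl, anchors = [], []
        for rid in members:
            for lig_atom, other_atom, other_res in explicit_links.get(rid, []):
                if other_res not in expl:
                    expl.append(other_res)
                anchors.append((lig_atom, other_atom))
        out.append(LigandInstance(residues=members, atoms=atoms,
                                  is_metal=is_metal,
                                  explicit_residues=expl,
                                  explicit_anchors=anchors))
    return out


def _res_sort_key(rid: ResidueId):
    name, chain, seq = rid
    return (chain, seq, name)


def select_composite(structure: Structure,
                     residue_range: tuple[str, int, int]) -> LigandInstance:
    """Build a user-specified composite ligand from an inclusive seq range."""
    chain, first, last = residue_range
    if last < first:
        raise LigandSelectionError(
            f"reversed range {chain}:{first}-{last} (last < first)")
    residues = structure.residues()
    members, atoms = [], []
    for seq in range(first, last + 1):
        hit = [rid for rid in residues
               if rid[1] == chain and rid[2] == seq
               and not residues[rid][0].is_water]
        if not hit:
            raise LigandSelectionError(
                f"no residue {chain}:{seq} in structure")
        for rid in sorted(hit, key=_res_sort_key):
            members.append(rid)
            atoms.extend(_residue_heavy(residues[rid]))
    return LigandInstance(residues=members, atoms=atoms,
                          is_metal=(len(atoms) == 1
                                    and atoms[0].element in METALS))
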
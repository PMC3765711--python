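"""Reading PDB coordinate files and chemical-component definitions.

PDB coordinate files carry atom positions but no bond orders; bond orders
come from per-residue chemical-component definitions (CCD/PDBeChem-style
mmCIF blocks with ``_chem_comp_atom`` and ``_chem_comp_bond`` loops).
Parsing is delegated to :mod:`gemmi`; this module flattens the result into
a small, explicit structure model suited to ligand-diagram generation:

* only MODEL 1 of multi-model files is kept,
* only the first alternate location of each atom is kept,
* waters (HOH/WAT/DOD) are flagged,
* hydrogens are parsed but downstream geometry ignores them.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import gemmi
import numpy as np

WATER_NAMES = frozenset({"HOH", "WAT", "DOD"})

#: bond-order vocabulary used throughout the package
BOND_ORDERS = ("single", "double", "triple", "aromatic")

_ORDER_ALIASES = {
    "sing": "single", "single": "single", "1": "single",
    "doub": "double", "double": "double", "2": "double",
    "trip": "triple", "triple": "triple", "3": "triple",
    "arom": "aromatic", "aromatic": "aromatic", "ar": "aromatic",
    "delo": "aromatic",
}


class PDBParseError(ValueError):
    """Raised for unreadable or empty coordinate input."""


class ComponentError(ValueError):
    """Raised for an inconsistent chemical-component definition."""


@dataclass(frozen=True)
class Atom:
    serial: int
    name: str
    element: str
    coords: np.ndarray  # (3,) in Angstrom
    residue_name: str
    residue_seq: int
    chain_id: str
    is_het: bool
    alt_loc: str = ""
    occupancy: float = 1.0

    @property
    def is_water(self) -> bool:
        return self.residue_name in WATER_NAMES

    @property
    def is_hydrogen(self) -> bool:
        return self.element in ("H", "D")

    @property
    def residue_id(self) -> tuple[str, str, int]:
        """(residue_name, chain_id, residue_seq) key."""
        return (self.residue_name, self.chain_id, self.residue_seq)

    def __repr__(self) -> str:  # compact, used in error messages
        return (f"Atom({self.serial} {self.name} "
                f"{self.residue_name}{self.residue_seq}:{self.chain_id})")


@dataclass(frozen=True)
class LinkRecord:
    """A LINK record: explicit inter-residue connectivity."""

    atom1: tuple[str, str, str, int]  # (atom_name, residue_name, chain_id, seq)
    atom2: tuple[str, str, str, int]
    distance: float | None = None


@dataclass
class Structure:
    atoms: list[Atom]
    links: list[LinkRecord] = field(default_factory=list)
    conect: dict[int, set[int]] = field(default_factory=dict)
    ss_segments: list[tuple[str, str, int, int]] = field(default_factory=list)
    # ss_segments: (kind 'helix'|'sheet', chain_id, first_seq, last_seq)

    def __post_init__(self) -> None:
        self._by_serial = {a.serial: a for a in self.atoms}

    def atom_by_serial(self, serial: int) -> Atom:
        return self._by_serial[serial]

    def residues(self) -> dict[tuple[str, str, int], list[Atom]]:
        """Atoms grouped by (residue_name, chain_id, residue_seq), file order."""
        out: dict[tuple[str, str, int], list[Atom]] = {}
        for a in self.atoms:
            out.setdefault(a.residue_id, []).append(a)
        return out

    def find_link_atom(self, endpoint: tuple[str, str, str, int]) -> Atom | None:
        name, res_name, chain, seq = endpoint
        for a in self.atoms:
            if (a.name == name and a.residue_name == res_name
                    and a.chain_id == chain and a.residue_seq == seq):
                return a
        return None

    def secondary_structure(self, chain_id: str, seq: int) -> str:
        for kind, ch, first, last in self.ss_segments:
            if ch == chain_id and first <= seq <= last:
                return kind
        return "coil"


@dataclass
class ComponentDefinition:
    """Atom names/elements and bond orders for one residue type."""

    comp_id: str
    atoms: dict[str, str]                      # atom name -> element symbol
    bonds: list[tuple[str, str, str]]          # (name1, name2, order)

    def __post_init__(self) -> None:
        seen: set[frozenset[str]] = set()
        for a1, a2, order in self.bonds:
            for a in (a1, a2):
                if a not in self.atoms:
                    raise ComponentError(
                        f"component {self.comp_id}: bond references "
                        f"undefined atom {a!r}")
            if order not in BOND_ORDERS:
                raise ComponentError(
                    f"component {self.comp_id}: unknown bond order {order!r}")
            key = frozenset((a1, a2))
            if key in seen:
                raise ComponentError(
                    f"component {self.comp_id}: duplicate bond {a1}-{a2}")
            seen.add(key)

    def heavy_atoms(self) -> dict[str, str]:
        return {n: e for n, e in self.atoms.items() if e not in ("H", "D")}

    def heavy_bonds(self) -> list[tuple[str, str, str]]:
        heavy = self.heavy_atoms()
        return [(a, b, o) for a, b, o in self.bonds if a in heavy and b in heavy]

    def hydrogen_count(self, atom_name: str) -> int:
        n = 0
        for a, b, _ in self.bonds:
            other = b if a == atom_name else a if b == atom_name else None
            if other is not None and self.atoms.get(other) in ("H", "D"):
                n += 1
        return n

    def bond_orders_of(self, atom_name: str) -> list[str]:
        """Orders of heavy-atom bonds incident to ``atom_name``."""
        heavy = self.heavy_atoms()
        out = []
        for a, b, o in self.bonds:
            other = b if a == atom_name else a if b == atom_name else None
            if other is not None and other in heavy:
                out.append(o)
        return out


def parse_pdb(text: str) -> Structure:
    """Parse PDB v3.3 fixed-width text into a :class:`Structure`.

    Keeps model 1 only and the first alternate location per atom.
    Raises :class:`PDBParseError` on empty input or unreadable records.
    """
    if not any(line.startswith(("ATOM  ", "HETATM")) for line in text.splitlines()):
        raise PDBParseError("no ATOM or HETATM records in input")
    try:
        st = gemmi.read_pdb_string(text)
    except (RuntimeError, ValueError) as exc:  # gemmi reports line numbers
        raise PDBParseError(f"unreadable PDB record: {exc}") from exc

    atoms: list[Atom] = []
    seen_altloc: set[tuple[str, int, str, str]] = set()
    model = st[0]
    for chain in model:
        for res in chain:
            for at in res:
                key = (chain.name, res.seqid.num, res.name, at.name)
                if key in seen_altloc:
                    continue  # keep first alt-loc only
                seen_altloc.add(key)
                atoms.append(Atom(
                    serial=at.serial,
                    name=at.name,
                    element=at.element.name.upper(),
                    coords=np.array([at.pos.x, at.pos.y, at.pos.z]),
                    residue_name=res.name,
                    residue_seq=res.seqid.num,
                    chain_id=chain.name,
                    is_het=(res.het_flag == "H"),
                    alt_loc="" if at.altloc == "\x00" else at.altloc,
                    occupancy=at.occ,
                ))

    links = []
    for con in st.connections:
        if con.type == gemmi.ConnectionType.Hydrog:
            continue
        p1, p2 = con.partner1, con.partner2
        e1 = (p1.atom_name, p1.res_id.name, p1.chain_name, p1.res_id.seqid.num)
        e2 = (p2.atom_name, p2.res_id.name, p2.chain_name, p2.res_id.seqid.num)
        if e1 == e2:
            continue
        dist = con.reported_distance if con.reported_distance > 0 else None
        links.append(LinkRecord(atom1=e1, atom2=e2, distance=dist))

    conect: dict[int, set[int]] = {}
    for serial, partners in st.conect_map.items():
        for p in partners:
            conect.setdefault(serial, set()).add(p)
            conect.setdefault(p, set()).add(serial)  # enforce symmetry

    ss: list[tuple[str, str, int, int]] = []
    for h in st.helices:
        ss.append(("helix", h.start.chain_name,
                   h.start.res_id.seqid.num, h.end.res_id.seqid.num))
    for sheet in st.sheets:
        for strand in sheet.strands:
            ss.append(("sheet", strand.start.chain_name,
                       strand.start.res_id.seqid.num,
                       strand.end.res_id.seqid.num))

    return Structure(atoms=atoms, links=links, conect=conect, ss_segments=ss)


def write_pdb(structure: Structure) -> str:
    """Minimal PDB writer (ATOM/HETATM/LINK/CONECT), used for round-trips."""
    lines = []
    for lk in structure.links:
        n1, r1, c1, s1 = lk.atom1
        n2, r2, c2, s2 = lk.atom2
        dist = f"{lk.distance:5.2f}" if lk.distance is not None else "     "
        lines.append(f"LINK        {_fmt_name(n1)} {r1:<3s} {c1}{s1:4d}       "
                     f"         {_fmt_name(n2)} {r2:<3s} {c2}{s2:4d}    "
                     f" 1555   1555 {dist}")
    for a in structure.atoms:
        rec = "HETATM" if a.is_het else "ATOM  "
        x, y, z = a.coords
        lines.append(
            f"{rec}{a.serial:5d} {_fmt_name(a.name)}{a.alt_loc or ' '}"
            f"{a.residue_name:<3s} {a.chain_id}{a.residue_seq:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{a.occupancy:6.2f}  0.00"
            f"          {a.element:>2s}")
    for serial in sorted(structure.conect):
        partners = sorted(structure.conect[serial])
        for i in range(0, len(partners), 4):
            chunk = "".join(f"{p:5d}" for p in partners[i:i + 4])
            lines.append(f"CONECT{serial:5d}{chunk}")
    lines.append("END")
    return "\n".join(lines) + "\n"


def _fmt_name(name: str) -> str:
    # PDB columns 13-16: names of <=3 chars start in column 14
    return f" {name:<3s}" if len(name) < 4 else name


def parse_component(text: str) -> ComponentDefinition:
    """Parse one mmCIF chemical-component block into a definition."""
    try:
        doc = gemmi.cif.read_string(text)
    except (RuntimeError, ValueError) as exc:
        raise ComponentError(f"unreadable component block: {exc}") from exc
    block = doc.sole_block()
    comp_id = block.find_value("_chem_comp.id") or block.name

    atoms: dict[str, str] = {}
    for row in block.find("_chem_comp_atom.", ["comp_id", "atom_id", "type_symbol"]):
        atoms[gemmi.cif.as_string(row[1])] = gemmi.cif.as_string(row[2]).upper()
    if not atoms:
        raise ComponentError(f"component {comp_id}: no _chem_comp_atom loop")

    bonds: list[tuple[str, str, str]] = []
    for row in block.find("_chem_comp_bond.",
                          ["atom_id_1", "atom_id_2", "value_order"]):
        raw = gemmi.cif.as_string(row[2]).lower()
        order = _ORDER_ALIASES.get(raw)
        if order is None:
            raise ComponentError(
                f"component {comp_id}: unknown bond order {raw!r}")
        bonds.append((gemmi.cif.as_string(row[0]),
                      gemmi.cif.as_string(row[1]), order))

    return ComponentDefinition(comp_id=comp_id, atoms=atoms, bonds=bonds)


def parse_components(text: str) -> dict[str, ComponentDefinition]:
    """Parse a multi-block component file into a comp_id -> definition map."""
    doc = gemmi.cif.read_string(text)
    out = {}
    for block in doc:
        comp = parse_component(block.as_string())
        out[comp.comp_id] = comp
    return out


def load_component_dir(path: str) -> dict[str, ComponentDefinition]:
    """Load every ``*.cif`` file under ``path``, keyed by component id."""
    out: dict[str, ComponentDefinition] = {}
    for fname in sorted(os.listdir(path)):
        if not fname.endswith(".cif"):
            continue
        with open(os.path.join(path, fname)) as fh:
            out.update(parse_components(fh.read()))
    return out
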
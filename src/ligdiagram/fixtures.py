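"""Synthetic PDB fixtures with controlled geometry.

Every downstream stage — graph building, ring perception, 2D layout,
interaction detection, placement — is exercised on structures generated
here, so no external data is ever needed.  Generated sites place each
feature (shell residue, water chain, donor/acceptor pair, covalent
residue) along its own well-separated direction from the ligand so the
requested distances and angles are realized exactly and independent
features do not interfere.

Pseudo-residues are deliberately minimal (3-5 heavy atoms): the geometric
criteria downstream only consume positions, names and elements, never
full amino-acid chemistry.  Output is deterministic: the same spec and
seed produce byte-identical text.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

LIGAND_KINDS = ("linear_chain", "ring", "fused_rings", "macrocycle")
SITE_KINDS = ("hbond_pair", "water_chain", "covalent_link", "full_site")

BOND_3D = 1.5  # Angstrom, typical heavy-atom bond length


class FixtureError(ValueError):
    """Raised for an unsupported or geometrically unrealizable request."""


@dataclass(frozen=True)
class FixtureSpec:
    kind: str
    parameters: dict[str, Any] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in LIGAND_KINDS + SITE_KINDS:
            raise FixtureError(f"unsupported fixture kind {self.kind!r}")


# ---------------------------------------------------------------- PDB text

def _het_line(serial: int, name: str, res: str, chain: str, seq: int,
              xyz: np.ndarray, element: str, record: str = "HETATM") -> str:
    x, y, z = xyz
    nm = f" {name:<3s}" if len(name) < 4 else name
    return (f"{record}{serial:5d} {nm} {res:<3s} {chain}{seq:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          {element:>2s}")


def _link_line(a1: tuple[str, str, str, int], a2: tuple[str, str, str, int],
               dist: float) -> str:
    n1, r1, c1, s1 = a1
    n2, r2, c2, s2 = a2
    f1 = f" {n1:<3s}" if len(n1) < 4 else n1
    f2 = f" {n2:<3s}" if len(n2) < 4 else n2
    return (f"LINK        {f1} {r1:<3s} {c1}{s1:4d}                "
            f"{f2} {r2:<3s} {c2}{s2:4d}     1555   1555 {dist:5.2f}")


def _component_block(comp_id: str, atoms: dict[str, str],
                     bonds: list[tuple[str, str, str]]) -> str:
    order_out = {"single": "SING", "double": "DOUB",
                 "triple": "TRIP", "aromatic": "AROM"}
    lines = [f"data_{comp_id}",
             f"_chem_comp.id {comp_id}",
             "loop_",
             "_chem_comp_atom.comp_id",
             "_chem_comp_atom.atom_id",
             "_chem_comp_atom.type_symbol"]
    for name, el in atoms.items():
        lines.append(f"{comp_id} {name} {el}")
    if bonds:
        lines += ["loop_",
                  "_chem_comp_bond.comp_id",
                  "_chem_comp_bond.atom_id_1",
                  "_chem_comp_bond.atom_id_2",
                  "_chem_comp_bond.value_order"]
        for a1, a2, order in bonds:
            lines.append(f"{comp_id} {a1} {a2} {order_out[order]}")
    return "\n".join(lines) + "\n"


# --------------------------------------------------------- ligand geometry

def _chain_coords(n: int, bond: float = BOND_3D,
                  angle_deg: float = 109.5) -> np.ndarray:
    """Planar zig-zag with the given interior angle; advances along +x."""
    half = np.radians(180.0 - angle_deg) / 2.0
    pts = [np.zeros(3)]
    for i in range(1, n):
        sign = 1.0 if i % 2 else -1.0
        step = bond * np.array([np.cos(half), sign * np.sin(half), 0.0])
        pts.append(pts[-1] + step)
    return np.array(pts)


def _ring_coords(n: int, bond: float = BOND_3D,
                 center: np.ndarray | None = None) -> np.ndarray:
    radius = bond / (2.0 * np.sin(np.pi / n))
    c = np.zeros(3) if center is None else center
    ang = 2.0 * np.pi * np.arange(n) / n
    return c + np.stack([radius * np.cos(ang), radius * np.sin(ang),
                         np.zeros(n)], axis=1)


def make_ligand(spec: FixtureSpec) -> tuple[str, str]:
    """Generate (PDB text, component text) for a free-standing ligand."""
    if spec.kind not in LIGAND_KINDS:
        raise FixtureError(f"make_ligand does not support kind {spec.kind!r}")
    p = spec.parameters
    if spec.kind == "linear_chain":
        n = int(p.get("n", 5))
        if n < 2:
            raise FixtureError("linear_chain needs n >= 2")
        coords = _chain_coords(n)
        names = [f"C{i+1}" for i in range(n)]
        elements = ["C"] * n
        bonds = [(names[i], names[i + 1], "single") for i in range(n - 1)]
        comp_id = p.get("comp_id", "LCH")
    elif spec.kind == "ring":
        n = int(p.get("n", 6))
        if n < 3:
            raise FixtureError("ring needs n >= 3")
        coords = _ring_coords(n)
        names = [f"C{i+1}" for i in range(n)]
        elements = ["C"] * n
        order = p.get("order", "aromatic" if n == 6 else "single")
        bonds = [(names[i], names[(i + 1) % n], order) for i in range(n)]
        comp_id = p.get("comp_id", "RNG")
    elif spec.kind == "fused_rings":
        # naphthalene-like: two hexagons sharing the C1-C2 edge; the
        # second hexagon's centre is the reflection of the first's
        # across the shared edge, i.e. v1 + v2 for a centred hexagon
        hexa = _ring_coords(6)
        hexb = _ring_coords(6, center=hexa[0] + hexa[1])
        coords = list(hexa)
        names = [f"C{i+1}" for i in range(6)]
        ring_b_names = [names[0], names[1]]
        k = 7
        for v in hexb:
            if min(np.linalg.norm(v - u) for u in hexa[:2]) < 1e-6:
                continue  # shared vertex
            coords.append(v)
            names.append(f"C{k}")
            ring_b_names.append(f"C{k}")
            k += 1
        coords = np.array(coords)
        elements = ["C"] * len(coords)
        bonds = [(names[i], names[(i + 1) % 6], "aromatic") for i in range(6)]
        second = _order_ring_by_distance(coords, names, ring_b_names)
        have = {frozenset(b[:2]) for b in bonds}
        for i in range(len(second)):
            a, b = second[i], second[(i + 1) % len(second)]
            if frozenset((a, b)) not in have:
                bonds.append((a, b, "aromatic"))
        comp_id = p.get("comp_id", "FUS")
    else:  # macrocycle
        return _make_macrocycle(spec)

    chain = p.get("chain_id", "A")
    seq = int(p.get("residue_seq", 401))
    lines = []
    for i, (nm, el) in enumerate(zip(names, elements)):
        lines.append(_het_line(i + 1, nm, comp_id, chain, seq, coords[i], el))
    lines.append("END")
    comp_text = _component_block(comp_id, dict(zip(names, elements)), bonds)
    return "\n".join(lines) + "\n", comp_text


def _order_ring_by_distance(coords: np.ndarray, names: list[str],
                            members: list[str]) -> list[str]:
    """Order ring member names by nearest-neighbour walking (~bond length)."""
    idx = {n: i for i, n in enumerate(names)}
    remaining = members[1:]
    ordered = [members[0]]
    while remaining:
        last = coords[idx[ordered[-1]]]
        nxt = min(remaining, key=lambda n: np.linalg.norm(coords[idx[n]] - last))
        ordered.append(nxt)
        remaining.remove(nxt)
    return ordered


def _make_macrocycle(spec: FixtureSpec) -> tuple[str, str]:
    """Cyclic pseudo-peptide: ``n_residues`` 3-atom (N, CA, C) backbones
    arranged head-to-tail on one large ring, closed by LINK records."""
    p = spec.parameters
    n_res = int(p.get("n_residues", 10))
    if n_res < 2:
        raise FixtureError("macrocycle needs n_residues >= 2")
    comp_id = p.get("comp_id", "MAA")
    chain = p.get("chain_id", "B")
    n_atoms = 3 * n_res
    coords = _ring_coords(n_atoms)
    lines, serial = [], 1
    for r in range(n_res):
        for j, nm in enumerate(("N", "CA", "C")):
            lines.append(_het_line(serial, nm, comp_id, chain, r + 1,
                                   coords[3 * r + j], nm[0]))
            serial += 1
    links = []
    for r in range(n_res):
        nxt = (r + 1) % n_res
        d = float(np.linalg.norm(coords[3 * r + 2] - coords[3 * nxt % n_atoms]))
        links.append(_link_line(("C", comp_id, chain, r + 1),
                                ("N", comp_id, chain, nxt + 1), d))
    text = "\n".join(links + lines + ["END"]) + "\n"
    comp = _component_block(comp_id, {"N": "N", "CA": "C", "C": "C"},
                            [("N", "CA", "single"), ("CA", "C", "single")])
    return text, comp


# ------------------------------------------------------------- site builder

#: pseudo-residue templates: name -> [(atom name, element, local offset)];
#: the first atom is the contact atom placed at the requested distance and
#: the local +x axis points away from the ligand
_RESIDUE_TEMPLATES = {
    "ALA": [("CB", "C", (0.0, 0.0, 0.0)), ("CA", "C", (1.5, 0.0, 0.0)),
            ("N", "N", (2.4, 1.2, 0.0)), ("C", "C", (2.4, -1.2, 0.0))],
    "SER": [("OG", "O", (0.0, 0.0, 0.0)), ("CB", "C", (1.4, 0.0, 0.0)),
            ("CA", "C", (2.3, 1.2, 0.0)), ("N", "N", (3.6, 1.1, 0.0))],
    "CYS": [("SG", "S", (0.0, 0.0, 0.0)), ("CB", "C", (1.8, 0.0, 0.0)),
            ("CA", "C", (2.7, 1.2, 0.0)), ("N", "N", (4.0, 1.1, 0.0))],
    "ASP": [("OD1", "O", (0.0, 0.0, 0.0)), ("CG", "C", (1.25, 0.0, 0.0)),
            ("OD2", "O", (1.9, 1.1, 0.0)), ("CB", "C", (2.0, -1.2, 0.0))],
    "LYS": [("NZ", "N", (0.0, 0.0, 0.0)), ("CE", "C", (1.5, 0.0, 0.0)),
            ("CD", "C", (2.4, 1.2, 0.0)), ("CG", "C", (3.9, 1.2, 0.0))],
    "GLY": [("CA", "C", (0.0, 0.0, 0.0)), ("N", "N", (1.5, 0.0, 0.0)),
            ("C", "C", (0.9, -1.2, 0.0))],
}

#: matching component definitions (hydrogens mark donors)
_TEMPLATE_COMPONENTS = {
    "ALA": ({"CB": "C", "CA": "C", "N": "N", "C": "C", "H": "H"},
            [("CB", "CA", "single"), ("CA", "N", "single"),
             ("CA", "C", "single"), ("N", "H", "single")]),
    "SER": ({"OG": "O", "CB": "C", "CA": "C", "N": "N",
             "HG": "H", "H": "H"},
            [("OG", "CB", "single"), ("CB", "CA", "single"),
             ("CA", "N", "single"), ("OG", "HG", "single"),
             ("N", "H", "single")]),
    "CYS": ({"SG": "S", "CB": "C", "CA": "C", "N": "N", "H": "H"},
            [("SG", "CB", "single"), ("CB", "CA", "single"),
             ("CA", "N", "single"), ("N", "H", "single")]),
    "ASP": ({"OD1": "O", "CG": "C", "OD2": "O", "CB": "C"},
            [("OD1", "CG", "double"), ("CG", "OD2", "single"),
             ("CG", "CB", "single")]),
    "LYS": ({"NZ": "N", "CE": "C", "CD": "C", "CG": "C",
             "HZ1": "H", "HZ2": "H", "HZ3": "H"},
            [("NZ", "CE", "single"), ("CE", "CD", "single"),
             ("CD", "CG", "single"), ("NZ", "HZ1", "single"),
             ("NZ", "HZ2", "single"), ("NZ", "HZ3", "single")]),
    "GLY": ({"CA": "C", "N": "N", "C": "C", "H": "H"},
            [("CA", "N", "single"), ("CA", "C", "single"),
             ("N", "H", "single")]),
}


def _orthonormal_frame(direction: np.ndarray) -> np.ndarray:
    """3x3 rotation whose first row is ``direction`` (unit)."""
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    ref = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(d, ref)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    u = np.cross(d, ref)
    u /= np.linalg.norm(u)
    v = np.cross(d, u)
    return np.stack([d, u, v])


def _place_template(res_name: str, contact_point: np.ndarray,
                    direction: np.ndarray) -> list[tuple[str, str, np.ndarray]]:
    """Rigid-place a residue template with its contact atom at
    ``contact_point``, extending away along ``direction``."""
    frame = _orthonormal_frame(direction)
    return [(name, el, contact_point + np.asarray(off) @ frame)
            for name, el, off in _RESIDUE_TEMPLATES[res_name]]


def _site_directions(count: int) -> np.ndarray:
    """Well-separated unit directions (deterministic Fibonacci sphere)."""
    i = np.arange(max(count, 1))
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * (i + 0.5) / max(count, 1)
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    return np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)


#: ligand used inside sites: propanol-like chain C1-C2-C3-O1 with O1 a
#: hydroxyl (donor+acceptor) and C3 its neighbour atom (the ``aa``).
#: O1 sits on the x-axis through C3 so the acceptor-neighbour direction
#: is exactly -x; coordinates are 3-decimal exact so that distances along
#: coordinate axes survive PDB's fixed 3-decimal columns unchanged.
_SITE_LIGAND = [("C1", "C", (0.0, 0.0, 0.0)), ("C2", "C", (1.5, 0.0, 0.0)),
                ("C3", "C", (2.4, 1.2, 0.0)), ("O1", "O", (3.8, 1.2, 0.0))]
SITE_LIGAND_COMP = "SLG"


def site_ligand_component_text() -> str:
    atoms = {nm: el for nm, el, _ in _SITE_LIGAND}
    atoms["HO1"] = "H"
    bonds = [("C1", "C2", "single"), ("C2", "C3", "single"),
             ("C3", "O1", "single"), ("O1", "HO1", "single")]
    return _component_block(SITE_LIGAND_COMP, atoms, bonds)


def make_site(shells: list[tuple[str, float]] | None = None,
              waters: list[int] | None = None,
              hbond_geometries: list[tuple[float, float]] | None = None,
              covalent_residues: list[str] | None = None,
              water_step: float = 2.8,
              water_first_leg: float | None = None,
              seed: int = 0) -> tuple[str, str]:
    """Build a synthetic binding site around a small hydroxyl ligand.

    Returns ``(pdb_text, components_text)``.

    shells
        ``(residue_name, min_distance)`` pairs; each residue's closest
        heavy atom sits at exactly ``min_distance`` from the nearest
        ligand atom.
    waters
        one bridge per entry (at most 6); the entry is the number of
        bridging waters between the ligand hydroxyl O1 and a SER OG;
        step distances are ``water_step`` except the ligand->first-water
        leg, which is ``water_first_leg`` when given.
    hbond_geometries
        ``(distance, angle)`` pairs: a LYS-like donor N placed at
        ``distance`` from the ligand acceptor O1 such that the
        donor-acceptor-neighbour angle (NZ, O1, C3) equals ``angle``
        degrees.
    covalent_residues
        residue template names LINKed to ligand atom C1 at 1.8 A.
    """
    del seed  # geometry is fully deterministic; kept for API symmetry
    shells = list(shells or [])
    waters = list(waters or [])
    hbond_geometries = list(hbond_geometries or [])
    covalent_residues = list(covalent_residues or [])
    if any(d <= 0 for _, d in shells):
        raise FixtureError("shell distances must be positive")
    if any(d <= 0 for d, _ in hbond_geometries):
        raise FixtureError("hbond distances must be positive")
    if len(waters) > 6:
        raise FixtureError("at most 6 water bridges supported")

    lig_atoms = [(nm, el, np.asarray(xyz, dtype=float))
                 for nm, el, xyz in _SITE_LIGAND]
    lig_pos = {nm: xyz for nm, _, xyz in lig_atoms}
    lig_coords = np.array([xyz for _, _, xyz in lig_atoms])

    comps = {SITE_LIGAND_COMP: site_ligand_component_text()}

    lines: list[str] = []
    link_lines: list[str] = []
    serial = 1
    for nm, el, xyz in lig_atoms:
        lines.append(_het_line(serial, nm, SITE_LIGAND_COMP, "A", 401, xyz, el))
        serial += 1

    used_seqs: dict[str, int] = {}

    def next_seq(chain: str) -> int:
        used_seqs[chain] = used_seqs.get(chain, 0) + 1
        return used_seqs[chain]

    def add_residue(res_name: str, chain: str, atoms, record="ATOM  "):
        nonlocal serial
        seq = next_seq(chain)
        for name, el, pos in atoms:
            lines.append(_het_line(serial, name, res_name, chain, seq,
                                   pos, el, record=record))
            serial += 1
        if res_name in _TEMPLATE_COMPONENTS and res_name not in comps:
            a, b = _TEMPLATE_COMPONENTS[res_name]
            comps[res_name] = _component_block(res_name, a, b)
        return seq

    # ---- shells: residues at exact minimum heavy-atom distance;
    # axis-aligned directions first so the contact coordinate (and hence
    # the distance) is exact even after 3-decimal PDB formatting
    shell_dirs = np.vstack([
        np.array([[0.0, 0.0, 1.0], [0.0, 0.0, -1.0],
                  [0.0, 1.0, 0.0], [0.0, -1.0, 0.0]]),
        _site_directions(max(len(shells), 1) * 3),
    ])
    di = 0
    for res_name, dist in shells:
        if res_name not in _RESIDUE_TEMPLATES:
            raise FixtureError(f"no template for residue {res_name!r}")
        placed_atoms = None
        while di < len(shell_dirs):
            direction = shell_dirs[di]
            di += 1
            proj = lig_coords @ direction
            anchor = lig_coords[int(np.argmax(proj))]
            contact = anchor + dist * direction
            atoms = _place_template(res_name, contact, direction)
            dmat = np.array([[np.linalg.norm(pos - lc) for lc in lig_coords]
                             for _, _, pos in atoms])
            if abs(dmat.min() - dist) < 1e-9:
                placed_atoms = atoms
                break
        if placed_atoms is None:
            raise FixtureError(f"cannot place shell residue {res_name} "
                               f"at {dist} A without a closer contact")
        add_residue(res_name, "E", placed_atoms)

    # ---- hydrogen-bond geometries: donor NZ vs ligand acceptor O1
    o1, c3 = lig_pos["O1"], lig_pos["C3"]
    aa_dir = (c3 - o1) / np.linalg.norm(c3 - o1)
    axis_frame = _orthonormal_frame(aa_dir)
    for k, (dist, angle) in enumerate(hbond_geometries):
        phi = np.radians(90.0 * k)
        perp = np.cos(phi) * axis_frame[1] + np.sin(phi) * axis_frame[2]
        theta = np.radians(angle)
        d_dir = np.cos(theta) * aa_dir + np.sin(theta) * perp
        donor = o1 + dist * d_dir
        add_residue("LYS", "D", _place_template("LYS", donor, perp))

    # ---- water bridges along near-orthogonal rays from O1
    ray_frame = _orthonormal_frame(-aa_dir)
    bridge_rays = [ray_frame[0], ray_frame[1], -ray_frame[1],
                   ray_frame[2], -ray_frame[2], -ray_frame[0]]
    for b, n_w in enumerate(waters):
        if n_w < 1:
            raise FixtureError("water chain length must be >= 1")
        direction = bridge_rays[b]
        pt = lig_pos["O1"]
        for w in range(n_w):
            leg = water_first_leg if (w == 0 and water_first_leg is not None) \
                else water_step
            pt = pt + leg * direction
            lines.append(_het_line(serial, "O", "HOH", "W",
                                   next_seq("W"), pt, "O"))
            serial += 1
        end = pt + water_step * direction
        add_residue("SER", "S", _place_template("SER", end, direction))

    # ---- covalent (explicit) residues LINKed to C1
    c1 = lig_pos["C1"]
    cov_dirs = _site_directions(len(covalent_residues) + 4)
    for k, res_name in enumerate(covalent_residues):
        if res_name not in _RESIDUE_TEMPLATES:
            raise FixtureError(f"no template for residue {res_name!r}")
        direction = -cov_dirs[k]
        contact = c1 + 1.8 * direction
        atoms = _place_template(res_name, contact, direction)
        seq = add_residue(res_name, "C", atoms)
        link_lines.append(_link_line(("C1", SITE_LIGAND_COMP, "A", 401),
                                     (atoms[0][0], res_name, "C", seq), 1.8))

    text = "\n".join(link_lines + lines + ["END"]) + "\n"
    return text, "\n".join(comps.values())
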
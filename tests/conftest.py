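import numpy as np
import pytest

from ligdiagram import (FixtureSpec, build_graph, detect_ligands,
                        detect_macrocycles, layout_ligand, make_ligand,
                        make_site, parse_components, parse_pdb, partition,
                        perceive_sssr)


def load_ligand(kind, **params):
    """Parse a generated ligand fixture into (structure, components, ligand)."""
    pdb, comp = make_ligand(FixtureSpec(kind, params))
    structure = parse_pdb(pdb)
    components = parse_components(comp)
    ligands = detect_ligands(structure)
    assert len(ligands) == 1
    return structure, components, ligands[0]


def load_site(**kwargs):
    pdb, comps = make_site(**kwargs)
    structure = parse_pdb(pdb)
    components = parse_components(comps)
    ligands = detect_ligands(structure)
    assert len(ligands) == 1
    return structure, components, ligands[0]


def graph_of(kind, **params):
    structure, components, ligand = load_ligand(kind, **params)
    return build_graph(ligand, components, structure)


def full_layout(kind, **params):
    """Graph, elements and 2D layout for a ligand fixture."""
    g = graph_of(kind, **params)
    rings = detect_macrocycles(perceive_sssr(g))
    elements = partition(g, rings)
    return g, elements, layout_ligand(g, elements)


#: pyrrolidine-like ligand: a 5-ring (N2, CD3, CG3, CB1, CA1) carrying a
#: 4-carbon chain with a carbonyl O - covers ring+chain+terminal partition
EPO_LIKE_PDB = """\
HETATM    1  CG1 EPL A 401       0.000   0.000   0.000  1.00  0.00           C
HETATM    2  CB  EPL A 401       1.450   0.380   0.000  1.00  0.00           C
HETATM    3  CG2 EPL A 401       2.000   1.100   1.150  1.00  0.00           C
HETATM    4  CA  EPL A 401       2.300  -0.850  -0.250  1.00  0.00           C
HETATM    5  C   EPL A 401       3.750  -0.480  -0.300  1.00  0.00           C
HETATM    6  O   EPL A 401       4.300   0.150  -1.200  1.00  0.00           O
HETATM    7  N2  EPL A 401       4.500  -0.900   0.700  1.00  0.00           N
HETATM    8  CD3 EPL A 401       4.050  -1.700   1.800  1.00  0.00           C
HETATM    9  CG3 EPL A 401       5.250  -2.000   2.650  1.00  0.00           C
HETATM   10  CB1 EPL A 401       6.400  -1.850   1.700  1.00  0.00           C
HETATM   11  CA1 EPL A 401       5.950  -0.900   0.600  1.00  0.00           C
END
"""

EPO_LIKE_COMPONENT = """\
data_EPL
_chem_comp.id EPL
loop_
_chem_comp_atom.comp_id
_chem_comp_atom.atom_id
_chem_comp_atom.type_symbol
EPL CG1 C
EPL CB C
EPL CG2 C
EPL CA C
EPL C C
EPL O O
EPL N2 N
EPL CD3 C
EPL CG3 C
EPL CB1 C
EPL CA1 C
loop_
_chem_comp_bond.comp_id
_chem_comp_bond.atom_id_1
_chem_comp_bond.atom_id_2
_chem_comp_bond.value_order
EPL CG1 CB SING
EPL CB CG2 SING
EPL CB CA SING
EPL CA C SING
EPL C O DOUB
EPL C N2 SING
EPL N2 CD3 SING
EPL CD3 CG3 SING
EPL CG3 CB1 SING
EPL CB1 CA1 SING
EPL CA1 N2 SING
"""


@pytest.fixture
def epo_like():
    structure = parse_pdb(EPO_LIKE_PDB)
    components = parse_components(EPO_LIKE_COMPONENT)
    ligands = detect_ligands(structure)
    assert len(ligands) == 1
    return structure, components, ligands[0]


def interior_angles(layout, serial_path):
    """Bond-bond angle at each interior atom of an ordered path."""
    out = []
    for i in range(1, len(serial_path) - 1):
        a = layout.pos(serial_path[i - 1])
        b = layout.pos(serial_path[i])
        c = layout.pos(serial_path[i + 1])
        v1, v2 = a - b, c - b
        cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
        out.append(float(np.degrees(np.arccos(np.clip(cosang, -1, 1)))))
    return out
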
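"""SVG/PNG rendering and flat-text interaction export.

SVG is the canonical backend: geometry from the scene is written once as
a small set of SVG primitives (line, polyline, ellipse, circle, polygon,
text) with deterministic ids and attribute order, so the same scene and
style always produce byte-identical output.  PNG output rasterizes those
same primitives with Pillow at a configurable DPI.

Colour schemes for nearby-residue ovals: hydrophobicity (polar pink,
non-polar green, other grey), Shapely-like amino-acid colours, charge
(non-polar grey, acidic red, basic blue, uncharged polar purple) and
secondary structure (helix red, sheet yellow, coil grey).  All schemes
are total: unknown residues get the scheme's fallback colour.
"""

from __future__ import annotations

import io
import math
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field

import numpy as np
from PIL import Image, ImageDraw

from .interactions import InteractionSet
from .pdb_io import Structure
from .scene import Scene

SCALE = 40.0      # px per Angstrom at the base 96 dpi
MARGIN = 60.0     # px

NONPOLAR = frozenset({"ALA", "VAL", "LEU", "ILE", "PRO", "PHE", "MET", "GLY"})
POLAR = frozenset({"SER", "THR", "CYS", "TYR", "ASN", "GLN", "HIS",
                   "LYS", "ARG", "ASP", "GLU", "TRP"})
ACIDIC = frozenset({"ASP", "GLU"})
BASIC = frozenset({"LYS", "ARG", "HIS"})

#: Shapely-like per-amino-acid palette (RasMol documentation values)
SHAPELY = {
    "ALA": "#8cff8c", "GLY": "#ffffff", "LEU": "#455e45", "SER": "#ff7042",
    "VAL": "#ff8cff", "THR": "#b84c00", "LYS": "#4747b8", "ASP": "#a00042",
    "ILE": "#004c00", "ASN": "#ff7c70", "GLU": "#660000", "PRO": "#525252",
    "ARG": "#00007c", "PHE": "#534c42", "GLN": "#ff4c4c", "TYR": "#8c704c",
    "HIS": "#7070ff", "CYS": "#ffff70", "MET": "#b8a042", "TRP": "#4f4600",
}
SHAPELY_FALLBACK = "#ff00fb"

ELEMENT_COLOURS = {"C": "#303030", "N": "#2040ff", "O": "#e00000",
                   "S": "#c8a000", "P": "#ff8000", "F": "#00c000",
                   "CL": "#00c000", "BR": "#a52a2a", "I": "#940094"}
ELEMENT_FALLBACK = "#707070"

HBOND_COLOUR = "#2040ff"
WATER_COLOUR = "#008000"
LIGAND_COLOUR = "#000000"


@dataclass
class StyleConfig:
    colour_mode: str = "standard_element"    # or "plain"
    residue_scheme: str = "hydrophobicity"
    show_atom_labels: bool = False
    hbond_style: str = "line"                # or "arrow"
    show_hbond_distances: bool = False
    show_waters: bool = False
    palette: dict[str, str] = field(default_factory=dict)
    hidden_residues: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.colour_mode not in ("standard_element", "plain"):
            raise ValueError(f"unknown colour mode {self.colour_mode!r}")
        if self.residue_scheme not in ("hydrophobicity", "amino_acid",
                                       "charge", "secondary_structure"):
            raise ValueError(f"unknown residue scheme "
                             f"{self.residue_scheme!r}")


def residue_colour(residue_id: tuple[str, str, int], scheme: str,
                   structure: Structure | None = None,
                   palette: dict[str, str] | None = None) -> str:
    """Total colour function for nearby-residue ovals."""
    name, chain, seq = residue_id
    if palette and name in palette:
        return palette[name]
    if scheme == "hydrophobicity":
        if name in POLAR:
            return "#ff9ecb"   # polar: pink
        if name in NONPOLAR:
            return "#7ec87e"   # non-polar: green
        return "#b0b0b0"       # other: grey
    if scheme == "amino_acid":
        return SHAPELY.get(name, SHAPELY_FALLBACK)
    if scheme == "charge":
        if name in ACIDIC:
            return "#e04040"   # acidic: red
        if name in BASIC:
            return "#4060e0"   # basic: blue
        if name in POLAR:
            return "#a060d0"   # uncharged polar: purple
        return "#b0b0b0"       # non-polar: grey
    # secondary structure
    kind = structure.secondary_structure(chain, seq) if structure else "coil"
    return {"helix": "#e04040", "sheet": "#e8d040",
            "coil": "#b0b0b0"}[kind]


def element_colour(element: str, mode: str) -> str:
    if mode == "plain":
        return LIGAND_COLOUR
    return ELEMENT_COLOURS.get(element.upper(), ELEMENT_FALLBACK)


# ----------------------------------------------------------------- SVG

def _fmt(x: float) -> str:
    return f"{x:.2f}"


class _SvgDoc:
    def __init__(self, width: float, height: float) -> None:
        self.parts: list[str] = [
            '<?xml version="1.0" encoding="UTF-8"?>\n'
            f'<svg xmlns="http://www.w3.org/2000/svg" version="1.1" '
            f'width="{_fmt(width)}" height="{_fmt(height)}" '
            f'viewBox="0 0 {_fmt(width)} {_fmt(height)}">\n'
            f'<rect x="0" y="0" width="{_fmt(width)}" '
            f'height="{_fmt(height)}" fill="#ffffff"/>\n']

    def line(self, p1, p2, colour, width=2.0, dash=None, eid=None):
        d = f' stroke-dasharray="{dash}"' if dash else ""
        i = f' id="{eid}"' if eid else ""
        self.parts.append(
            f'<line{i} x1="{_fmt(p1[0])}" y1="{_fmt(p1[1])}" '
            f'x2="{_fmt(p2[0])}" y2="{_fmt(p2[1])}" stroke="{colour}" '
            f'stroke-width="{_fmt(width)}"{d}/>\n')

    def polygon(self, pts, colour, eid=None):
        i = f' id="{eid}"' if eid else ""
        coords = " ".join(f"{_fmt(x)},{_fmt(y)}" for x, y in pts)
        self.parts.append(
            f'<polygon{i} points="{coords}" fill="{colour}"/>\n')

    def circle(self, c, r, fill, eid=None):
        i = f' id="{eid}"' if eid else ""
        self.parts.append(
            f'<circle{i} cx="{_fmt(c[0])}" cy="{_fmt(c[1])}" '
            f'r="{_fmt(r)}" fill="{fill}"/>\n')

    def ellipse(self, c, rx, ry, fill, stroke="#404040", eid=None):
        i = f' id="{eid}"' if eid else ""
        self.parts.append(
            f'<ellipse{i} cx="{_fmt(c[0])}" cy="{_fmt(c[1])}" '
            f'rx="{_fmt(rx)}" ry="{_fmt(ry)}" fill="{fill}" '
            f'stroke="{stroke}" stroke-width="1.00"/>\n')

    def text(self, p, s, colour="#000000", size=12.0, anchor="middle",
             eid=None):
        i = f' id="{eid}"' if eid else ""
        esc = (s.replace("&", "&amp;").replace("<", "&lt;")
               .replace(">", "&gt;"))
        self.parts.append(
            f'<text{i} x="{_fmt(p[0])}" y="{_fmt(p[1])}" '
            f'font-family="sans-serif" font-size="{_fmt(size)}" '
            f'text-anchor="{anchor}" fill="{colour}">{esc}</text>\n')

    def tostring(self) -> str:
        return "".join(self.parts) + "</svg>\n"


def _scene_extent(scene: Scene) -> tuple[np.ndarray, np.ndarray]:
    pts = [p for p in scene.layout.positions.values()]
    for el in scene.placed:
        pts.append(el.position)
        pts.extend(el.waters_positions)
    for lb in scene.labels:
        pts.append(lb.position)
    arr = np.array(pts) if pts else np.zeros((1, 2))
    return arr.min(axis=0), arr.max(axis=0)


def render_svg(scene: Scene, style: StyleConfig | None = None,
               structure: Structure | None = None) -> str:
    """Render the assembled scene to an SVG 1.1 document string."""
    style = style or StyleConfig()
    lo, hi = _scene_extent(scene)
    size = (hi - lo) * SCALE + 2 * MARGIN

    def T(p: np.ndarray) -> tuple[float, float]:
        return (float((p[0] - lo[0]) * SCALE + MARGIN),
                float((hi[1] - p[1]) * SCALE + MARGIN))

    doc = _SvgDoc(size[0], size[1])
    layout, graph = scene.layout, scene.graph

    def hidden(el) -> bool:
        return el.label.split("(")[0] in style.hidden_residues

    # water bridges (green), drawn under everything else
    if style.show_waters:
        for k, el in enumerate(e for e in scene.placed
                               if e.kind == "water_bridge"):
            if hidden(el):
                continue
            pts = [el.anchor, *el.waters_positions, el.position]
            for i in range(len(pts) - 1):
                doc.line(T(pts[i]), T(pts[i + 1]), WATER_COLOUR, width=2.0,
                         dash="6,4", eid=f"wbridge-{k}-seg{i}")
            mid = pts[len(pts) // 2]
            n_w = len(el.waters_positions)
            doc.text((T(mid)[0], T(mid)[1] - 6.0), f"{n_w} H2O",
                     colour=WATER_COLOUR, eid=f"wbridge-{k}-count")
            doc.text(T(el.position), el.label, colour=WATER_COLOUR,
                     eid=f"wbridge-{k}-label")

    # hydrogen bonds (blue)
    for k, el in enumerate(e for e in scene.placed
                           if e.kind == "hbond_partner"):
        if hidden(el):
            continue
        hb = el.payload
        a, b = T(el.anchor), T(el.position)
        if style.hbond_style == "arrow" and hb is not None:
            tail, head = (a, b) if hb.ligand_side == "donor" else (b, a)
            doc.line(tail, head, HBOND_COLOUR, width=2.0, dash="7,4",
                     eid=f"hbond-{k}")
            doc.polygon(_arrow_head(tail, head), HBOND_COLOUR,
                        eid=f"hbond-{k}-head")
        else:
            doc.line(a, b, HBOND_COLOUR, width=2.0, dash="7,4",
                     eid=f"hbond-{k}")
        if style.show_hbond_distances and hb is not None:
            mid = ((a[0] + b[0]) / 2, (a[1] + b[1]) / 2 - 4.0)
            doc.text(mid, f"{hb.distance:.2f}", colour=HBOND_COLOUR,
                     size=10.0, eid=f"hbond-{k}-dist")
        doc.text((b[0], b[1] - 8.0), el.label, colour=HBOND_COLOUR,
                 size=10.0, eid=f"hbond-{k}-partner")

    # nearby-residue ovals
    for k, el in enumerate(e for e in scene.placed
                           if e.kind == "residue_oval"):
        if hidden(el):
            continue
        nr = el.payload
        rid = nr.residue_id if nr is not None else ("UNK", "?", 0)
        fill = residue_colour(rid, style.residue_scheme, structure,
                              style.palette)
        c = T(el.position)
        doc.ellipse(c, 1.1 * SCALE, 0.55 * SCALE, fill,
                    eid=f"oval-{k}")
        doc.text((c[0], c[1] + 4.0), el.label, size=11.0,
                 eid=f"oval-{k}-name")

    # ligand bonds
    for k, (s1, s2) in enumerate(sorted(graph.g.edges)):
        if s1 not in layout.positions or s2 not in layout.positions:
            continue
        order = graph.bond_order(s1, s2)
        p1, p2 = layout.pos(s1), layout.pos(s2)
        colour = LIGAND_COLOUR
        if order in ("double", "triple", "aromatic"):
            for j, off in enumerate(_parallel_offsets(order)):
                n = _normal(p1, p2) * off
                dash = "5,3" if (order == "aromatic" and j == 1) else None
                doc.line(T(p1 + n), T(p2 + n), colour, width=2.0,
                         dash=dash, eid=f"bond-{k}-{j}")
        else:
            doc.line(T(p1), T(p2), colour, width=2.0, eid=f"bond-{k}")

    # atoms
    for s in sorted(layout.positions):
        if s not in {a.serial for a in graph.atoms()}:
            continue
        atom = graph.atom(s)
        c = T(layout.pos(s))
        colour = element_colour(atom.element, style.colour_mode)
        doc.circle(c, 3.5, colour, eid=f"atom-{s}")
        if style.show_atom_labels:
            doc.text((c[0] + 6.0, c[1] - 6.0), atom.name, colour=colour,
                     size=9.0, anchor="start", eid=f"atom-{s}-label")

    # residue-name labels
    for k, lb in enumerate(scene.labels):
        doc.text(T(lb.position), lb.text, size=12.0, eid=f"label-{k}")

    return doc.tostring()


def _normal(p1: np.ndarray, p2: np.ndarray) -> np.ndarray:
    v = p2 - p1
    n = np.array([-v[1], v[0]])
    norm = np.linalg.norm(n)
    return n / norm if norm > 0 else np.array([0.0, 1.0])


def _parallel_offsets(order: str) -> list[float]:
    if order == "double":
        return [-0.06, 0.06]
    if order == "triple":
        return [-0.1, 0.0, 0.1]
    return [0.0, 0.1]  # aromatic: solid line + dashed inner line


def _arrow_head(tail, head, size=9.0):
    dx, dy = head[0] - tail[0], head[1] - tail[1]
    ln = math.hypot(dx, dy) or 1.0
    ux, uy = dx / ln, dy / ln
    px, py = -uy, ux
    return [(head[0], head[1]),
            (head[0] - size * ux + 0.45 * size * px,
             head[1] - size * uy + 0.45 * size * py),
            (head[0] - size * ux - 0.45 * size * px,
             head[1] - size * uy - 0.45 * size * py)]


# ----------------------------------------------------------------- PNG

class RasterizationError(RuntimeError):
    pass


def render_png(svg_text: str, dpi: float = 96.0) -> bytes:
    """Rasterize an SVG document produced by :func:`render_svg`.

    Understands the primitive subset this package emits (rect, line,
    polygon, circle, ellipse, text).  Raises
    :class:`RasterizationError` for SVG it cannot interpret, advising
    SVG output instead.
    """
    try:
        root = ET.fromstring(svg_text)
    except ET.ParseError as exc:
        raise RasterizationError(
            f"invalid SVG ({exc}); use SVG output instead") from exc
    ns = "{http://www.w3.org/2000/svg}"
    if not root.tag == f"{ns}svg":
        raise RasterizationError("not an SVG document; use SVG output")
    scale = dpi / 96.0
    # integer base dimensions first, so doubling dpi doubles pixel size
    w = int(round(round(float(root.get("width"))) * scale))
    h = int(round(round(float(root.get("height"))) * scale))
    img = Image.new("RGB", (max(w, 1), max(h, 1)), "#ffffff")
    draw = ImageDraw.Draw(img)
    for el in root:
        tag = el.tag.removeprefix(ns)
        if tag == "rect":
            x, y = float(el.get("x")) * scale, float(el.get("y")) * scale
            ww = float(el.get("width")) * scale
            hh = float(el.get("height")) * scale
            draw.rectangle([x, y, x + ww, y + hh], fill=el.get("fill"))
        elif tag == "line":
            p = [float(el.get(k)) * scale for k in ("x1", "y1", "x2", "y2")]
            lw = max(1, int(round(float(el.get("stroke-width", "1")) * scale)))
            _draw_line(draw, p, el.get("stroke"), lw,
                       el.get("stroke-dasharray"))
        elif tag == "polygon":
            pts = [tuple(float(v) * scale for v in pair.split(","))
                   for pair in el.get("points").split()]
            draw.polygon(pts, fill=el.get("fill"))
        elif tag == "circle":
            cx, cy = float(el.get("cx")) * scale, float(el.get("cy")) * scale
            r = float(el.get("r")) * scale
            draw.ellipse([cx - r, cy - r, cx + r, cy + r],
                         fill=el.get("fill"))
        elif tag == "ellipse":
            cx, cy = float(el.get("cx")) * scale, float(el.get("cy")) * scale
            rx, ry = float(el.get("rx")) * scale, float(el.get("ry")) * scale
            draw.ellipse([cx - rx, cy - ry, cx + rx, cy + ry],
                         fill=el.get("fill"), outline=el.get("stroke"))
        elif tag == "text":
            x, y = float(el.get("x")) * scale, float(el.get("y")) * scale
            draw.text((x, y), el.text or "", fill=el.get("fill", "#000000"),
                      anchor="ms" if el.get("text-anchor") == "middle"
                      else "ls")
        else:
            raise RasterizationError(
                f"unsupported SVG element <{tag}>; use SVG output")
    buf = io.BytesIO()
    img.save(buf, format="PNG")
    return buf.getvalue()


def _draw_line(draw, p, colour, width, dash):
    if not dash:
        draw.line(p, fill=colour, width=width)
        return
    on, off = (float(v) for v in dash.split(",")[:2])
    x1, y1, x2, y2 = p
    ln = math.hypot(x2 - x1, y2 - y1)
    if ln == 0:
        return
    ux, uy = (x2 - x1) / ln, (y2 - y1) / ln
    t = 0.0
    while t < ln:
        t2 = min(t + on, ln)
        draw.line([x1 + ux * t, y1 + uy * t, x1 + ux * t2, y1 + uy * t2],
                  fill=colour, width=width)
        t = t2 + off


# ----------------------------------------------------------- flat text

def export_interactions(interactions: InteractionSet) -> str:
    """Tab-separated interaction list: one row per interaction."""
    rows = ["type\tligand_atom\tpartner\tchain\tdistance_A"]
    for hb in interactions.hbonds:
        lig, par = hb.ligand_atom, hb.partner_atom
        rows.append("hydrogen_bond\t"
                    f"{lig.name}\t{par.residue_name}{par.residue_seq} "
                    f"{par.name}\t{par.chain_id}\t{hb.distance:.2f}")
    for nr in interactions.nearby_residues:
        lig, ra = nr.closest_atom_pair
        name, chain, seq = nr.residue_id
        rows.append("nearby_residue\t"
                    f"{lig.name}\t{name}{seq} {ra.name}\t{chain}\t"
                    f"{nr.min_distance:.2f}")
    for wb in interactions.water_bridges:
        ra = wb.residue_atom
        steps = ",".join(f"{d:.2f}" for d in wb.step_distances)
        rows.append("water_bridge\t"
                    f"{wb.ligand_atom.name}\t{ra.residue_name}"
                    f"{ra.residue_seq} {ra.name}\t{ra.chain_id}\t"
                    f"{steps} (total {wb.total_distance:.2f})")
    return "\n".join(rows) + "\n"
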
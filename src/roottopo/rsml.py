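"""Reading and writing Root System Markup Language (RSML 1.0) files.

RSML stores root architectures as XML: a ``metadata`` block (version,
length unit, resolution) and one or more ``scene/plant`` elements whose
nested ``root`` elements carry a ``geometry/polyline`` of points plus
optional per-node ``functions`` (diameter, age).  The reader accepts
both the per-node ``diameter`` sample function and a single root-level
diameter attribute/property (broadcast to all nodes), and treats any
function whose name contains "age" or "time" (case-insensitive) as node
age.  Optional blocks (properties, annotations) are ignored.
"""

from __future__ import annotations

import math
import os
from typing import IO

from lxml import etree

from .tree import Root, RootNode, RootSystemTree, ValidationError

__all__ = ["read_rsml", "write_rsml", "RSMLParseError"]


class RSMLParseError(ValueError):
    """Malformed or non-conforming RSML document."""


def _is_age_name(name: str) -> bool:
    n = name.lower()
    return "age" in n or "time" in n


def _parse_functions(root_el) -> tuple[list[float] | None, list[float] | None]:
    """Extract per-node diameter and age sample vectors, if present."""
    diam = age = None
    fns = root_el.find("functions")
    if fns is None:
        return None, None
    for fn in fns.findall("function"):
        name = fn.get("name", "")
        samples = []
        for s in fn.findall("sample"):
            txt = s.get("value", s.text)
            samples.append(float(txt) if txt not in (None, "") else math.nan)
        if name.lower() == "diameter":
            diam = samples
        elif _is_age_name(name):
            age = samples
    return diam, age


def _nearest_node_index(nodes: list[RootNode], point: tuple[float, float, float]) -> int:
    return min(range(len(nodes)), key=lambda i: math.dist(nodes[i].position(), point))


def _parse_root(root_el, order: int, parent: Root | None, roots: list[Root],
                fallback_prefix: str) -> None:
    rid = root_el.get("ID") or root_el.get("id") or root_el.get("label")
    if not rid:
        rid = f"{fallback_prefix}"
    geometry = root_el.find("geometry/polyline")
    if geometry is None:
        raise RSMLParseError(f"root {rid!r}: missing geometry/polyline")
    points = geometry.findall("point")
    if len(points) < 2:
        raise ValidationError(
            f"root {rid!r} has {len(points)} node(s); at least 2 required"
        )
    diam, age = _parse_functions(root_el)
    if diam is None:
        # root-level diameter dialect: a single scalar broadcast to all nodes
        scalar = root_el.get("diameter")
        if scalar is None:
            prop = root_el.find("properties/diameter")
            if prop is not None:
                scalar = prop.get("value", prop.text)
        diam = [float(scalar)] * len(points) if scalar is not None else [0.0] * len(points)
    nodes = []
    for i, p in enumerate(points):
        try:
            x, y = float(p.get("x")), float(p.get("y"))
        except (TypeError, ValueError) as exc:
            raise RSMLParseError(f"root {rid!r}: point {i} lacks numeric x/y") from exc
        z = float(p.get("z", 0.0) or 0.0)
        nodes.append(RootNode(
            x=x, y=y, z=z,
            diameter=float(diam[i]) if i < len(diam) else float(diam[-1]),
            age=(float(age[i]) if age is not None and i < len(age) else None),
        ))
    insertion = None
    if parent is not None:
        insertion = _nearest_node_index(parent.nodes, nodes[0].position())
    root = Root(id=rid, order=order, nodes=nodes,
                parent_id=parent.id if parent else None,
                insertion_index=insertion)
    roots.append(root)
    for j, child in enumerate(root_el.findall("root")):
        _parse_root(child, order + 1, root, roots, f"{rid}.{j + 1}")


def read_rsml(source: str | os.PathLike | IO) -> list[RootSystemTree]:
    """Parse an RSML document into one :class:`RootSystemTree` per plant.

    ``source`` may be a path, an open file, or the XML text itself.

    Raises
    ------
    RSMLParseError
        If the XML is malformed (the message names the line) or the
        document lacks the required ``rsml/scene/plant/root`` structure.
    ValidationError
        If a root has fewer than two nodes.
    """
    if isinstance(source, str) and source.lstrip().startswith("<"):
        source = source.encode()
    try:
        if isinstance(source, bytes):
            doc = etree.fromstring(source)
        else:
            doc = etree.parse(os.fspath(source) if not hasattr(source, "read")
                              else source).getroot()
    except etree.XMLSyntaxError as exc:
        raise RSMLParseError(f"malformed RSML XML: {exc}") from exc
    if doc.tag != "rsml":
        raise RSMLParseError(f"expected <rsml> document root, found <{doc.tag}>")

    unit, resolution = "cm", 1.0
    meta = doc.find("metadata")
    if meta is not None:
        u = meta.findtext("unit")
        if u:
            unit = u.strip()
        res = meta.findtext("resolution")
        if res:
            resolution = float(res)

    trees = []
    plants = doc.findall("scene/plant")
    if not plants:
        raise RSMLParseError("document contains no scene/plant element")
    for k, plant_el in enumerate(plants):
        pid = plant_el.get("ID") or plant_el.get("id") or plant_el.get("label") \
            or f"plant{k + 1}"
        roots: list[Root] = []
        top = plant_el.findall("root")
        if not top:
            raise RSMLParseError(f"plant {pid!r} contains no root element")
        for j, root_el in enumerate(top):
            _parse_root(root_el, 1, None, roots, f"{pid}.R{j + 1}")
        tree = RootSystemTree(plant_id=pid, roots=roots, unit=unit,
                              resolution=resolution)
        tree.validate()
        trees.append(tree)
    return trees


def _fmt(v: float) -> str:
    return format(float(v), ".8g")


def _write_root(parent_el, tree: RootSystemTree, root: Root) -> None:
    el = etree.SubElement(parent_el, "root", ID=root.id)
    geom = etree.SubElement(el, "geometry")
    poly = etree.SubElement(geom, "polyline")
    for n in root.nodes:
        etree.SubElement(poly, "point", x=_fmt(n.x), y=_fmt(n.y), z=_fmt(n.z))
    fns = etree.SubElement(el, "functions")
    dfn = etree.SubElement(fns, "function", name="diameter", domain="polyline")
    for n in root.nodes:
        etree.SubElement(dfn, "sample", value=_fmt(n.diameter))
    if all(n.age is not None for n in root.nodes):
        afn = etree.SubElement(fns, "function", name="age", domain="polyline")
        for n in root.nodes:
            etree.SubElement(afn, "sample", value=_fmt(n.age))
    for child in tree.children_of(root.id):
        _write_root(el, tree, child)


def write_rsml(trees: list[RootSystemTree], path: str | os.PathLike | None = None) -> bytes:
    """Serialise trees to one schema-conformant RSML document.

    Validates every tree before anything is written; returns the XML
    bytes and, if ``path`` is given, writes them there.
    """
    if not trees:
        raise ValidationError("no trees to write")
    for t in trees:
        t.validate()
    doc = etree.Element("rsml")
    meta = etree.SubElement(doc, "metadata")
    etree.SubElement(meta, "version").text = "1"
    etree.SubElement(meta, "unit").text = trees[0].unit
    etree.SubElement(meta, "resolution").text = _fmt(trees[0].resolution)
    etree.SubElement(meta, "software").text = "roottopo"
    scene = etree.SubElement(doc, "scene")
    for t in trees:
        plant_el = etree.SubElement(scene, "plant", ID=t.plant_id)
        for r in t.first_order_roots():
            _write_root(plant_el, t, r)
    data = etree.tostring(doc, pretty_print=True, xml_declaration=True,
                          encoding="UTF-8")
    if path is not None:
        with open(path, "wb") as fh:
            fh.write(data)
    return data
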
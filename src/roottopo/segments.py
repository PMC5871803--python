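"""Flatten root system trees into a per-segment table.

A root segment is the straight line between two consecutive polyline
nodes.  Each segment carries geometry (endpoint coordinates and
diameters, length, frustum surface and volume, orientation from the
downward vertical) and topology (branching order, parent root, geodesic
distance from the plant base to the segment's distal node).  The
geodesic distance accumulates segment lengths from the first node of
each first-order root; laterals continue from the geodesic value of
their insertion node on the parent.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd

from .tree import Root, RootSystemTree

logger = logging.getLogger(__name__)

#: Column order of the segment table.  The first 23 cover coordinates,
#: length, diameter, surface, volume, growth rate, orientation and
#: geodesic distance; ``insertion_node`` additionally records the parent
#: polyline index where a lateral attaches.
SEGMENT_COLUMNS = [
    "file", "plant", "root", "order", "parent_root", "apical", "time",
    "x1", "y1", "z1", "x2", "y2", "z2", "diameter1", "diameter2",
    "length", "surface", "volume", "orientation", "growth_rate",
    "geodesic", "branching_node_geodesic", "dist_from_base",
    "insertion_node",
]


def _frustum_surface(length: float, d1: float, d2: float) -> float:
    # lateral surface of a conical frustum with slant `length`
    return math.pi * length * (d1 + d2) / 2.0


def _frustum_volume(length: float, d1: float, d2: float) -> float:
    return math.pi * length / 12.0 * (d1 * d1 + d1 * d2 + d2 * d2)


def _orientation_deg(dx: float, dy: float, dz: float, length: float) -> float:
    """Angle from the downward vertical (+y in the y-down convention)."""
    c = max(-1.0, min(1.0, dy / length))
    return math.degrees(math.acos(c))


def node_geodesics(tree: RootSystemTree) -> dict[str, list[float]]:
    """Geodesic distance from the plant base to every polyline node.

    Returns a mapping root id -> per-node geodesic values.  The first
    node of a first-order root is the base (geodesic 0); the first node
    of a lateral inherits the geodesic of its insertion node on the
    parent (lateral polylines start at the branching point).
    """
    geo: dict[str, list[float]] = {}

    def visit(root: Root, start: float) -> None:
        g = [start]
        for a, b in zip(root.nodes, root.nodes[1:]):
            g.append(g[-1] + math.dist(a.position(), b.position()))
        geo[root.id] = g
        for child in tree.children_of(root.id):
            visit(child, g[child.insertion_index])

    for r in tree.first_order_roots():
        visit(r, 0.0)
    return geo


def geodesic_distance(tree: RootSystemTree, root_id: str, node_index: int) -> float:
    """Geodesic distance from the plant base to one node (path length
    along the roots, as opposed to straight-line distance)."""
    geo = node_geodesics(tree)
    if root_id not in geo:
        raise KeyError(f"unknown root {root_id!r}")
    g = geo[root_id]
    if not (0 <= node_index < len(g)):
        raise IndexError(f"root {root_id!r} has no node {node_index}")
    return g[node_index]


def build_segment_table(trees: list[RootSystemTree],
                        file_label: str = "") -> pd.DataFrame:
    """Build the per-segment table (one row per inter-node segment).

    Zero-length segments are dropped with a logged warning.  Growth rate
    is length / node-age difference when ages are present (NaN when ages
    are missing or equal).
    """
    rows = []
    dropped = 0
    for tree in trees:
        tree.validate()
        geo = node_geodesics(tree)
        base = tree.first_order_roots()[0].nodes[0].position()
        for root in tree.roots:
            g = geo[root.id]
            branch_geo = g[0] if root.order > 1 else 0.0
            nseg = root.n_segments
            for i in range(nseg):
                a, b = root.nodes[i], root.nodes[i + 1]
                length = math.dist(a.position(), b.position())
                if length == 0.0:
                    dropped += 1
                    continue
                if a.age is not None and b.age is not None and b.age > a.age:
                    rate = length / (b.age - a.age)
                else:
                    rate = math.nan
                rows.append((
                    file_label, tree.plant_id, root.id, root.order,
                    root.parent_id if root.parent_id is not None else "",
                    i == nseg - 1,
                    b.age if b.age is not None else math.nan,
                    a.x, a.y, a.z, b.x, b.y, b.z,
                    a.diameter, b.diameter,
                    length,
                    _frustum_surface(length, a.diameter, b.diameter),
                    _frustum_volume(length, a.diameter, b.diameter),
                    _orientation_deg(b.x - a.x, b.y - a.y, b.z - a.z, length),
                    rate,
                    g[i + 1],
                    branch_geo,
                    math.dist(b.position(), base),
                    root.insertion_index if root.insertion_index is not None else -1,
                ))
    if dropped:
        logger.warning("dropped %d zero-length segment(s)", dropped)
    table = pd.DataFrame(rows, columns=SEGMENT_COLUMNS)
    table.attrs["unit"] = trees[0].unit if trees else "cm"
    table.attrs["dropped_segments"] = dropped
    return table


def total_length(table: pd.DataFrame, plant: str | None = None) -> float:
    """Sum of segment lengths, optionally restricted to one plant."""
    if plant is not None:
        table = table[table["plant"] == plant]
    return float(table["length"].sum())


def write_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def read_table(path) -> pd.DataFrame:
    table = pd.read_csv(path, keep_default_na=True,
                        dtype={"file": str, "plant": str, "root": str,
                               "parent_root": str})
    table["parent_root"] = table["parent_root"].fillna("")
    return table
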
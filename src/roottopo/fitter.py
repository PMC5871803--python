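"""Fitter's topological indices of a root system.

The root system is reduced to its link representation: a link is the
portion of root between two consecutive branching points, between the
base and the first branching point, or between the last branching point
and a root tip.  External links end at a tip; internal links end at a
branching point.  From that rooted link tree, three indices:

* magnitude  -- number of external links (= number of root tips),
* altitude   -- number of links on the longest base-to-tip path,
* external path length -- sum over tips of the base-to-tip path length.

Path lengths count links, not nodes.  Two laterals inserted at the same
parent node form a single multi-way branching point.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx

from .tree import RootSystemTree

BASE = "__base__"


@dataclass(frozen=True)
class FitterIndices:
    magnitude: int
    altitude: int
    external_path_length: int


def build_link_graph(tree: RootSystemTree) -> nx.DiGraph:
    """Reduce a root system to its rooted link tree.

    Nodes are the plant base (``BASE``), branching points ``(root_id,
    node_index)`` and tips ``(root_id, "tip")``; each directed edge is
    one link, with attribute ``kind`` in {"internal", "external"}.
    """
    tree.validate()
    g = nx.DiGraph()
    g.add_node(BASE)

    # branch vertices per root: polyline indices where laterals insert
    branch_at: dict[str, list[int]] = {}
    for r in tree.roots:
        if r.parent_id is not None:
            branch_at.setdefault(r.parent_id, []).append(r.insertion_index)

    def anchor_on(root_id: str, insertion_index: int):
        return (root_id, insertion_index)

    def walk(root, start_vertex):
        prev = start_vertex
        for idx in sorted(set(branch_at.get(root.id, []))):
            v = (root.id, idx)
            g.add_edge(prev, v, kind="internal")
            prev = v
        g.add_edge(prev, (root.id, "tip"), kind="external")
        for child in tree.children_of(root.id):
            walk(child, anchor_on(root.id, child.insertion_index))

    for r in tree.first_order_roots():
        walk(r, BASE)
    return g


def fitter_indices(graph: nx.DiGraph) -> FitterIndices:
    """Compute (magnitude, altitude, external path length) from a link
    tree, by a single post-order recursion."""
    if graph.number_of_edges() == 0:
        raise ValueError("empty link graph")

    def rec(v) -> tuple[int, int, int]:
        # returns (magnitude, altitude, Pe) of the subtree hanging at v,
        # counting the links below v
        children = list(graph.successors(v))
        if not children:
            return 1, 0, 0
        mag = alt = pe = 0
        for c in children:
            m, a, p = rec(c)
            mag += m
            alt = max(alt, a + 1)
            pe += p + m  # each of the m tip paths gains the link v->c
        return mag, alt, pe

    mag, alt, pe = rec(BASE)
    return FitterIndices(magnitude=mag, altitude=alt, external_path_length=pe)


def tree_fitter_indices(tree: RootSystemTree) -> FitterIndices:
    """Convenience: link graph + indices in one call."""
    return fitter_indices(build_link_graph(tree))
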
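"""Shared builders and independent oracles for the test suite.

The oracles deliberately take different code paths from the package:
geodesics come from Dijkstra on a networkx graph, barcodes from a
threshold-sweep with explicit component-set tracking, Fitter indices
from exhaustive base-to-tip path enumeration, and bottleneck distances
from brute-force enumeration of all partial matchings.
"""

from __future__ import annotations

import itertools
import math

import networkx as nx
import numpy as np

from roottopo.fitter import BASE
from roottopo.persistence import Barcode, PersistencePair
from roottopo.tree import Root, RootNode, RootSystemTree


# ---------------------------------------------------------------------------
# tree builders

def polyline_root(rid, order, points, diameter=0.1, parent=None,
                  insertion=None, ages=None):
    nodes = [RootNode(x=p[0], y=p[1], z=(p[2] if len(p) > 2 else 0.0),
                      diameter=diameter,
                      age=(ages[i] if ages else None))
             for i, p in enumerate(points)]
    return Root(id=rid, order=order, nodes=nodes, parent_id=parent,
                insertion_index=insertion)


def single_root_tree(length=5.0, diameter=0.1):
    r = polyline_root("R1", 1, [(0, 0), (0, length)], diameter)
    return RootSystemTree(plant_id="single", roots=[r])


def y_tree():
    """First-order axis (0,0)->(0,2)->(0,5); lateral of length 1 at (0,2).

    Tip geodesics: 5 (axis) and 3 (lateral)."""
    axis = polyline_root("R1", 1, [(0, 0), (0, 2), (0, 5)])
    lat = polyline_root("R1.1", 2, [(0, 2), (1, 2)], parent="R1", insertion=1)
    return RootSystemTree(plant_id="y", roots=[axis, lat])


def herringbone(mu, axis_step=2.0, lat_len=1.0):
    """Herringbone of magnitude mu: one axis carrying mu - 1 laterals."""
    n_lat = mu - 1
    pts = [(0, i * axis_step) for i in range(n_lat + 2)]
    roots = [polyline_root("R1", 1, pts)]
    for k in range(1, n_lat + 1):
        roots.append(polyline_root(
            f"R1.{k}", 2, [(0, k * axis_step), (lat_len, k * axis_step)],
            parent="R1", insertion=k))
    return RootSystemTree(plant_id=f"hb{mu}", roots=roots)


def dichotomous4():
    """Perfect dichotomous topology with 4 tips: the main axis splits at
    two successive branch points and the first lateral splits once."""
    roots = [
        polyline_root("R1", 1, [(0, 0), (0, 1), (0, 2), (0, 3)]),
        polyline_root("L1", 2, [(0, 1), (1, 2), (1, 3)],
                      parent="R1", insertion=1),
        polyline_root("L2", 2, [(0, 2), (-1, 3)], parent="R1", insertion=2),
        polyline_root("L11", 3, [(1, 2), (2, 3)], parent="L1", insertion=1),
    ]
    return RootSystemTree(plant_id="dich4", roots=roots)


def random_tree(rng, max_tips=12, n_first_order=None, max_order=4):
    """Random valid root system: random topology, segment lengths and
    branching points; independent of the synthetic growth model."""
    n1 = n_first_order or int(rng.integers(1, 3))
    roots = []
    count = [0]

    def new_polyline(start, n_seg):
        pts = [start]
        for _ in range(n_seg):
            ang = rng.uniform(0, 2 * math.pi)
            step = rng.uniform(0.2, 3.0)
            pts.append((pts[-1][0] + step * math.cos(ang),
                        pts[-1][1] + step * math.sin(ang)))
        return pts

    for k in range(n1):
        count[0] += 1
        roots.append(polyline_root(
            f"R{k + 1}", 1, new_polyline((0.0, 0.0), int(rng.integers(2, 6)))))
    while count[0] < max_tips:
        parent = roots[int(rng.integers(0, len(roots)))]
        if parent.order >= max_order:
            continue
        idx = int(rng.integers(1, len(parent.nodes)))
        start = (parent.nodes[idx].x, parent.nodes[idx].y)
        count[0] += 1
        roots.append(polyline_root(
            f"{parent.id}.{count[0]}", parent.order + 1,
            new_polyline(start, int(rng.integers(1, 5))),
            parent=parent.id, insertion=idx))
    tree = RootSystemTree(plant_id="random", roots=roots)
    tree.validate()
    return tree


# ---------------------------------------------------------------------------
# geodesic / barcode oracle

def tree_graph(tree):
    """networkx graph of tree nodes with Euclidean edge weights; all
    first-order first nodes collapse into 'base'."""
    g = nx.Graph()
    g.add_node("base")
    for r in tree.roots:
        for i in range(len(r.nodes)):
            if i == 0:
                if r.order == 1:
                    v = "base"
                else:
                    v = (r.parent_id, r.insertion_index)
                    if r.insertion_index == 0:
                        # alias for the parent's own start
                        p = tree.root_by_id(r.parent_id)
                        v = "base" if p.order == 1 \
                            else (p.parent_id, p.insertion_index)
                prev = v
                continue
            v = (r.id, i)
            w = math.dist(r.nodes[i - 1].position(), r.nodes[i].position())
            g.add_edge(prev, v, weight=w)
            prev = v
    return g


def geodesic_oracle(tree):
    g = tree_graph(tree)
    return g, nx.single_source_dijkstra_path_length(g, "base", weight="weight")


def barcode_oracle(tree):
    """Elder-rule barcode by thresholding the geodesic function at every
    distinct value and tracking connected-component sets."""
    g, f = geodesic_oracle(tree)
    thresholds = sorted(set(f.values()), reverse=True)
    prev: list[tuple[set, float, object]] = []  # (vertex set, birth, tip key)
    pairs = []
    tipkey = {v: (("",) if v == "base" else v) for v in g}
    for t in thresholds:
        sub = g.subgraph([v for v in g if f[v] >= t])
        comps = [set(c) for c in nx.connected_components(sub)]
        new = []
        for c in comps:
            owners = [(b, k) for (s, b, k) in prev if s & c]
            fresh = [v for v in c if f[v] == t]
            cands = owners + [(t, tipkey[v]) for v in fresh
                              if not any(v in s for s, _, _ in prev)]
            # survivor: largest birth, then smallest tip key
            cands.sort(key=lambda bk: (-bk[0], bk[1]))
            birth, key = cands[0]
            for b, _ in cands[1:]:
                if b > t:
                    pairs.append((0, b, t))
            new.append((c, birth, key))
        prev = new
    assert len(prev) == 1
    pairs.append((0, prev[0][1], 0.0))
    return sorted(pairs, key=lambda p: (-p[1], -p[2]))


def barcode_pairs(b: Barcode):
    return sorted(((p.dimension, p.birth, p.death) for p in b.pairs),
                  key=lambda p: (-p[1], -p[2]))


# ---------------------------------------------------------------------------
# Fitter oracle

def fitter_oracle(link_graph):
    """Indices by exhaustive enumeration of base-to-tip paths."""
    tips = [v for v in link_graph if link_graph.out_degree(v) == 0]
    lengths = []
    for tip in tips:
        paths = list(nx.all_simple_paths(link_graph, BASE, tip))
        assert len(paths) == 1
        lengths.append(len(paths[0]) - 1)
    return len(tips), max(lengths), sum(lengths)


# ---------------------------------------------------------------------------
# bottleneck oracle

def bottleneck_brute(a: Barcode, b: Barcode) -> float:
    """Brute-force bottleneck distance: enumerate every assignment of
    A-points to distinct B-points or the diagonal (small diagrams)."""
    pa = [(p.birth, p.death) for p in a.pairs]
    pb = [(p.birth, p.death) for p in b.pairs]

    def linf(p, q):
        return max(abs(p[0] - q[0]), abs(p[1] - q[1]))

    def diag(p):
        return (p[0] - p[1]) / 2.0

    best = math.inf

    def rec(i, used, cur):
        nonlocal best
        if cur >= best:
            return
        if i == len(pa):
            cost = cur
            for j, q in enumerate(pb):
                if j not in used:
                    cost = max(cost, diag(q))
            best = min(best, cost)
            return
        rec(i + 1, used, max(cur, diag(pa[i])))
        for j, q in enumerate(pb):
            if j not in used:
                rec(i + 1, used | {j}, max(cur, linf(pa[i], q)))

    rec(0, frozenset(), 0.0)
    return best


def random_diagram(rng, max_points=6, scale=10.0, source_id=""):
    n = int(rng.integers(1, max_points + 1))
    pairs = []
    for _ in range(n):
        death = rng.uniform(0, scale)
        birth = death + rng.uniform(1e-3, scale)
        pairs.append(PersistencePair(0, float(birth), float(death)))
    return Barcode(pairs=pairs, source_id=source_id)
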
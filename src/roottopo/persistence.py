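"""H0 persistent homology of root systems under the geodesic distance,
and bottleneck distances between the resulting barcodes.

The geodesic distance function is swept from its maximum down to the
base (a superlevel-set filtration on the root-system tree).  Each root
tip is a local maximum and births a connected component at its geodesic
value; when two components meet at a junction, the elder rule applies:
the component with the larger birth (the longer branch) persists and
the other dies at the junction's geodesic value.  The last surviving
component dies at 0, so every bar is finite, births exceed deaths, and
the total persistence equals the total root length exactly.

Bottleneck distances are computed exactly: binary search over the
finite candidate-cost set with a maximum-bipartite-matching feasibility
test (no approximation parameter).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import maximum_bipartite_matching

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PersistencePair:
    """One H0 bar: born at geodesic value ``birth``, dead at ``death``
    (0 for the globally oldest component)."""
    dimension: int
    birth: float
    death: float

    @property
    def persistence(self) -> float:
        return self.birth - self.death


@dataclass
class Barcode:
    """Multiset of H0 persistence pairs for one root system."""
    pairs: list[PersistencePair] = field(default_factory=list)
    source_id: str = ""

    def __len__(self) -> int:
        return len(self.pairs)

    def total_persistence(self) -> float:
        return sum(p.persistence for p in self.pairs)

    def to_frame(self) -> pd.DataFrame:
        """3-column matrix (dimension, birth, death), one row per bar."""
        return pd.DataFrame(
            [(p.dimension, p.birth, p.death) for p in self.pairs],
            columns=["dimension", "birth", "death"],
        )

    def to_array(self) -> np.ndarray:
        """(n, 2) array of (birth, death) points."""
        return np.array([(p.birth, p.death) for p in self.pairs], dtype=float) \
            if self.pairs else np.empty((0, 2))


class _UnionFind:
    def __init__(self):
        self.parent: dict = {}
        # representative tip (birth value, tie-break key) per component
        self.birth: dict = {}

    def add(self, v, birth_value, tiekey):
        self.parent[v] = v
        self.birth[v] = (birth_value, tiekey)

    def find(self, v):
        root = v
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[v] != root:
            self.parent[v], v = root, self.parent[v]
        return root

    def union(self, a, b):
        """Merge components of a and b; return (survivor_root, dying_birth)."""
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return ra, None
        (ba, ka), (bb, kb) = self.birth[ra], self.birth[rb]
        # elder rule: larger birth survives; equal births -> the tip with
        # the smaller (root id, node index) persists
        if ba > bb or (ba == bb and ka < kb):
            survivor, dying = ra, rb
        else:
            survivor, dying = rb, ra
        dying_birth = self.birth[dying][0]
        self.parent[dying] = survivor
        return survivor, dying_birth


def _plant_graph(table: pd.DataFrame, plant: str):
    """Vertex function values and adjacency for one plant's tree.

    Vertices are ``(root, node_index)``; the first nodes of all
    first-order roots collapse into the shared base vertex ``("", 0)``
    with geodesic 0; a lateral's first node is its parent's insertion
    node, re-connecting the forest into one tree.
    """
    sub = table[table["plant"] == plant]
    if sub.empty:
        raise KeyError(f"plant {plant!r} not found in segment table")
    base = ("", 0)
    f = {base: 0.0}
    adj: dict = {base: []}
    known_roots = set(sub["root"])
    orphans = sorted(
        set(sub.loc[(sub["order"] > 1)
                    & ~sub["parent_root"].isin(known_roots), "root"])
    )
    if orphans:
        raise ValueError(
            f"plant {plant!r} is disconnected: roots with missing parents: "
            + ", ".join(map(str, orphans))
        )

    # rows of one root appear in polyline order, so the k-th row of a
    # root ends at polyline node k+1
    groups = {rid: rows.reset_index(drop=True)
              for rid, rows in sub.groupby("root", sort=False)}

    start_vertex: dict = {}

    def resolve_start(rid):
        """Graph vertex standing for polyline node 0 of root `rid`."""
        if rid in start_vertex:
            return start_vertex[rid]
        rows = groups[rid]
        if int(rows.at[0, "order"]) == 1:
            v = base
        else:
            parent = rows.at[0, "parent_root"]
            k = int(rows.at[0, "insertion_node"])
            # node 0 of the parent is itself an alias for the parent's
            # start vertex
            v = resolve_start(parent) if k == 0 else (parent, k)
        start_vertex[rid] = v
        return v

    def add_edge(u, v):
        adj.setdefault(u, []).append(v)
        adj.setdefault(v, []).append(u)

    for rid, rows in groups.items():
        prev = resolve_start(rid)
        for i in range(len(rows)):
            v = (rid, i + 1)
            f[v] = float(rows.at[i, "geodesic"])
            add_edge(prev, v)
            prev = v
    # geodesic values of junction vertices referenced before definition
    for v in list(adj):
        if v not in f:
            rid, idx = v
            f[v] = float(groups[rid].at[idx - 1, "geodesic"])
    return f, adj


def compute_barcode(table: pd.DataFrame, plant: str) -> Barcode:
    """Elder-rule H0 barcode of one plant's geodesic distance function.

    Tips are sorted by decreasing geodesic value and merged with a
    union-find structure keyed by junction values; ties between equal
    births are broken toward the lexicographically smaller tip.
    """
    f, adj = _plant_graph(table, plant)
    verts = sorted(f, key=lambda v: (-f[v], v))
    uf = _UnionFind()
    pairs: list[PersistencePair] = []
    processed = set()
    for v in verts:
        fv = f[v]
        higher = [u for u in adj[v] if u in processed]
        uf.add(v, fv, v)
        processed.add(v)
        for u in higher:
            _, dying_birth = uf.union(v, u)
            if dying_birth is not None and dying_birth > fv:
                pairs.append(PersistencePair(0, dying_birth, fv))
            elif dying_birth is not None and dying_birth == fv:
                # zero-persistence component (degenerate tie): skip the bar
                pass
    # the last component dies at the base (death 0)
    roots_alive = {uf.find(v) for v in f}
    assert len(roots_alive) == 1, "plant graph is disconnected"
    eldest_birth = max(f.values())
    pairs.append(PersistencePair(0, eldest_birth, 0.0))
    pairs.sort(key=lambda p: (-p.birth, -p.death))
    return Barcode(pairs=pairs, source_id=plant)


def compute_barcodes(table: pd.DataFrame) -> list[Barcode]:
    """One barcode per plant present in the segment table."""
    return [compute_barcode(table, p)
            for p in table["plant"].drop_duplicates()]


# ---------------------------------------------------------------------------
# bottleneck distance

def _linf(p: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Pairwise L-infinity distances between diagram points (n,2),(m,2)."""
    if len(p) == 0 or len(q) == 0:
        return np.empty((len(p), len(q)))
    return np.maximum(np.abs(p[:, None, 0] - q[None, :, 0]),
                      np.abs(p[:, None, 1] - q[None, :, 1]))


def _feasible(cross: np.ndarray, pa: np.ndarray, pb: np.ndarray,
              cost: float) -> bool:
    """Is there a perfect matching at bottleneck cost <= cost?

    Bipartite graph: left = points of A plus m diagonal slots, right =
    points of B plus n diagonal slots.  A point may match a point of the
    other diagram within L-inf `cost`, or its diagonal projection when
    persistence/2 <= cost; diagonal-diagonal matches are free.
    """
    n, m = len(pa), len(pb)
    size = n + m
    if size == 0:
        return True
    ii, jj = np.nonzero(cross <= cost)
    ai = np.nonzero(pa / 2.0 <= cost)[0]        # a_i -> its diag slot m+i
    bj = np.nonzero(pb / 2.0 <= cost)[0]        # diag slot n+j -> b_j
    # diagonal-diagonal matches are free (complete n x m block)
    dj = np.repeat(np.arange(n, size), n)
    di = np.tile(np.arange(m, size), m)
    rows = np.concatenate([ii, ai, bj + n, dj])
    cols = np.concatenate([jj, ai + m, bj, di])
    g = csr_matrix((np.ones(len(rows), dtype=np.int8), (rows, cols)),
                   shape=(size, size))
    match = maximum_bipartite_matching(g, perm_type="column")
    return int((match >= 0).sum()) == size


def bottleneck_distance(a: Barcode, b: Barcode) -> float:
    """Exact bottleneck distance between two persistence diagrams.

    Points are (birth, death) with the L-infinity ground metric;
    unmatched points map to the diagonal at cost persistence/2.  Binary
    search over the finite set of candidate costs (all cross L-inf
    distances and all persistence/2 values) with a bipartite matching
    feasibility test.
    """
    pa_pts, pb_pts = a.to_array(), b.to_array()
    if len(pa_pts) == 0 and len(pb_pts) == 0:
        return 0.0
    pa = pa_pts[:, 0] - pa_pts[:, 1] if len(pa_pts) else np.empty(0)
    pb = pb_pts[:, 0] - pb_pts[:, 1] if len(pb_pts) else np.empty(0)
    cross = _linf(pa_pts, pb_pts)
    candidates = np.unique(np.concatenate([
        cross.ravel(), pa / 2.0, pb / 2.0, [0.0]]))
    lo, hi = 0, len(candidates) - 1
    # ensure the largest candidate is feasible (it always is: everything
    # to the diagonal, or any full matching)
    while lo < hi:
        mid = (lo + hi) // 2
        if _feasible(cross, pa, pb, candidates[mid]):
            hi = mid
        else:
            lo = mid + 1
    return float(candidates[lo])


def pairwise_bottleneck(barcodes: list[Barcode]) -> pd.DataFrame:
    """Symmetric pairwise bottleneck-distance matrix over barcodes.

    Computation time grows with the number and complexity of the root
    systems compared; progress is logged per row.
    """
    if len(barcodes) < 2:
        raise ValueError("need at least 2 barcodes")
    ids = [b.source_id for b in barcodes]
    n = len(barcodes)
    d = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        d[i, j] = d[j, i] = bottleneck_distance(barcodes[i], barcodes[j])
        if j == n - 1:
            logger.info("bottleneck row %d/%d done", i + 1, n - 1)
    return pd.DataFrame(d, index=ids, columns=ids)


# ---------------------------------------------------------------------------
# rendering

def render_barcode_text(b: Barcode, width: int = 60) -> str:
    """Plain-text barcode: one bar per line, sorted by birth descending."""
    if not b.pairs:
        raise ValueError("empty barcode")
    vmax = max(p.birth for p in b.pairs)
    lines = [f"barcode {b.source_id or '<unnamed>'} "
             f"({len(b.pairs)} bars, max geodesic {vmax:g})"]
    for p in sorted(b.pairs, key=lambda p: -p.birth):
        left = int(round(p.death / vmax * width)) if vmax else 0
        right = max(left + 1, int(round(p.birth / vmax * width)))
        lines.append(" " * left + "#" * (right - left)
                     + f"  [{p.death:g}, {p.birth:g}]")
    return "\n".join(lines)


def render_barcode(b: Barcode, ax=None):
    """Plot the barcode: horizontal bars from death to birth on the
    geodesic-distance axis, longest (earliest-born) bar on top."""
    import matplotlib.pyplot as plt

    if not b.pairs:
        raise ValueError("empty barcode")
    if ax is None:
        _, ax = plt.subplots(figsize=(6, max(1.5, 0.12 * len(b.pairs))))
    ordered = sorted(b.pairs, key=lambda p: p.birth)
    for k, p in enumerate(ordered):
        ax.hlines(k, p.death, p.birth, lw=2)
    ax.set_xlabel("geodesic distance")
    ax.set_ylabel("H0 bar")
    ax.set_title(b.source_id)
    return ax


def write_barcode(b: Barcode, path) -> None:
    b.to_frame().to_csv(path, index=False)


def write_matrix(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path)


def read_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col=0)
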
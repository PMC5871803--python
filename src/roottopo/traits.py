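"""Aggregated whole-plant traits of a root system.

Twenty whole-plant metrics computed from the segment table, covering
morphology (lengths, diameters, surface, volume), architecture (root
counts per branching order, lateral density, convex hull, depth, width)
and topology (Fitter's magnitude, altitude and external path length).

Mean diameters are length-weighted; the convex hull is the 2D area on
(x, y) for planar data and the 3D hull volume when any z differs from
zero.  Depth is the maximum y (y-down convention); width the maximum
horizontal extent over x (and z in 3D).
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError

from .fitter import FitterIndices

TRAIT_COLUMNS = [
    "TRL", "L1R", "TN1R", "TNLR", "TLRL", "N2LR", "N3LR", "L2LR", "L3LR",
    "MD1", "MDLR", "D2LR", "Convexhull", "Stot", "Vtot",
    "Magnitude", "Altitude", "ExtPathLength", "Depth", "Width",
]


def _hull_measure(points: np.ndarray) -> float:
    """Convex-hull area (2D input) or volume (3D input); 0 when the
    points are degenerate (collinear/coplanar)."""
    planar = np.allclose(points[:, 2], 0.0)
    pts = points[:, :2] if planar else points
    try:
        hull = ConvexHull(pts)
    except (QhullError, ValueError):
        return 0.0
    # scipy names the top-dimensional measure "volume" in both cases
    return float(hull.volume)


def _wmean(values: pd.Series, weights: pd.Series) -> float:
    w = weights.to_numpy(float)
    return float(np.average(values.to_numpy(float), weights=w)) if w.sum() > 0 \
        else math.nan


def compute_traits(table: pd.DataFrame, indices: FitterIndices | None = None,
                   plant: str | None = None) -> pd.Series:
    """Trait vector for exactly one plant of a segment table.

    ``indices`` supplies the Fitter topological indices (computed from
    the tree with :func:`roottopo.fitter.tree_fitter_indices`); when
    omitted those three traits are NaN.
    """
    if plant is not None:
        table = table[table["plant"] == plant]
        if table.empty:
            raise KeyError(f"plant {plant!r} not found in segment table")
    plants = table["plant"].unique()
    if len(plants) != 1:
        raise ValueError(f"expected one plant, found {len(plants)}")

    by_root = table.groupby("root", sort=False)
    root_order = by_root["order"].first()
    root_len = by_root["length"].sum()

    def olen(o):  # total root length at branching order o
        return float(root_len[root_order == o].sum())

    def ocount(o):
        return int((root_order == o).sum())

    first = table["order"] == 1
    lateral = ~first
    trl = float(table["length"].sum())
    l1r = float(table.loc[first, "length"].sum())

    pts = np.column_stack([
        np.concatenate([table["x1"], table["x2"]]),
        np.concatenate([table["y1"], table["y2"]]),
        np.concatenate([table["z1"], table["z2"]]),
    ])
    mean_d = (table["diameter1"] + table["diameter2"]) / 2.0
    planar = np.allclose(pts[:, 2], 0.0)
    width = float(pts[:, 0].max() - pts[:, 0].min()) if planar else \
        float(max(pts[:, 0].max() - pts[:, 0].min(),
                  pts[:, 2].max() - pts[:, 2].min()))

    values = {
        "TRL": trl,
        "L1R": l1r,
        "TN1R": ocount(1),
        "TNLR": int((root_order > 1).sum()),
        "TLRL": float(table.loc[lateral, "length"].sum()),
        "N2LR": ocount(2),
        "N3LR": ocount(3),
        "L2LR": olen(2),
        "L3LR": olen(3),
        "MD1": _wmean(mean_d[first], table.loc[first, "length"]),
        "MDLR": _wmean(mean_d[lateral], table.loc[lateral, "length"])
        if lateral.any() else math.nan,
        "D2LR": ocount(2) / l1r if l1r > 0 else math.nan,
        "Convexhull": _hull_measure(pts),
        "Stot": float(table["surface"].sum()),
        "Vtot": float(table["volume"].sum()),
        "Magnitude": indices.magnitude if indices else math.nan,
        "Altitude": indices.altitude if indices else math.nan,
        "ExtPathLength": indices.external_path_length if indices else math.nan,
        "Depth": float(np.max(pts[:, 1])),
        "Width": width,
    }
    return pd.Series(values, index=TRAIT_COLUMNS, name=plants[0])


def trait_matrix(table: pd.DataFrame,
                 indices: dict[str, FitterIndices] | None = None) -> pd.DataFrame:
    """One trait row per plant (stable column order, PCA-ready).

    ``indices`` maps plant id to its Fitter indices.
    """
    rows = []
    for plant in table["plant"].drop_duplicates():
        idx = indices.get(plant) if indices else None
        rows.append(compute_traits(table, indices=idx, plant=plant))
    return pd.DataFrame(rows)


def write_traits(traits: pd.DataFrame, path) -> None:
    traits.to_csv(path, index_label="plant")


def read_traits(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="plant")
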
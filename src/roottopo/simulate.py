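"""Seeded generator of synthetic root systems.

A minimal root-architecture growth model in the spirit of structural
root models: each axis elongates along its heading at a constant rate,
the heading is pulled toward the gravity vector (gravitropism) and
jittered with Gaussian noise each step, and a new lateral initiates
every ``inter_lateral_distance`` of parent growth up to ``max_order``,
with its insertion angle drawn from a normal distribution.  Diameters
and elongation rates taper geometrically with branching order; node
ages record the simulation time of node creation.

This is deliberately *not* a full architecture model: there is no soil
interaction, no diameter-driven elongation and no root death.  It
exists to produce realistic fibrous and tap-rooted test architectures.

Determinism: every axis owns an RNG seeded from the master seed and the
axis's topological path, so the same ``(params, seed)`` always yields
the same tree and a longer duration strictly extends a shorter one
(total root length is non-decreasing in duration).

Seven genotype presets share a standard parameter set (``mock``) with
exactly one parameter changed: growth rate (``slow`` / ``fast``),
inter-lateral distance (``dense`` / ``sparse``) or gravitropism
(``steep`` / ``shallow``).  Two additional presets give the fibrous
(many first-order axes) and tap-rooted (single dominant axis)
categories.  The preset table ships as a plain YAML config file.
"""

from __future__ import annotations

import importlib.resources
import math
import os
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .rsml import write_rsml
from .tree import Root, RootNode, RootSystemTree

__all__ = ["GenotypeParams", "load_presets", "generate", "generate_library",
           "calibrate_length", "CalibrationError"]


class CalibrationError(RuntimeError):
    pass


@dataclass(frozen=True)
class GenotypeParams:
    """Parameters of one synthetic genotype (lengths in cm, times in days)."""

    name: str
    n_first_order: int = 1
    elongation_rate: float = 2.0          # cm/day, first-order axes
    inter_lateral_distance: float = 1.0   # cm of parent growth per lateral
    insertion_angle_mean: float = 65.0    # degrees from parent heading
    insertion_angle_sd: float = 8.0
    gravitropism_strength: float = 0.12   # per-step pull toward vertical, [0,1]
    heading_noise_sd: float = 6.0         # degrees per step
    elongation_cv: float = 0.15           # per-step elongation noise (CV)
    axis_rate_cv: float = 0.25            # between-axis growth-rate variability
    lateral_spacing_cv: float = 0.25      # variability of inter-lateral spacing
    max_order: int = 3
    diameter_base: float = 0.12           # cm, first-order axes
    diameter_ratio_lateral: float = 0.5   # per-order taper of diameter & rate
    duration: float = 18.0                # days
    step: float = 0.5                     # days

    def validate(self) -> None:
        if self.step <= 0 or self.duration <= 0:
            raise ValueError("duration and step must be positive")
        if not (self.elongation_rate > 0 and self.inter_lateral_distance > 0
                and self.diameter_base > 0):
            raise ValueError("rates and distances must be positive")
        if not (0 < self.diameter_ratio_lateral <= 1):
            raise ValueError("diameter_ratio_lateral must be in (0, 1]")
        if not (0 <= self.gravitropism_strength <= 1):
            raise ValueError("gravitropism_strength must be in [0, 1]")
        if self.n_first_order < 1 or self.max_order < 1:
            raise ValueError("n_first_order and max_order must be >= 1")


def load_presets() -> dict[str, GenotypeParams]:
    """Genotype presets from the packaged config file."""
    text = importlib.resources.files("roottopo").joinpath("presets.yaml") \
        .read_text()
    raw = yaml.safe_load(text)
    base = raw.pop("mock")
    presets = {"mock": GenotypeParams(name="mock", **base)}
    for name, overrides in raw.items():
        merged = dict(base)
        merged.update(overrides or {})
        presets[name] = GenotypeParams(name=name, **merged)
    return presets


class _Axis:
    __slots__ = ("key", "order", "x", "y", "phi", "nodes", "ages",
                 "since_lateral", "next_lateral_at", "rate_factor", "rng",
                 "parent", "insertion_index", "n_children")

    def __init__(self, key, order, x, y, phi, t, seed, parent,
                 insertion_index, params):
        self.key = key
        self.order = order
        self.x, self.y, self.phi = x, y, phi
        self.nodes = [(x, y)]
        self.ages = [t]
        self.since_lateral = 0.0
        self.rng = np.random.default_rng([int(seed) & 0x7FFFFFFF, *key])
        # between-axis growth-rate variability (lognormal, mean ~1)
        self.rate_factor = float(np.exp(
            self.rng.normal(0.0, params.axis_rate_cv)))
        self.next_lateral_at = _draw_spacing(self.rng, params)
        self.parent = parent
        self.insertion_index = insertion_index
        self.n_children = 0


def _draw_spacing(rng, params) -> float:
    spacing = rng.normal(params.inter_lateral_distance,
                         params.lateral_spacing_cv
                         * params.inter_lateral_distance)
    return max(spacing, 0.2 * params.inter_lateral_distance)


def generate(params: GenotypeParams, seed: int,
             plant_id: str | None = None) -> RootSystemTree:
    """Grow one synthetic root system (deterministic given params, seed).

    Coordinates are 2D (z = 0) in a y-down frame with the plant base at
    the origin.
    """
    params.validate()
    n_steps = max(1, int(round(params.duration / params.step)))
    dt = params.step
    axes: list[_Axis] = []
    for k in range(params.n_first_order):
        if params.n_first_order == 1:
            phi0 = 0.0
        else:  # fan the seminal axes out around the vertical
            spread = math.radians(140.0)
            phi0 = -spread / 2 + spread * k / (params.n_first_order - 1)
        ax = _Axis((k,), 1, 0.0, 0.0, phi0, 0.0, seed, None, None, params)
        ax.phi += ax.rng.normal(0.0, math.radians(4.0))
        axes.append(ax)

    for istep in range(n_steps):
        t = (istep + 1) * dt
        for ax in list(axes):  # new laterals grow from the next step on
            rate = params.elongation_rate * ax.rate_factor * \
                params.diameter_ratio_lateral ** (ax.order - 1)
            noise = 1.0 + float(ax.rng.normal(0.0, params.elongation_cv))
            dl = rate * dt * max(0.05, noise)
            # gravitropic pull toward phi = 0, then Gaussian jitter
            ax.phi *= (1.0 - params.gravitropism_strength)
            ax.phi += ax.rng.normal(0.0, math.radians(params.heading_noise_sd))
            ax.x += dl * math.sin(ax.phi)
            ax.y += dl * math.cos(ax.phi)
            ax.nodes.append((ax.x, ax.y))
            ax.ages.append(t)
            ax.since_lateral += dl
            while (ax.since_lateral >= ax.next_lateral_at
                   and ax.order < params.max_order):
                ax.since_lateral -= ax.next_lateral_at
                ax.n_children += 1
                child = _Axis(ax.key + (ax.n_children,), ax.order + 1,
                              ax.x, ax.y, 0.0, t, seed, ax,
                              len(ax.nodes) - 1, params)
                side = 1.0 if child.rng.random() < 0.5 else -1.0
                angle = child.rng.normal(params.insertion_angle_mean,
                                         params.insertion_angle_sd)
                child.phi = ax.phi + side * math.radians(angle)
                axes.append(child)
                ax.next_lateral_at = _draw_spacing(ax.rng, params)

    # drop axes spawned on the last step (no segment yet, no children)
    axes = [ax for ax in axes if len(ax.nodes) >= 2]
    kept = {ax.key for ax in axes}
    id_of = {ax.key: "R" + ".".join(str(i + 1) for i in ax.key) for ax in axes}
    roots = []
    for ax in axes:
        diam = params.diameter_base * \
            params.diameter_ratio_lateral ** (ax.order - 1)
        nodes = [RootNode(x=x, y=y, z=0.0, diameter=diam, age=a)
                 for (x, y), a in zip(ax.nodes, ax.ages)]
        parent_id = None
        if ax.parent is not None:
            if ax.parent.key not in kept:
                continue
            parent_id = id_of[ax.parent.key]
        roots.append(Root(id=id_of[ax.key], order=ax.order, nodes=nodes,
                          parent_id=parent_id,
                          insertion_index=ax.insertion_index))
    tree = RootSystemTree(
        plant_id=plant_id or f"{params.name}_s{seed}", roots=roots)
    tree.validate()
    return tree


def _replicate_seed(master: int, index: int) -> int:
    # stated splitting rule: derived seeds stay below 2^31
    return (int(master) * 1009 + index * 7919 + 1) % (2 ** 31 - 1)


def generate_library(presets: list[GenotypeParams], replicates: int,
                     seed: int, out_dir: str | os.PathLike) -> pd.DataFrame:
    """Write one RSML file per (preset, replicate); return the manifest.

    The manifest records file name, genotype, replicate, derived seed
    and total root length, and is written to ``manifest.csv`` alongside
    the RSML files.
    """
    if not presets or replicates < 1:
        raise ValueError("need at least one preset and one replicate")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    probe = out / ".write_test"
    try:
        probe.touch()
        probe.unlink()
    except OSError as exc:
        raise OSError(f"destination {out} is not writable") from exc
    rows = []
    idx = 0
    for p in presets:
        p.validate()
        for rep in range(1, replicates + 1):
            s = _replicate_seed(seed, idx)
            idx += 1
            tree = generate(p, s, plant_id=f"{p.name}_{rep:02d}")
            fname = f"{p.name}_{rep:02d}.rsml"
            write_rsml([tree], out / fname)
            rows.append((fname, p.name, rep, s, tree.total_length))
    manifest = pd.DataFrame(
        rows, columns=["file", "genotype", "replicate", "seed",
                       "total_root_length"])
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest


def calibrate_length(params: GenotypeParams, target_trl: float,
                     tolerance: float, seed: int,
                     max_iter: int = 40) -> RootSystemTree:
    """Bisection on growth duration until total root length hits the
    target window ``target ± tolerance·target``.

    Relies on total root length being non-decreasing in duration at a
    fixed seed (a property of the per-axis RNG scheme).
    """
    if target_trl <= 0 or not (0 < tolerance < 1):
        raise ValueError("target must be > 0 and tolerance in (0, 1)")
    params.validate()

    def trl_at(duration: float) -> tuple[float, RootSystemTree]:
        t = generate(replace(params, duration=duration), seed)
        return t.total_length, t

    lo, hi = params.step, params.duration
    trl, tree = trl_at(hi)
    if abs(trl - target_trl) <= tolerance * target_trl:
        return tree
    grow = 0
    while trl < target_trl and grow < 12:
        lo, hi = hi, hi * 2
        trl, tree = trl_at(hi)
        grow += 1
        if abs(trl - target_trl) <= tolerance * target_trl:
            return tree
    if trl < target_trl:
        raise CalibrationError(
            f"target {target_trl:g} unreachable; closest TRL {trl:g}")
    best_err, best_tree = abs(trl - target_trl), tree
    for _ in range(max_iter):
        mid = (lo + hi) / 2
        trl, tree = trl_at(mid)
        err = abs(trl - target_trl)
        if err < best_err:
            best_err, best_tree = err, tree
        if err <= tolerance * target_trl:
            return tree
        if trl < target_trl:
            lo = mid
        else:
            hi = mid
        if hi - lo < params.step / 4:
            break
    if best_err <= tolerance * target_trl:
        return best_tree
    raise CalibrationError(
        f"calibration did not converge; closest TRL "
        f"{target_trl + (best_err if best_tree.total_length > target_trl else -best_err):g}"
    )
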
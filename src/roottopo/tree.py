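"""In-memory model of a root system architecture.

A root system is a forest of polyline roots connected through parent
links: first-order roots start at the plant base, laterals of order
``k + 1`` insert on a node of an order-``k`` parent.  Coordinates follow
a y-down convention (depth is positive y); ``flip_y`` converts data
recorded with the opposite convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterator


class ValidationError(ValueError):
    """A tree violates a structural invariant."""


@dataclass
class RootNode:
    """One vertex of a root polyline.

    Coordinates and diameter are in the file's length unit; ``z`` is 0
    for 2D data.  ``age`` (time units) is optional and, when present,
    non-decreasing along the polyline.
    """

    x: float
    y: float
    z: float = 0.0
    diameter: float = 0.0
    age: float | None = None

    def position(self) -> tuple[float, float, float]:
        return (self.x, self.y, self.z)


@dataclass
class Root:
    """A single root: an ordered polyline of nodes plus topology links.

    ``insertion_index`` is the index of the parent-polyline node nearest
    the branching point (None for first-order roots).
    """

    id: str
    order: int
    nodes: list[RootNode]
    parent_id: str | None = None
    insertion_index: int | None = None

    @property
    def length(self) -> float:
        return sum(
            math.dist(a.position(), b.position())
            for a, b in zip(self.nodes, self.nodes[1:])
        )

    @property
    def n_segments(self) -> int:
        return len(self.nodes) - 1


@dataclass
class RootSystemTree:
    """One plant: a connected forest of roots with RSML metadata."""

    plant_id: str
    roots: list[Root] = field(default_factory=list)
    unit: str = "cm"
    resolution: float = 1.0

    def root_by_id(self, root_id: str) -> Root:
        for r in self.roots:
            if r.id == root_id:
                return r
        raise KeyError(f"no root with id {root_id!r} in plant {self.plant_id!r}")

    def children_of(self, root_id: str) -> list[Root]:
        return [r for r in self.roots if r.parent_id == root_id]

    def first_order_roots(self) -> list[Root]:
        return [r for r in self.roots if r.order == 1]

    def iter_nodes(self) -> Iterator[RootNode]:
        for r in self.roots:
            yield from r.nodes

    @property
    def total_length(self) -> float:
        return sum(r.length for r in self.roots)

    def n_tips(self) -> int:
        return len(self.roots)

    def validate(self) -> None:
        """Raise :class:`ValidationError` on any structural defect."""
        if not self.roots:
            raise ValidationError(f"plant {self.plant_id!r} has no roots")
        ids = [r.id for r in self.roots]
        if len(set(ids)) != len(ids):
            raise ValidationError(f"duplicate root ids in plant {self.plant_id!r}")
        by_id = {r.id: r for r in self.roots}
        for r in self.roots:
            if len(r.nodes) < 2:
                raise ValidationError(
                    f"root {r.id!r} has {len(r.nodes)} node(s); at least 2 required"
                )
            if (r.order == 1) != (r.parent_id is None):
                raise ValidationError(
                    f"root {r.id!r}: order {r.order} inconsistent with parent "
                    f"{r.parent_id!r} (order 1 iff no parent)"
                )
            if r.parent_id is not None:
                parent = by_id.get(r.parent_id)
                if parent is None:
                    raise ValidationError(
                        f"root {r.id!r} references missing parent {r.parent_id!r}"
                    )
                if parent.order != r.order - 1:
                    raise ValidationError(
                        f"root {r.id!r} (order {r.order}) attached to parent of "
                        f"order {parent.order}; expected {r.order - 1}"
                    )
                if r.insertion_index is None or not (
                    0 <= r.insertion_index < len(parent.nodes)
                ):
                    raise ValidationError(
                        f"root {r.id!r}: insertion index {r.insertion_index} "
                        f"out of range on parent {r.parent_id!r}"
                    )
            for n in r.nodes:
                if not all(math.isfinite(v) for v in (n.x, n.y, n.z)):
                    raise ValidationError(f"root {r.id!r}: non-finite coordinate")
                if n.diameter < 0:
                    raise ValidationError(f"root {r.id!r}: negative diameter")
            ages = [n.age for n in r.nodes if n.age is not None]
            if ages and any(b < a for a, b in zip(ages, ages[1:])):
                raise ValidationError(f"root {r.id!r}: age decreases along polyline")

    def flip_y(self) -> "RootSystemTree":
        """Return a copy with the y axis negated (convention switch)."""
        roots = [
            replace(r, nodes=[replace(n, y=-n.y) for n in r.nodes])
            for r in self.roots
        ]
        return replace(self, roots=roots)
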
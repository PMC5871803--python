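# Methods

This note documents the models, conventions, numerical choices and
known limitations behind `roottopo`.

## Data model and RSML conventions

A root system is a forest of polyline roots. First-order roots start at
the plant base; a lateral of order k+1 attaches to a node of an
order-k parent (`insertion_index`). Coordinates follow a **y-down**
convention (depth is positive y); `RootSystemTree.flip_y()` converts
data recorded y-up. No unit conversion is performed anywhere: the RSML
metadata unit label (default `cm`) is propagated verbatim.

The RSML reader accepts both common diameter dialects — a per-node
`diameter` sample function or a single root-level diameter broadcast to
all nodes — and treats any polyline `function` whose name contains
"age" or "time" (case-insensitive) as node age; the exact set of
age-function names recognised by other RSML tools is not standardised,
so this substring rule is our choice. When ages are absent,
growth-rate columns are NaN. Optional RSML blocks (properties,
annotations, multi-scene time series) are ignored. A lateral's
insertion index is recovered as the parent node nearest the lateral's
first point.

## Segment table

Every polyline edge becomes one record. The 24-column schema is
`file, plant, root, order, parent_root, apical, time, x1..z2,
diameter1, diameter2, length, surface, volume, orientation,
growth_rate, geodesic, branching_node_geodesic, dist_from_base,
insertion_node`. Column names are our reconstruction of the standard
roles (coordinates, length, diameter, surface, volume, growth rate,
orientation, geodesic distance, ...); `insertion_node` additionally
records the parent polyline index of a lateral's attachment so that
downstream graph construction needs no floating-point matching.

Per-segment geometry treats each segment as a conical frustum with
slant L and end diameters d1, d2:

* surface = π·L·(d1+d2)/2 (reduces to π·d·L for a cylinder),
* volume = (π·L/12)·(d1² + d1·d2 + d2²),
* orientation = angle from the downward vertical, degrees in [0, 180],
* growth_rate = L / (age₂ − age₁), NaN for missing or equal ages.

Geodesic distance accumulates segment lengths from the first node of
each first-order root; a lateral continues from the geodesic value of
its insertion node. Zero-length segments are dropped with a logged
count (`table.attrs["dropped_segments"]`).

## Persistence barcodes (H0, geodesic filtration)

The superlevel-set filtration of the geodesic function on the root
graph is computed by sorting vertices by decreasing geodesic value and
merging with union-find. Each leaf births a component at its geodesic
value; at a junction the component with the larger birth survives
(elder rule) and the other dies at the junction value; the final
component dies at 0, so every bar is finite and births and deaths are
non-negative geodesic values (no negative-axis or infinity
conventions — other implementations may differ by sign or offset).
Consequences used as test invariants: one bar per root tip, one
zero-death bar per first-order root (all seminal axes merge at the
base, geodesic 0), and Σ(birth − death) = total root length exactly.

Tie-breaks: when two components with equal births merge, the one whose
tip has the lexicographically smaller (root id, node index) survives;
zero-persistence pairs (birth = death at a junction) are suppressed. A
plant whose laterals reference missing parents is rejected with the
orphan root ids listed.

All first-order roots of a plant are joined at a single base vertex, so
multi-axis (fibrous) plants form one connected filtration domain.

## Bottleneck distance

Exact, with no approximation parameter: the optimal value is one of the
finitely many candidate costs {all cross L∞ distances} ∪ {all
persistence/2 values} ∪ {0}; a binary search over the sorted candidates
uses a maximum-bipartite-matching feasibility test (points of one
diagram plus diagonal slots for the other; diagonal–diagonal matches
free; scipy's Hopcroft–Karp-based matcher). Diagrams from root systems
here have at most a few hundred points, for which this is exact and
fast (~milliseconds per pair). An empty diagram is handled by matching
every point of the other diagram to the diagonal (cost = max
persistence/2). The test suite checks agreement to 1e-9 with a
brute-force enumeration over all partial matchings on small diagrams,
plus the metric axioms and a stability property under tip
perturbations.

## Fitter indices

The link representation contracts each portion of root between
consecutive branching points into one link; laterals inserted at the
same parent node form a single multi-way branching point, and path
lengths count links, not nodes (whether altitude should be counted in
links or nodes is not universally fixed; we count links and record the
convention). Indices are computed by one post-order recursion over the
link tree — magnitude μ = Σ child μ, altitude = 1 + max child altitude,
Pe = Σ(child Pe) + μ — and are verified against exhaustive base-to-tip
path enumeration and the herringbone closed forms (altitude = μ,
Pe = (μ² + 3μ)/2 − 1).

## Traits

The 20-trait vector covers morphology, architecture and topology: TRL,
L1R, TN1R, TNLR, TLRL, N2LR, N3LR, L2LR, L3LR, MD1, MDLR, D2LR,
Convexhull, Stot, Vtot, Magnitude, Altitude, ExtPathLength, Depth,
Width. The canonical published trait set names 16–18 of these; Depth
(maximum y) and Width (maximum horizontal extent) complete the 20 and
are needed for the steep/shallow genotype contrast — this completion is
our reconstruction. Mean diameters are length-weighted (robust to
heterogeneous vectorisation density). The convex hull is the 2D hull
area on (x, y) for planar data and the 3D hull volume when any z ≠ 0;
degenerate point sets yield 0.

## Synthetic root systems

The generator is a minimal growth model, *not* a full architecture
model: no soil interaction, no diameter-driven elongation, no root
death. Per time step (default 0.5 day) each axis elongates by
rate·dt·(1 + ε), ε ~ N(0, elongation_cv); its heading is pulled toward
the vertical by `gravitropism_strength` and jittered by
N(0, heading_noise_sd); a lateral initiates whenever the parent has
grown the current inter-lateral spacing (drawn per interval,
CV `lateral_spacing_cv`), with insertion angle N(mean, sd) on a random
side. Diameters and elongation rates taper geometrically with order
(`diameter_ratio_lateral`); axes carry a lognormal between-axis rate
factor (`axis_rate_cv`). Defaults (cm, days) are in
`src/roottopo/presets.yaml`: `mock` is the standard set; `slow/fast`,
`dense/sparse` and `steep/shallow` each change exactly one parameter;
`fibrous` (6 seminal axes, thin, order ≤ 2) and `taproot` (one dominant
axis, order ≤ 3) give the two classical categories. Durations are
chosen so default systems carry ~100–300 tips and a few hundred cm of
root — large enough for rich barcodes, small enough that a 100-system
bottleneck matrix computes in about two minutes on one CPU.

Reproducibility: every axis owns an RNG seeded from (master seed,
topological path of the axis), so trees are deterministic given
(params, seed) and a longer duration strictly extends a shorter run —
total root length is monotone in duration, which `calibrate_length`
exploits by bisection (library seeds derive from the master seed by a
fixed affine rule, kept below 2³¹).

What the generator does *not* emulate: tropism interactions with soil
heterogeneity, root death and decay, diameter-dependent elongation, 3D
geometry (generated systems are planar; the analysis side fully
supports 3D inputs and is exercised on hand-built 3D trees in tests).
Passing tests on synthetic data therefore demonstrate correctness of
the pipeline's mathematics and bookkeeping, not biological fidelity of
any particular real data set.

## Ordination and classification

NMDS minimises Kruskal stress-1 over monotone-regression disparities
(SMACOF, scikit-learn backend) with one classical-scaling (Torgerson)
initialisation plus seeded random restarts (default 20), keeping the
best-stress solution; an exactly embeddable distance matrix reaches
stress < 1e-6 via the classical start. An all-zero matrix returns
coincident points with stress 0. PCA standardises variables to unit
variance (correlation-matrix PCA); constant columns are dropped with a
warning. The 2-class split used in the fibrous/taproot demonstration is
partitioning-around-medoids, solved exactly for k = 2 by exhaustive
search over medoid pairs.

## Problem sizes and known limitations

The packaged demonstration compares 50 fibrous + 50 tap-rooted systems
length-matched into a 1000 cm ± 15% total-root-length window (the
selection-window protocol at half scale); length matching matters
because the bottleneck distance is a max-norm dominated by the longest
bar, i.e. by overall geodesic extent, and without it size differences
mask topology. Even with matching, the k-medoids recovery of the two
categories from the NMDS embedding is seed-sensitive — across held-out
seed blocks we observe recoveries from ~0.65 to 1.00 (typically
≥ 0.93) — because the bottleneck metric reflects only the single
worst-matched bar, giving between/within distance ratios of only
~1.3–1.5. This mirrors the method's character: barcode comparisons
separate gross architectural classes clearly on average but are not a
high-power classifier. Other limitations: only H0 under the geodesic
filtration (no H1+, no alternative filtration functions); no DART
ingestion; no time-resolved (multi-scene) RSML.
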
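"""Elder-rule barcodes and bottleneck distances, against independent
oracles (threshold-sweep component tracking; brute-force matching)."""

import itertools

import numpy as np
import pytest

from roottopo import (Barcode, PersistencePair, bottleneck_distance,
                      build_segment_table, compute_barcode, compute_barcodes,
                      pairwise_bottleneck, render_barcode_text)
from roottopo.persistence import render_barcode
from rt_testutil import (barcode_oracle, barcode_pairs, bottleneck_brute,
                         random_diagram, random_tree, single_root_tree,
                         y_tree)


def _barcode_of(tree):
    return compute_barcode(build_segment_table([tree]), tree.plant_id)


def test_single_root_is_one_bar_dying_at_zero():
    b = _barcode_of(single_root_tree(length=5.0))
    assert barcode_pairs(b) == [(0, 5.0, 0.0)]


def test_y_tree_elder_rule():
    b = _barcode_of(y_tree())
    assert barcode_pairs(b) == [(0, 5.0, 0.0), (0, 3.0, 2.0)]


def test_barcode_structural_invariants(rng):
    tree = random_tree(rng, max_tips=30)
    b = _barcode_of(tree)
    # one bar per tip; a root whose last node carries a lateral has no
    # distinct tip of its own
    absorbed = {r.parent_id for r in tree.roots
                if r.parent_id is not None and r.insertion_index
                == len(tree.root_by_id(r.parent_id).nodes) - 1}
    assert len(b) == len(tree.roots) - len(absorbed)
    # seminal axes merge only at the base, so one zero-death bar per
    # first-order root; the eldest bar spans the full geodesic range
    zero_deaths = [p for p in b.pairs if p.death == 0.0]
    assert len(zero_deaths) == len(tree.first_order_roots())
    assert max(p.birth for p in zero_deaths) == pytest.approx(
        max(p.birth for p in b.pairs))
    assert b.total_persistence() == pytest.approx(tree.total_length,
                                                  rel=1e-9)
    assert all(p.birth > p.death >= 0 for p in b.pairs)


def test_elder_rule_matches_threshold_sweep_oracle(rng):
    for _ in range(50):
        tree = random_tree(rng, max_tips=int(rng.integers(2, 40)))
        got = barcode_pairs(_barcode_of(tree))
        expected = barcode_oracle(tree)
        assert len(got) == len(expected)
        for (d1, b1, x1), (d2, b2, x2) in zip(got, expected):
            assert d1 == d2
            assert b1 == pytest.approx(b2, rel=1e-9, abs=1e-12)
            assert x1 == pytest.approx(x2, rel=1e-9, abs=1e-12)


def test_disconnected_plant_rejected():
    table = build_segment_table([y_tree()])
    broken = table.copy()
    broken.loc[broken["root"] == "R1.1", "parent_root"] = "ghost"
    with pytest.raises(ValueError, match="ghost|disconnected"):
        compute_barcode(broken, "y")


def test_barcode_frame_has_three_columns():
    frame = _barcode_of(y_tree()).to_frame()
    assert list(frame.columns) == ["dimension", "birth", "death"]
    assert (frame["dimension"] == 0).all()


# ---------------------------------------------------------------------------
# bottleneck

def test_bottleneck_identity_is_zero(rng):
    b = random_diagram(rng, max_points=6)
    assert bottleneck_distance(b, b) == 0.0


def test_bottleneck_to_empty_diagram_is_half_max_persistence():
    a = Barcode([PersistencePair(0, 5.0, 0.0)], "a")
    assert bottleneck_distance(a, Barcode([], "e")) == pytest.approx(2.5)
    assert bottleneck_distance(Barcode([], "e"), a) == pytest.approx(2.5)


def test_bottleneck_two_point_example():
    a = Barcode([PersistencePair(0, 5, 0), PersistencePair(0, 3, 2)], "a")
    b = Barcode([PersistencePair(0, 5, 0), PersistencePair(0, 3.4, 2)], "b")
    assert bottleneck_distance(a, b) == pytest.approx(0.4, abs=1e-12)


def test_bottleneck_agrees_with_brute_force_on_random_pairs(rng):
    for _ in range(50):
        a = random_diagram(rng, max_points=6)
        b = random_diagram(rng, max_points=6)
        assert bottleneck_distance(a, b) == pytest.approx(
            bottleneck_brute(a, b), abs=1e-9)


def test_metric_axioms_on_random_diagrams(rng):
    diagrams = [random_diagram(rng, max_points=5, source_id=str(i))
                for i in range(10)]
    n = len(diagrams)
    d = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        d[i, j] = d[j, i] = bottleneck_distance(diagrams[i], diagrams[j])
        assert d[i, j] >= 0
    for i, j, k in itertools.permutations(range(n), 3):
        assert d[i, k] <= d[i, j] + d[j, k] + 1e-12


def test_identity_of_indiscernibles(rng):
    a = random_diagram(rng, max_points=4)
    shifted = Barcode([PersistencePair(0, p.birth + 0.5, p.death)
                       for p in a.pairs], "s")
    assert bottleneck_distance(a, shifted) > 0
    same = Barcode(list(reversed(a.pairs)), "same")
    assert bottleneck_distance(a, same) == 0.0


def test_stability_under_tip_perturbation(rng):
    tree = random_tree(rng, max_tips=20)
    b = _barcode_of(tree)
    eps = 0.01 * max(p.birth for p in b.pairs)
    noisy = Barcode([
        PersistencePair(0, p.birth + float(rng.uniform(-eps, eps)), p.death)
        for p in b.pairs], "noisy")
    assert bottleneck_distance(b, noisy) <= eps + 1e-12


def test_pairwise_matrix_symmetry_and_consistency(rng):
    diagrams = [random_diagram(rng, max_points=5, source_id=f"d{i}")
                for i in range(4)]
    m = pairwise_bottleneck(diagrams)
    assert (m.values == m.values.T).all()
    assert np.allclose(np.diag(m.values), 0.0)
    assert m.iloc[1, 2] == pytest.approx(
        bottleneck_distance(diagrams[1], diagrams[2]))
    identical = pairwise_bottleneck([diagrams[0], diagrams[0]])
    assert (identical.values == 0).all()


def test_pairwise_needs_two_barcodes(rng):
    with pytest.raises(ValueError):
        pairwise_bottleneck([random_diagram(rng)])


# ---------------------------------------------------------------------------
# rendering

def test_text_rendering_has_one_bar_per_pair():
    b = _barcode_of(y_tree())
    text = render_barcode_text(b)
    assert text.count("#") > 0
    assert len(text.splitlines()) == len(b) + 1
    # longest bar rendered first
    assert "[0, 5]" in text.splitlines()[1]


def test_plot_rendering_bar_count():
    import matplotlib
    matplotlib.use("Agg")
    b = _barcode_of(y_tree())
    ax = render_barcode(b)
    assert len(ax.collections) == len(b)
    import matplotlib.pyplot as plt
    plt.close(ax.figure)


def test_empty_barcode_rendering_rejected():
    with pytest.raises(ValueError):
        render_barcode_text(Barcode([], "e"))
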
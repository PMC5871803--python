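"""Synthetic root-system generator: determinism, genotype contrasts,
length calibration."""

import math

import pytest

from roottopo import (GenotypeParams, build_segment_table, calibrate_length,
                      compute_traits, generate, generate_library,
                      load_presets, tree_fitter_indices)


@pytest.fixture(scope="module")
def presets():
    return load_presets()


def _traits(tree):
    return compute_traits(build_segment_table([tree]),
                          tree_fitter_indices(tree))


def test_presets_cover_the_seven_genotypes_plus_categories(presets):
    assert {"mock", "dense", "sparse", "steep", "shallow", "slow",
            "fast"} <= set(presets)
    assert {"fibrous", "taproot"} <= set(presets)
    # each named genotype differs from mock in exactly one parameter
    mock = presets["mock"]
    for name in ("dense", "sparse", "steep", "shallow", "slow", "fast"):
        diffs = [f for f in GenotypeParams.__dataclass_fields__
                 if f != "name"
                 and getattr(presets[name], f) != getattr(mock, f)]
        assert len(diffs) == 1, (name, diffs)


def test_same_params_and_seed_give_identical_trees(presets):
    a = generate(presets["mock"], 42)
    b = generate(presets["mock"], 42)
    assert len(a.roots) == len(b.roots)
    for ra, rb in zip(a.roots, b.roots):
        assert ra.id == rb.id
        assert all(na.position() == nb.position()
                   for na, nb in zip(ra.nodes, rb.nodes))
    c = generate(presets["mock"], 43)
    assert a.total_length != c.total_length


def test_generated_trees_are_valid(presets, rng):
    for name in ("mock", "fibrous", "taproot"):
        tree = generate(presets[name], int(rng.integers(0, 1000)))
        tree.validate()  # raises on any invariant violation


def test_dense_has_more_laterals_than_sparse(presets):
    for seed in (1, 2, 3):
        dense = _traits(generate(presets["dense"], seed))
        sparse = _traits(generate(presets["sparse"], seed))
        assert dense["TNLR"] > sparse["TNLR"]


def test_fibrous_has_more_first_order_roots_than_taproot(presets):
    for seed in (1, 2):
        fib = _traits(generate(presets["fibrous"], seed))
        tap = _traits(generate(presets["taproot"], seed))
        assert fib["TN1R"] > tap["TN1R"]
        assert fib["L1R"] > tap["L1R"]


def test_genotype_contrasts_over_replicates(presets):
    """steep grows deeper than shallow; fast longer than slow; dense
    carries more laterals than sparse (n = 10 fixed seeds each)."""
    seeds = range(10)

    def mean(name, trait, ratio=None):
        vals = []
        for s in seeds:
            tv = _traits(generate(presets[name], s))
            vals.append(tv[trait] if ratio is None
                        else tv[trait] / tv[ratio])
        return sum(vals) / len(vals)

    assert mean("steep", "Depth", "Width") > mean("shallow", "Depth", "Width")
    assert mean("fast", "TRL") > mean("slow", "TRL")
    assert mean("dense", "TNLR") > mean("sparse", "TNLR")


def test_trl_monotone_in_duration(presets):
    from dataclasses import replace
    p = presets["mock"]
    trls = [generate(replace(p, duration=d), 7).total_length
            for d in (4, 8, 12, 16, 20)]
    assert trls == sorted(trls)
    assert trls[-1] > trls[0]


def test_library_bookkeeping(tmp_path, presets):
    manifest = generate_library([presets["mock"], presets["steep"]],
                                replicates=1, seed=3, out_dir=tmp_path)
    assert len(manifest) == 2
    for row in manifest.itertuples():
        assert (tmp_path / row.file).exists()
    assert (tmp_path / "manifest.csv").exists()
    # manifest TRL equals TRL recomputed through the pipeline
    from roottopo import read_rsml
    for row in manifest.itertuples():
        tree = read_rsml(tmp_path / row.file)[0]
        tv = _traits(tree)
        assert tv["TRL"] == pytest.approx(row.total_root_length, rel=1e-6)


def test_invalid_parameters_rejected(presets):
    from dataclasses import replace
    with pytest.raises(ValueError):
        generate(replace(presets["mock"], step=-1.0), 0)
    with pytest.raises(ValueError):
        generate(replace(presets["mock"], duration=0.0), 0)
    with pytest.raises(ValueError):
        generate_library([], replicates=1, seed=0, out_dir=".")


def test_calibration_loose_tolerance_converges_fast(presets):
    tree = calibrate_length(presets["mock"], target_trl=50.0,
                            tolerance=0.5, seed=1)
    assert abs(tree.total_length - 50.0) <= 0.5 * 50.0


def test_calibration_hits_target_window(presets):
    tree = calibrate_length(presets["taproot"], target_trl=600.0,
                            tolerance=0.15, seed=4)
    assert 510.0 <= tree.total_length <= 690.0
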
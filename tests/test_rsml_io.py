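"""RSML reading, writing and round-trip fidelity."""

import math

import pytest

from roottopo import (RSMLParseError, ValidationError, generate,
                      generate_library, load_presets, read_rsml, write_rsml)
from rt_testutil import random_tree, y_tree


def test_minimal_document_round_trips_structure(minimal_rsml_text):
    trees = read_rsml(minimal_rsml_text)
    assert len(trees) == 1
    t = trees[0]
    assert t.unit == "cm"
    assert len(t.roots) == 1
    root = t.roots[0]
    assert len(root.nodes) == 2
    assert root.nodes[1].y == 5
    assert root.nodes[0].diameter == pytest.approx(0.1)
    assert all(n.z == 0 for n in root.nodes)


def test_nested_laterals_get_orders_and_parent_links(nested_rsml_text):
    t = read_rsml(nested_rsml_text)[0]
    assert t.unit == "mm" and t.resolution == 2
    assert len(t.roots) == 3
    axis = t.root_by_id("axis")
    assert axis.order == 1 and axis.parent_id is None
    for rid, ins in [("lat1", 1), ("lat2", 2)]:
        lat = t.root_by_id(rid)
        assert lat.order == 2
        assert lat.parent_id == "axis"
        assert lat.insertion_index == ins
    # root-level diameter absent on lat2 -> broadcast default 0
    assert t.root_by_id("lat2").nodes[0].diameter == 0.0


def test_order_equals_parent_order_plus_one_after_reading(nested_rsml_text):
    t = read_rsml(nested_rsml_text)[0]
    for r in t.roots:
        if r.parent_id is not None:
            assert r.order == t.root_by_id(r.parent_id).order + 1


@pytest.mark.parametrize("seed", [0, 7])
def test_write_read_round_trip_preserves_geometry(seed, rng):
    tree = random_tree(rng, max_tips=15) if seed else \
        generate(load_presets()["mock"], 11)
    text = write_rsml([tree]).decode()
    back = read_rsml(text)[0]
    assert len(back.roots) == len(tree.roots)
    for a, b in zip(tree.roots, sorted(back.roots, key=lambda r: [
            x.id for x in tree.roots].index(r.id))):
        assert a.id == b.id and a.order == b.order
        assert a.parent_id == b.parent_id
        assert a.insertion_index == b.insertion_index
        for na, nb in zip(a.nodes, b.nodes):
            assert math.dist(na.position(), nb.position()) < 1e-6
            assert abs(na.diameter - nb.diameter) < 1e-6
    assert abs(back.total_length - tree.total_length) < 1e-5


def test_age_function_round_trips():
    tree = generate(load_presets()["mock"], 3)
    back = read_rsml(write_rsml([tree]).decode())[0]
    orig = {r.id: [n.age for n in r.nodes] for r in tree.roots}
    for r in back.roots:
        assert orig[r.id] == pytest.approx([n.age for n in r.nodes], abs=1e-6)


def test_malformed_xml_raises_parse_error():
    with pytest.raises(RSMLParseError, match="line"):
        read_rsml("<rsml><scene><plant><root></scene></rsml>")


def test_single_node_root_raises_validation_error_naming_root():
    bad = """<rsml><metadata><unit>cm</unit></metadata><scene><plant ID="p">
    <root ID="stub"><geometry><polyline><point x="0" y="0"/></polyline>
    </geometry></root></plant></scene></rsml>"""
    with pytest.raises(ValidationError, match="stub"):
        read_rsml(bad)


def test_missing_geometry_raises():
    bad = """<rsml><scene><plant ID="p"><root ID="r"/></plant></scene></rsml>"""
    with pytest.raises(RSMLParseError, match="geometry"):
        read_rsml(bad)


def test_write_empty_list_raises_before_writing(tmp_path):
    out = tmp_path / "x.rsml"
    with pytest.raises(ValidationError):
        write_rsml([], out)
    assert not out.exists()


def test_written_document_structure_counts():
    text = write_rsml([y_tree()]).decode()
    assert text.count("<root ") == 2
    # axis has 3 points, lateral 2
    assert text.count("<point ") == 5


def test_library_round_trip_preserves_root_counts(tmp_path):
    presets = load_presets()
    manifest = generate_library([presets["fibrous"], presets["taproot"]],
                                replicates=2, seed=5, out_dir=tmp_path)
    assert len(manifest) == 4
    for row in manifest.itertuples():
        back = read_rsml(tmp_path / row.file)[0]
        assert back.total_length == pytest.approx(row.total_root_length,
                                                  rel=1e-6)
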
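"""Snapshot serialization, storage and lifecycle."""

import hashlib
import json

import pytest
from hypothesis import given, settings, strategies as st

from pipetest.channels import ChannelMap, FileRef
from pipetest.snapshots import (
    SnapshotError, SnapshotStore, canonical_serialize, record_or_compare,
    render_diff, snapshot_digest,
)


def test_file_reference_serializes_as_basename_md5(tmp_path):
    f = tmp_path / "x.txt"
    f.write_bytes(b"ACGT\n")
    # digest computed with an independent md5 call on the raw bytes
    expected = hashlib.md5(b"ACGT\n").hexdigest()
    assert canonical_serialize(FileRef(f)) == f'"x.txt:md5,{expected}"'


def test_empty_mapping_and_sorted_keys():
    assert canonical_serialize({}) == "{}"
    text = canonical_serialize({"b": 1, "a": 2})
    assert text.index('"a"') < text.index('"b"')


def test_digest_of_empty_mapping_is_md5_of_two_bytes():
    assert snapshot_digest(canonical_serialize({})) == \
        hashlib.md5(b"{}").hexdigest()


def test_channels_canonicalized_before_serialization():
    a = canonical_serialize({"ch": [["b"], ["a"]]})
    b = canonical_serialize({"ch": [["a"], ["b"]]})
    assert a == b
    assert canonical_serialize(ChannelMap({"ch": [[2], [1]]})) == \
        canonical_serialize(ChannelMap({"ch": [[1], [2]]}))


json_values = st.recursive(
    st.none() | st.booleans() | st.integers(-9, 9) |
    st.floats(-5, 5, allow_nan=False) | st.text(max_size=5),
    lambda c: st.lists(c, max_size=3) |
    st.dictionaries(st.text(max_size=3), c, max_size=3),
    max_leaves=10)


@settings(max_examples=100, deadline=None)
@given(json_values)
def test_serialize_parse_serialize_idempotent(value):
    once = canonical_serialize(value)
    assert canonical_serialize(json.loads(once)) == once


def test_lifecycle_create_then_match(tmp_path):
    store = SnapshotStore.load(tmp_path / "s.snap")
    assert record_or_compare(store, "k", {"a": 1}).event == "created"
    reloaded = SnapshotStore.load(tmp_path / "s.snap")
    assert record_or_compare(reloaded, "k", {"a": 1}).event == "matched"


def test_single_byte_file_perturbation_mismatches(tmp_path):
    f = tmp_path / "out.bin"
    f.write_bytes(b"AAAA")
    store = SnapshotStore.load(tmp_path / "s.snap")
    record_or_compare(store, "k", {"file": FileRef(f)})
    f.write_bytes(b"AAAB")
    reloaded = SnapshotStore.load(tmp_path / "s.snap")
    outcome = record_or_compare(reloaded, "k", {"file": FileRef(f)})
    assert outcome.event == "mismatched"
    assert "md5," in outcome.diff  # diff shows the differing digests


def test_update_then_verify_passes(tmp_path):
    store = SnapshotStore.load(tmp_path / "s.snap")
    record_or_compare(store, "k", {"v": 1})
    outcome = record_or_compare(store, "k", {"v": 2}, mode="update")
    assert outcome.event == "updated"
    reloaded = SnapshotStore.load(tmp_path / "s.snap")
    assert record_or_compare(reloaded, "k", {"v": 2}).event == "matched"


def test_ci_mode_missing_reference_fails_and_never_writes(tmp_path):
    path = tmp_path / "s.snap"
    store = SnapshotStore.load(path)
    outcome = record_or_compare(store, "k", {"v": 1}, mode="ci")
    assert outcome.event == "mismatched"
    assert not path.exists()


def test_ci_mode_differing_reference_fails(tmp_path):
    store = SnapshotStore.load(tmp_path / "s.snap")
    record_or_compare(store, "k", {"v": 1})
    before = (tmp_path / "s.snap").read_bytes()
    outcome = record_or_compare(store, "k", {"v": 2}, mode="ci")
    assert outcome.event == "mismatched"
    assert (tmp_path / "s.snap").read_bytes() == before


def test_comparison_invariant_to_tuple_input_order(tmp_path):
    store = SnapshotStore.load(tmp_path / "s.snap")
    record_or_compare(store, "k", {"ch": [["b", 1], ["a", 2]]})
    reloaded = SnapshotStore.load(tmp_path / "s.snap")
    outcome = record_or_compare(reloaded, "k", {"ch": [["a", 2], ["b", 1]]})
    assert outcome.event == "matched"


def test_compressed_snapshot_stores_digest_only(tmp_path):
    store = SnapshotStore.load(tmp_path / "s.snap")
    record_or_compare(store, "k", {"v": [1, 2]}, compressed=True)
    raw = json.loads((tmp_path / "s.snap").read_text())
    assert "md5" in raw["k"] and "content" not in raw["k"]
    reloaded = SnapshotStore.load(tmp_path / "s.snap")
    assert record_or_compare(reloaded, "k", {"v": [1, 2]},
                             compressed=True).event == "matched"
    assert record_or_compare(reloaded, "k", {"v": [1, 3]},
                             compressed=True).event == "mismatched"


def test_digest_changes_with_any_nested_value():
    base = snapshot_digest(canonical_serialize({"a": {"b": [1, 2]}}))
    other = snapshot_digest(canonical_serialize({"a": {"b": [1, 3]}}))
    assert base != other


def test_store_rewrite_is_byte_identical(tmp_path):
    store = SnapshotStore.load(tmp_path / "s.snap")
    record_or_compare(store, "k", {"a": 1})
    first = (tmp_path / "s.snap").read_bytes()
    reloaded = SnapshotStore.load(tmp_path / "s.snap")
    reloaded.save()
    assert (tmp_path / "s.snap").read_bytes() == first


def test_corrupt_store_errors_no_silent_overwrite(tmp_path):
    path = tmp_path / "s.snap"
    path.write_text("{ not json")
    with pytest.raises(SnapshotError, match="corrupt"):
        SnapshotStore.load(path)
    assert path.read_text() == "{ not json"


def test_render_diff_line_granular():
    ref = canonical_serialize({"a": 1, "b": [1, 2]})
    assert render_diff(ref, ref) == ""
    actual = canonical_serialize({"a": 1, "b": [1, 3]})
    diff = render_diff(ref, actual)
    removed = [ln for ln in diff.splitlines()
               if ln.startswith("-") and not ln.startswith("---")]
    added = [ln for ln in diff.splitlines()
             if ln.startswith("+") and not ln.startswith("+++")]
    assert len(removed) == 1 and len(added) == 1  # one leaf per line

    grown = canonical_serialize({"a": 1, "ab": 9, "b": [1, 2]})
    diff2 = render_diff(ref, grown)
    assert not [ln for ln in diff2.splitlines()
                if ln.startswith("-") and not ln.startswith("---")]
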
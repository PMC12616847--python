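"""Snapshot testing: canonical serialization, storage, comparison.

A snapshot records the canonical serialization of a value (typically a
channel mapping) keyed by name in a JSON store living beside the suite
(``<suite>.snap``).  Files are never stored by content — a file reference
serializes as ``"<basename>:md5,<hex>"``.  Whole snapshots can be reduced
to a single MD5 for a compressed representation.

The serialized form is deterministic: mappings sort their keys, channel
tuple lists are canonically ordered before serialization, and the pretty
layout puts one leaf per line so stores diff cleanly under version
control.
"""

from __future__ import annotations

import difflib
import hashlib
import json
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path
from typing import Any, Optional

from pipetest.channels import ChannelMap, FileRef, sort_channel

FRAMEWORK_VERSION = "0.1.0"


class SnapshotError(RuntimeError):
    pass


def _convert(value: Any) -> Any:
    """Reduce a value to plain JSON types with canonical channel order.

    A list whose elements are all lists/tuples is treated as a channel
    (tuples arrive in nondeterministic order) and sorted; scalar lists
    keep their order.
    """
    if isinstance(value, FileRef):
        return value.serialized()
    if isinstance(value, ChannelMap):
        return {k: _convert(sort_channel(v)) for k, v in value.items()}
    if isinstance(value, dict):
        return {str(k): _convert(v) for k, v in value.items()}
    if isinstance(value, (list, tuple)):
        items = list(value)
        if items and all(isinstance(x, (list, tuple)) for x in items):
            items = sort_channel(items)
        return [_convert(x) for x in items]
    if isinstance(value, (str, int, float, bool)) or value is None:
        return value
    raise SnapshotError(
        f"cannot serialize value of type {type(value).__name__}")


def canonical_serialize(value: Any) -> str:
    """Canonical JSON text: sorted keys, UTF-8, one leaf per line,
    shortest round-trip floats, files as ``basename:md5,<hex>``."""
    return json.dumps(_convert(value), indent=2, sort_keys=True,
                      ensure_ascii=False)


def snapshot_digest(serialized: str) -> str:
    """MD5 of the exact serialized bytes — the compressed representation
    of an entire snapshot."""
    return hashlib.md5(serialized.encode("utf-8")).hexdigest()


def render_diff(reference: str, actual: str) -> str:
    """Unified line diff of two canonical texts (empty when equal)."""
    lines = difflib.unified_diff(
        reference.splitlines(keepends=True), actual.splitlines(keepends=True),
        fromfile="reference", tofile="actual", lineterm="\n")
    out = []
    for ln in lines:
        out.append(ln if ln.endswith("\n") else ln + "\n")
    return "".join(out)


@dataclass
class SnapshotStore:
    """One JSON store per suite, mapping key → recorded content."""

    path: Path
    entries: dict[str, dict]
    meta: dict

    @classmethod
    def load(cls, path: str | Path) -> "SnapshotStore":
        path = Path(path)
        if not path.exists():
            return cls(path=path, entries={},
                       meta={"framework_version": FRAMEWORK_VERSION})
        try:
            raw = json.loads(path.read_text())
        except (json.JSONDecodeError, OSError) as exc:
            raise SnapshotError(
                f"corrupt snapshot store {path}: {exc}") from exc
        if not isinstance(raw, dict):
            raise SnapshotError(f"corrupt snapshot store {path}: not a "
                                f"JSON object")
        meta = raw.pop("meta", {"framework_version": FRAMEWORK_VERSION})
        entries = {}
        for key, entry in raw.items():
            if not isinstance(entry, dict) or \
                    ("content" not in entry and "md5" not in entry):
                raise SnapshotError(
                    f"corrupt snapshot store {path}: bad entry {key!r}")
            entries[key] = entry
        return cls(path=path, entries=entries, meta=meta)

    def save(self) -> None:
        doc: dict[str, Any] = {"meta": self.meta}
        doc.update(self.entries)
        text = json.dumps(doc, indent=2, sort_keys=True, ensure_ascii=False)
        self.path.parent.mkdir(parents=True, exist_ok=True)
        self.path.write_text(text + "\n")

    def reference_text(self, key: str) -> Optional[str]:
        entry = self.entries.get(key)
        if entry is None:
            return None
        if "content" in entry:
            return json.dumps(entry["content"], indent=2, sort_keys=True,
                              ensure_ascii=False)
        return None  # compressed entry: compare digests instead

    def reference_digest(self, key: str) -> Optional[str]:
        entry = self.entries.get(key)
        if entry is None:
            return None
        if "md5" in entry:
            return entry["md5"]
        return snapshot_digest(self.reference_text(key))


@dataclass
class SnapshotOutcome:
    key: str
    event: str  # created | matched | mismatched | updated
    diff: str = ""


def record_or_compare(store: SnapshotStore, key: str, value: Any,
                      mode: str = "verify",
                      compressed: bool = False) -> SnapshotOutcome:
    """Record a new snapshot or compare against the stored reference.

    Modes: ``verify`` — first run creates and passes, later runs must
    match; ``update`` — overwrite the reference with the actual value;
    ``ci`` — strict: a missing or differing reference fails and the store
    is never written.
    """
    if mode not in ("verify", "update", "ci"):
        raise ValueError(f"unknown snapshot mode {mode!r}")
    actual_text = canonical_serialize(value)
    actual_digest = snapshot_digest(actual_text)
    now = datetime.now(timezone.utc).isoformat(timespec="seconds")

    def entry() -> dict:
        if compressed:
            return {"md5": actual_digest, "created_at": now}
        return {"content": json.loads(actual_text), "created_at": now}

    existing = store.entries.get(key)

    if mode == "update":
        event = "updated" if existing is not None else "created"
        store.entries[key] = entry()
        store.save()
        return SnapshotOutcome(key, event)

    if existing is None:
        if mode == "ci":
            return SnapshotOutcome(
                key, "mismatched",
                f"no reference snapshot for key {key!r} (CI mode forbids "
                f"creation)")
        store.entries[key] = entry()
        store.save()
        return SnapshotOutcome(key, "created")

    ref_text = store.reference_text(key)
    if ref_text is None:  # compressed reference
        if store.reference_digest(key) == actual_digest:
            return SnapshotOutcome(key, "matched")
        return SnapshotOutcome(
            key, "mismatched",
            f"snapshot md5 differs: reference "
            f"{store.reference_digest(key)} != actual {actual_digest}")
    if ref_text == actual_text:
        return SnapshotOutcome(key, "matched")
    return SnapshotOutcome(key, "mismatched", render_diff(ref_text, actual_text))
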
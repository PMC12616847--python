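"""Channel values, file references, and canonical tuple ordering.

Pipeline units emit output *channels*: streams of tuples whose arrival
order is nondeterministic under parallel execution.  Assertions and
snapshots must therefore never depend on arrival order — every channel is
canonically sorted before evaluation or storage.

The total order is frozen: values rank by type
(null < boolean < number < text < file reference < list < mapping), then
within a type numbers compare numerically, text bytewise (UTF-8), file
references by (basename, content MD5), lists elementwise with the shorter
prefix first, and mappings as their sorted key/value lists.
"""

from __future__ import annotations

import hashlib
from functools import total_ordering
from pathlib import Path
from typing import Any, Iterable


@total_ordering
class FileRef:
    """Reference to a produced file; identity is (basename, content MD5).

    The MD5 is computed lazily on first use and cached, so building large
    output listings stays cheap until a digest is actually needed.
    """

    __slots__ = ("path", "_md5")

    def __init__(self, path: str | Path, md5: str | None = None):
        self.path = Path(path)
        self._md5 = md5

    @property
    def basename(self) -> str:
        return self.path.name

    @property
    def md5(self) -> str:
        if self._md5 is None:
            try:
                digest = hashlib.md5()
                with open(self.path, "rb") as fh:
                    for chunk in iter(lambda: fh.read(1 << 16), b""):
                        digest.update(chunk)
            except OSError as exc:
                raise FileNotFoundError(
                    f"cannot read referenced file {self.path}: {exc}"
                ) from exc
            self._md5 = digest.hexdigest()
        return self._md5

    def serialized(self) -> str:
        return f"{self.basename}:md5,{self.md5}"

    def __eq__(self, other) -> bool:
        if not isinstance(other, FileRef):
            return NotImplemented
        return (self.basename, self.md5) == (other.basename, other.md5)

    def __lt__(self, other) -> bool:
        if not isinstance(other, FileRef):
            return NotImplemented
        return (self.basename, self.md5) < (other.basename, other.md5)

    def __hash__(self) -> int:
        return hash((self.basename, self.md5))

    def __repr__(self) -> str:
        return f"FileRef({self.path})"


_RANK_NULL, _RANK_BOOL, _RANK_NUM, _RANK_TEXT, _RANK_FILE, _RANK_LIST, \
    _RANK_MAP = range(7)


def canonical_key(value: Any) -> tuple:
    """Sort key realizing the frozen total order over nested values."""
    if value is None:
        return (_RANK_NULL,)
    if isinstance(value, bool):
        return (_RANK_BOOL, int(value))
    if isinstance(value, (int, float)):
        return (_RANK_NUM, float(value))
    if isinstance(value, str):
        return (_RANK_TEXT, value.encode("utf-8"))
    if isinstance(value, FileRef):
        return (_RANK_FILE, (value.basename, value.md5))
    if isinstance(value, (list, tuple)):
        return (_RANK_LIST, tuple(canonical_key(v) for v in value))
    if isinstance(value, dict):
        return (_RANK_MAP, tuple(sorted(
            (canonical_key(k), canonical_key(v)) for k, v in value.items())))
    raise TypeError(f"unorderable value of type {type(value).__name__}")


def sort_channel(tuples: Iterable[Any]) -> list:
    """Canonically order a channel's tuples; idempotent and
    permutation-invariant."""
    return sorted(tuples, key=canonical_key)


class ChannelMap(dict):
    """Mapping channel name → sorted tuple list, with a failure-friendly
    lookup: a missing channel is an assertion failure, not a crash."""

    def __getitem__(self, key):
        from pipetest.exprs import AssertionFailure
        if key not in self:
            raise AssertionFailure(f"missing channel {key!r}")
        return dict.__getitem__(self, key)

    def canonicalized(self) -> "ChannelMap":
        return ChannelMap({k: sort_channel(v) for k, v in self.items()})
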
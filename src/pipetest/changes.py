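"""Changed-file detection from version control.

The VCS client is invoked as an external operating-system process behind a
narrow adapter, so every consumer (the firewall, the CLI) is testable with
a stub returning canned change sets.  Only Git is implemented; the adapter
surface permits other backends.

Untracked (non-ignored) files count as changes — a freshly written suite
must run.  Renames contribute both the old and the new path, since either
may carry graph edges.
"""

from __future__ import annotations

import subprocess
from dataclasses import dataclass, field
from pathlib import Path
from typing import Protocol

from pipetest.model import norm_rel


class VcsError(RuntimeError):
    pass


@dataclass(frozen=True)
class ChangeSet:
    files: frozenset[str]
    source: str  # working_tree | commit_range | explicit

    @classmethod
    def explicit(cls, files) -> "ChangeSet":
        return cls(frozenset(norm_rel(f) for f in files), "explicit")


class VcsAdapter(Protocol):
    def working_tree_files(self, repo_root: Path) -> set[str]: ...
    def diff_files(self, repo_root: Path, ref_from: str,
                   ref_to: str) -> set[str]: ...


@dataclass
class GitAdapter:
    """Thin wrapper over the ``git`` executable."""

    git_exe: str = "git"

    def _run(self, repo_root: Path, *args: str) -> str:
        try:
            proc = subprocess.run(
                [self.git_exe, "-C", str(repo_root), *args],
                capture_output=True, text=True, check=False)
        except FileNotFoundError as exc:
            raise VcsError(f"{self.git_exe} not found on PATH") from exc
        if proc.returncode != 0:
            raise VcsError(
                f"git {' '.join(args)} failed: {proc.stderr.strip()}")
        return proc.stdout

    def is_repo(self, repo_root: Path) -> bool:
        try:
            out = self._run(repo_root, "rev-parse", "--is-inside-work-tree")
        except VcsError:
            return False
        return out.strip() == "true"

    def working_tree_files(self, repo_root: Path) -> set[str]:
        # porcelain v1 -z: NUL-separated entries; renames carry two paths
        out = self._run(repo_root, "status", "--porcelain", "-z",
                        "--untracked-files=all")
        files: set[str] = set()
        fields = out.split("\0")
        i = 0
        while i < len(fields):
            entry = fields[i]
            if not entry:
                i += 1
                continue
            status, path = entry[:2], entry[3:]
            files.add(norm_rel(path))
            if status[0] in "RC" and i + 1 < len(fields) and fields[i + 1]:
                files.add(norm_rel(fields[i + 1]))  # rename/copy source
                i += 1
            i += 1
        return files

    def diff_files(self, repo_root: Path, ref_from: str,
                   ref_to: str) -> set[str]:
        for ref in (ref_from, ref_to):
            try:
                self._run(repo_root, "rev-parse", "--verify",
                          f"{ref}^{{commit}}")
            except VcsError as exc:
                raise VcsError(f"cannot resolve revision {ref!r}") from exc
        out = self._run(repo_root, "diff", "--name-status", "-z",
                        "--find-renames", ref_from, ref_to)
        files: set[str] = set()
        fields = out.split("\0")
        i = 0
        while i < len(fields):
            status = fields[i]
            if not status:
                i += 1
                continue
            if status[0] in "RC":
                files.add(norm_rel(fields[i + 1]))
                files.add(norm_rel(fields[i + 2]))
                i += 3
            else:
                files.add(norm_rel(fields[i + 1]))
                i += 2
        return files


@dataclass
class StubAdapter:
    """Canned change sets, for testing selection logic without a repo."""

    working: set[str] = field(default_factory=set)
    diffs: dict[tuple[str, str], set[str]] = field(default_factory=dict)

    def working_tree_files(self, repo_root: Path) -> set[str]:
        return set(self.working)

    def diff_files(self, repo_root: Path, ref_from: str,
                   ref_to: str) -> set[str]:
        return set(self.diffs.get((ref_from, ref_to), set()))


def working_tree_changes(repo_root: str | Path,
                         adapter: VcsAdapter | None = None) -> ChangeSet:
    """Union of unstaged, staged, and untracked (non-ignored) files."""
    repo_root = Path(repo_root)
    adapter = adapter or GitAdapter()
    if isinstance(adapter, GitAdapter) and not adapter.is_repo(repo_root):
        raise VcsError(
            f"{repo_root} is not inside a version-controlled tree; "
            f"pass changed files explicitly with --related-tests")
    files = adapter.working_tree_files(repo_root)
    return ChangeSet(frozenset(files), "working_tree")


def changes_between(repo_root: str | Path, ref_from: str, ref_to: str,
                    adapter: VcsAdapter | None = None) -> ChangeSet:
    """Files differing between two revisions' trees."""
    repo_root = Path(repo_root)
    adapter = adapter or GitAdapter()
    files = adapter.diff_files(repo_root, ref_from, ref_to)
    return ChangeSet(frozenset(files), "commit_range")
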
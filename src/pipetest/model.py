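"""Core domain types: test subjects, cases, suites, results, project config.

A *test subject* is one executable unit of a dataflow pipeline — a process
(single tool invocation), a workflow (composition of processes), the
top-level pipeline, or a plain function.  One suite file describes one
subject and holds one or more named cases, each with a ``when`` block
(input parameters) and a ``then`` block (assertions) and/or snapshot
expressions.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path, PurePosixPath
from typing import Any, Optional

import yaml


class UnitKind(enum.Enum):
    """Kind of pipeline unit a suite tests.

    Sort order (function < process < workflow < pipeline) reflects the
    testing pyramid: cheap unit tests run before integration and
    end-to-end tests in deterministic plans.
    """

    FUNCTION = "function"
    PROCESS = "process"
    WORKFLOW = "workflow"
    PIPELINE = "pipeline"

    @property
    def order(self) -> int:
        return _KIND_ORDER[self]

    def __lt__(self, other: "UnitKind") -> bool:
        if not isinstance(other, UnitKind):
            return NotImplemented
        return self.order < other.order

    @classmethod
    def parse(cls, text: str) -> "UnitKind":
        try:
            return cls(text.strip().lower())
        except ValueError:
            raise SpecError(
                f"unknown unit kind {text!r}; expected one of "
                f"{[k.value for k in cls]}"
            ) from None


_KIND_ORDER = {
    UnitKind.FUNCTION: 0,
    UnitKind.PROCESS: 1,
    UnitKind.WORKFLOW: 2,
    UnitKind.PIPELINE: 3,
}


class SpecError(ValueError):
    """A test-specification file violates the schema or grammar.

    Carries the offending path and, when known, a 1-based line number.
    """

    def __init__(self, message: str, path: Optional[str] = None,
                 line: Optional[int] = None):
        self.path = path
        self.line = line
        loc = ""
        if path is not None:
            loc = f"{path}:" + (f"{line}: " if line is not None else " ")
        super().__init__(loc + message)


def norm_rel(path: Any) -> str:
    """Normalize a project-relative path to `/`-separated form.

    Suite and component identities in reports, snapshots and the
    dependency graph use these keys on every platform.
    """
    return PurePosixPath(str(path).replace("\\", "/")).as_posix()


@dataclass(frozen=True)
class TestSubject:
    __test__ = False  # domain class, not a pytest collection target
    kind: UnitKind
    name: str
    script_path: str  # project-relative, '/'-separated
    entry_name: str = ""  # process/workflow/function name inside the script


@dataclass
class TestCase:
    __test__ = False  # domain class, not a pytest collection target
    name: str
    tags: frozenset[str] = frozenset()
    when_params: dict[str, Any] = field(default_factory=dict)
    then_assertions: list[Any] = field(default_factory=list)  # AssertionExpr
    snapshot_keys: list[str] = field(default_factory=list)
    snapshot_exprs: list[Any] = field(default_factory=list)  # AssertionExpr


@dataclass
class TestSuite:
    __test__ = False  # domain class, not a pytest collection target
    suite_path: str  # project-relative, '/'-separated
    subject: TestSubject
    cases: list[TestCase]
    declared_assets: list[str] = field(default_factory=list)
    dialect: str = "native"  # "native" | "compat"
    tags: frozenset[str] = frozenset()

    def __post_init__(self):
        if not self.cases:
            raise SpecError("suite declares no test cases", self.suite_path)
        seen: set[str] = set()
        for c in self.cases:
            if c.name in seen:
                raise SpecError(
                    f"duplicate case name {c.name!r}", self.suite_path)
            seen.add(c.name)


@dataclass
class SnapshotEvent:
    key: str
    event: str  # created | matched | mismatched | updated
    diff: str = ""


@dataclass
class TestResult:
    __test__ = False  # domain class, not a pytest collection target
    suite_path: str
    case_name: str
    status: str  # passed | failed | errored | skipped
    failures: list[tuple[str, str]] = field(default_factory=list)
    duration_s: float = 0.0
    snapshot_events: list[SnapshotEvent] = field(default_factory=list)
    message: str = ""

    @property
    def identity(self) -> str:
        return f"{self.suite_path}::{self.case_name}"


DEFAULT_PATTERNS = ["tests/**/*.test.yaml", "**/*.nf.test"]


@dataclass
class ProjectConfig:
    """Per-project configuration, read from ``pipetest.config.yaml``.

    ``triggers`` are globs naming files whose change forces a full retest
    (container recipes, global config).  ``snapshot_suffix`` is appended to
    a suite path to locate its snapshot store.
    """

    tests_dir: str = "tests"
    patterns: list[str] = field(default_factory=lambda: list(DEFAULT_PATTERNS))
    triggers: list[str] = field(default_factory=list)
    plugins: list[str] = field(default_factory=list)
    snapshot_suffix: str = ".snap"

    @classmethod
    def load(cls, project_root: Path) -> "ProjectConfig":
        cfg_path = Path(project_root) / "pipetest.config.yaml"
        if not cfg_path.is_file():
            return cls()
        with open(cfg_path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise SpecError("config must be a mapping", str(cfg_path))
        return cls(
            tests_dir=raw.get("testsDir", "tests"),
            patterns=list(raw.get("patterns", DEFAULT_PATTERNS)),
            triggers=list(raw.get("triggers", [])),
            plugins=list(raw.get("plugins", [])),
            snapshot_suffix=raw.get("snapshotSuffix", ".snap"),
        )
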
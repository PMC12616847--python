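"""Test planning, sharding, backends, and case execution.

The runner materializes each case in an isolated work directory, asks a
*backend* to execute the subject with the case's ``when`` parameters, and
receives :class:`UnitOutputs` — exit status, named output channels,
produced files, captured stdout/stderr.  Channels are canonically sorted
(arrival order is nondeterministic under parallel execution), then the
``then`` assertions and snapshot expressions are evaluated.

Three backends ship with the framework:

``replay``   canned outputs from a fixture file — deterministic, used to
             test the framework itself and for worked examples;
``command``  the subject is an executable command template; produced
             files are gathered by declared globs into pseudo-channel
             ``out``;
``engine``   renders a driver workflow that includes the subject script,
             binds the when-parameters and serializes each output channel
             as JSON, then invokes the external workflow engine as a
             separate process (requires the engine on PATH).

Plans are sorted by (unit kind, suite path, case index) so every machine
derives the same order, which makes coordinator-free sharding possible:
``chunk`` splits the list into contiguous blocks whose sizes differ by at
most one, ``round_robin`` deals entries out cyclically.
"""

from __future__ import annotations

import hashlib
import json
import logging
import shlex
import shutil
import subprocess
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import yaml

from pipetest.channels import ChannelMap, FileRef, sort_channel  # noqa: F401
from pipetest.exprs import (
    AssertionExpr, AssertionFailure, Environment, EvalError, evaluate,
)
from pipetest.model import SnapshotEvent, TestCase, TestResult, TestSuite
from pipetest.plugins import PluginRegistry, default_registry
from pipetest.reporters import RunReport
from pipetest.snapshots import SnapshotStore, record_or_compare

logger = logging.getLogger("pipetest.execution")


# ------------------------------------------------------------ planning

@dataclass
class TestPlan:
    __test__ = False  # domain class, not a pytest collection target
    entries: list[tuple[str, str]] = field(default_factory=list)
    suites: dict[str, TestSuite] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.entries)


def order_tests(suites: list[TestSuite]) -> TestPlan:
    """Deterministic plan: suites by (unit kind, path), cases in suite
    order.  Invariant to the input permutation."""
    ordered = sorted(suites, key=lambda s: (s.subject.kind.order,
                                            s.suite_path))
    plan = TestPlan()
    seen: set[tuple[str, str]] = set()
    for suite in ordered:
        plan.suites[suite.suite_path] = suite
        for case in suite.cases:
            key = (suite.suite_path, case.name)
            if key not in seen:
                seen.add(key)
                plan.entries.append(key)
    return plan


@dataclass(frozen=True)
class ShardSpec:
    index: int  # 1-based
    total: int
    strategy: str = "chunk"  # chunk | round_robin

    def __post_init__(self):
        if self.total < 1 or not (1 <= self.index <= self.total):
            raise ValueError(
                f"invalid shard {self.index}/{self.total}")
        if self.strategy not in ("chunk", "round_robin"):
            raise ValueError(f"unknown shard strategy {self.strategy!r}")

    @classmethod
    def parse(cls, text: str, strategy: str = "chunk") -> "ShardSpec":
        try:
            i, n = text.split("/")
            return cls(int(i), int(n), strategy)
        except ValueError as exc:
            raise ValueError(
                f"shard must look like 'i/n', got {text!r}") from exc


def shard(plan: TestPlan, spec: ShardSpec) -> TestPlan:
    """This machine's subset; all machines partition the same sorted list."""
    n, i = spec.total, spec.index - 1
    if spec.strategy == "round_robin":
        entries = [e for j, e in enumerate(plan.entries) if j % n == i]
    else:
        total = len(plan.entries)
        base, rem = divmod(total, n)
        start = i * base + min(i, rem)
        size = base + (1 if i < rem else 0)
        entries = plan.entries[start:start + size]
    sub = TestPlan(entries=entries)
    for spath, _ in entries:
        if spath in plan.suites:
            sub.suites[spath] = plan.suites[spath]
    return sub


# ------------------------------------------------------------- outputs

@dataclass
class UnitOutputs:
    exit_status: int = 0
    channels: ChannelMap = field(default_factory=ChannelMap)
    produced_files: list[FileRef] = field(default_factory=list)
    stdout: str = ""
    stderr: str = ""
    duration_s: float = 0.0

    def canonicalized(self) -> "UnitOutputs":
        return UnitOutputs(
            exit_status=self.exit_status,
            channels=self.channels.canonicalized(),
            produced_files=list(self.produced_files),
            stdout=self.stdout,
            stderr=self.stderr,
            duration_s=self.duration_s,
        )


class BackendError(RuntimeError):
    pass


class BackendUnavailable(BackendError):
    """The backend cannot run this suite here (e.g. no engine on PATH)."""


# ------------------------------------------------------------- backends

class ReplayBackend:
    """Canned outputs keyed by ``<suite path>::<case name>``.

    The fixture is a YAML mapping; ``files`` entries are paths relative to
    the project root and become file references in pseudo-channel entries
    and ``out.files``.
    """

    name = "replay"
    capabilities = {"native"}

    def __init__(self, outputs: dict[str, dict] | str | Path,
                 project_root: Optional[Path] = None):
        if isinstance(outputs, (str, Path)):
            fixture_path = Path(outputs)
            with open(fixture_path) as fh:
                outputs = yaml.safe_load(fh) or {}
            if project_root is None:
                project_root = fixture_path.parent
        self.outputs = outputs
        self.project_root = Path(project_root) if project_root else Path(".")

    def run(self, suite: TestSuite, case: TestCase,
            workdir: Path) -> UnitOutputs:
        key = f"{suite.suite_path}::{case.name}"
        canned = self.outputs.get(key) or self.outputs.get(suite.suite_path)
        if canned is None:
            raise BackendError(f"no canned outputs for {key}")
        channels = ChannelMap()
        for name, tuples in (canned.get("channels") or {}).items():
            channels[name] = [self._hydrate(t) for t in tuples]
        files = [FileRef(self.project_root / p)
                 for p in (canned.get("files") or [])]
        return UnitOutputs(
            exit_status=int(canned.get("exit_status", 0)),
            channels=channels,
            produced_files=files,
            stdout=canned.get("stdout", ""),
            stderr=canned.get("stderr", ""),
        )

    def _hydrate(self, value: Any) -> Any:
        if isinstance(value, dict) and set(value) == {"file"}:
            return FileRef(self.project_root / value["file"])
        if isinstance(value, list):
            return [self._hydrate(v) for v in value]
        if isinstance(value, dict):
            return {k: self._hydrate(v) for k, v in value.items()}
        return value


class CommandBackend:
    """Runs the case's ``command`` parameter as a subprocess in the work
    directory; globs in the ``collect`` parameter gather produced files
    into pseudo-channel ``out``."""

    name = "command"
    capabilities = {"native"}

    def __init__(self, project_root: Optional[Path] = None):
        self.project_root = Path(project_root) if project_root else Path(".")

    def run(self, suite: TestSuite, case: TestCase,
            workdir: Path) -> UnitOutputs:
        params = dict(case.when_params.get("params", {}))
        template = case.when_params.get("command")
        if not template:
            raise BackendError(
                "command backend requires a 'command' when-parameter")
        cmd = template.format(**params) if params else template
        proc = subprocess.run(
            shlex.split(cmd), cwd=workdir, capture_output=True, text=True)
        globs = case.when_params.get("collect", ["*"])
        produced: list[FileRef] = []
        for pattern in globs:
            produced.extend(FileRef(p) for p in sorted(workdir.glob(pattern))
                            if p.is_file())
        channels = ChannelMap()
        channels["out"] = [[ref] for ref in produced]
        return UnitOutputs(
            exit_status=proc.returncode,
            channels=channels,
            produced_files=produced,
            stdout=proc.stdout,
            stderr=proc.stderr,
        )


_DRIVER_TEMPLATE = """\
include {{ {entry} }} from '{script}'

workflow {{
    def result = {entry}({args})
    // each output channel is serialized as one JSON document
{serializers}
}}
"""


class EngineBackend:
    """Drives the external workflow engine through a generated driver
    script.  The driver includes the subject script, binds the
    when-parameters and writes each output channel as a JSON document in
    the work directory, which the runner parses back into channels."""

    name = "engine"
    capabilities = {"native", "compat"}

    def __init__(self, engine_exe: str = "nextflow",
                 project_root: Optional[Path] = None):
        self.engine_exe = engine_exe
        self.project_root = Path(project_root) if project_root else Path(".")

    def available(self) -> bool:
        return shutil.which(self.engine_exe) is not None

    def render_driver(self, suite: TestSuite, case: TestCase) -> str:
        entry = suite.subject.entry_name or suite.subject.name
        script = "../" + suite.subject.script_path
        params = case.when_params.get("params", {})
        args = ", ".join(json.dumps(v) for v in params.values())
        serializers = (
            "    result.out.each { ch -> "
            "file(\"channels.json\").text = groovy.json.JsonOutput.toJson(ch) }"
        )
        return _DRIVER_TEMPLATE.format(
            entry=entry, script=script, args=args, serializers=serializers)

    def run(self, suite: TestSuite, case: TestCase,
            workdir: Path) -> UnitOutputs:
        if not self.available():
            raise BackendUnavailable(
                f"workflow engine {self.engine_exe!r} not found on PATH")
        driver = workdir / "driver.nf"
        driver.write_text(self.render_driver(suite, case))
        proc = subprocess.run(
            [self.engine_exe, "run", str(driver)],
            cwd=workdir, capture_output=True, text=True)
        channels = ChannelMap()
        doc = workdir / "channels.json"
        if doc.is_file():
            for name, tuples in json.loads(doc.read_text()).items():
                channels[name] = tuples
        return UnitOutputs(
            exit_status=proc.returncode,
            channels=channels,
            stdout=proc.stdout,
            stderr=proc.stderr,
        )


BACKENDS = {"replay": ReplayBackend, "command": CommandBackend,
            "engine": EngineBackend}


# ------------------------------------------------------------ assertions

@dataclass
class AssertionOutcome:
    source: str
    status: str  # passed | failed | errored
    message: str = ""


def build_environment(outputs: UnitOutputs, params: dict,
                      registry: Optional[PluginRegistry] = None
                      ) -> Environment:
    registry = registry or default_registry()
    out = {
        "channels": outputs.channels,
        "files": list(outputs.produced_files),
        "exit_status": outputs.exit_status,
        "stdout": outputs.stdout,
        "stderr": outputs.stderr,
    }
    return Environment(
        names={"out": out, "params": dict(params)},
        namespaces=registry.namespaces(),
    )


def evaluate_then(case: TestCase, outputs: UnitOutputs,
                  plugin_registry: Optional[PluginRegistry] = None
                  ) -> list[AssertionOutcome]:
    """Evaluate a case's assertions against canonicalized outputs.

    A falsy result or a definite failure (missing channel) marks the
    assertion failed; an evaluation error (unknown namespace, plugin
    raised) marks it errored.
    """
    env = build_environment(outputs, case.when_params.get("params", {}),
                            plugin_registry)
    outcomes: list[AssertionOutcome] = []
    for expr in case.then_assertions:
        source = expr.source if isinstance(expr, AssertionExpr) else str(expr)
        try:
            value = evaluate(expr, env)
        except AssertionFailure as exc:
            outcomes.append(AssertionOutcome(source, "failed", str(exc)))
            continue
        except EvalError as exc:
            outcomes.append(AssertionOutcome(source, "errored", str(exc)))
            continue
        if bool(value):
            outcomes.append(AssertionOutcome(source, "passed"))
        else:
            outcomes.append(AssertionOutcome(
                source, "failed", f"assertion evaluated to {value!r}"))
    return outcomes


# --------------------------------------------------------------- runner

@dataclass
class RunOptions:
    update_snapshots: bool = False
    ci_mode: bool = False
    workdir_root: Optional[Path] = None
    seed: int = 0
    keep_workdirs: bool = False
    project_root: Path = Path(".")
    snapshot_suffix: str = ".snap"
    registry: Optional[PluginRegistry] = None


def _case_workdir(root: Path, suite_path: str, case_name: str) -> Path:
    digest = hashlib.md5(f"{suite_path}::{case_name}".encode()).hexdigest()[:10]
    return root / digest


def run_plan(plan: TestPlan, backend, options: Optional[RunOptions] = None
             ) -> RunReport:
    """Execute every (suite, case) entry of the plan and aggregate results.

    The process exit-code contract lives on the report: success iff no
    case failed or errored.
    """
    options = options or RunOptions()
    registry = options.registry or default_registry()
    workroot = options.workdir_root or (
        Path(options.project_root) / ".pipetest" / "work")
    report = RunReport()
    t_start = time.monotonic()
    stores: dict[str, SnapshotStore] = {}
    snapshot_mode = ("update" if options.update_snapshots
                     else "ci" if options.ci_mode else "verify")

    for suite_path, case_name in plan.entries:
        suite = plan.suites[suite_path]
        case = next(c for c in suite.cases if c.name == case_name)

        if suite.dialect == "compat" and \
                "compat" not in getattr(backend, "capabilities", set()):
            report.results.append(TestResult(
                suite_path, case_name, "skipped",
                message=f"compat suite requires an engine backend; "
                        f"{getattr(backend, 'name', '?')} cannot run it"))
            continue

        t0 = time.monotonic()
        workdir = _case_workdir(workroot, suite_path, case_name)
        workdir.mkdir(parents=True, exist_ok=True)
        try:
            outputs = backend.run(suite, case, workdir)
        except BackendUnavailable as exc:
            report.results.append(TestResult(
                suite_path, case_name, "skipped", message=str(exc)))
            continue
        except BackendError as exc:
            report.results.append(TestResult(
                suite_path, case_name, "errored",
                duration_s=time.monotonic() - t0, message=str(exc)))
            continue

        outputs = outputs.canonicalized()
        outcomes = evaluate_then(case, outputs, registry)
        failures = [(o.source, o.message) for o in outcomes
                    if o.status == "failed"]
        errored = [o for o in outcomes if o.status == "errored"]

        snapshot_events: list[SnapshotEvent] = []
        if case.snapshot_exprs:
            store = stores.get(suite_path)
            if store is None:
                store = SnapshotStore.load(
                    Path(options.project_root) /
                    (suite_path + options.snapshot_suffix))
                stores[suite_path] = store
            env = build_environment(
                outputs, case.when_params.get("params", {}), registry)
            for key, expr in zip(case.snapshot_keys, case.snapshot_exprs):
                try:
                    value = evaluate(expr, env)
                except (AssertionFailure, EvalError) as exc:
                    failures.append((expr.source, f"snapshot expression "
                                     f"failed: {exc}"))
                    continue
                outcome = record_or_compare(store, key, value, snapshot_mode)
                snapshot_events.append(SnapshotEvent(
                    key, outcome.event, outcome.diff))

        mismatched = any(ev.event == "mismatched" for ev in snapshot_events)
        if errored:
            status, message = "errored", errored[0].message
        elif failures or mismatched:
            status, message = "failed", ""
        else:
            status, message = "passed", ""
        duration = time.monotonic() - t0
        report.results.append(TestResult(
            suite_path, case_name, status, failures=failures,
            duration_s=duration, snapshot_events=snapshot_events,
            message=message))

        if status == "passed" and not options.keep_workdirs:
            shutil.rmtree(workdir, ignore_errors=True)

    report.duration_s = time.monotonic() - t_start
    return report
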
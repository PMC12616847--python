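"""Parser for the native declarative suite dialect (YAML).

Schema::

    suite:
      name: fastqc            # suite name
      subject:
        kind: process         # process | workflow | pipeline | function
        script: ../modules/fastqc.nf   # relative to this suite file
        entry: FASTQC         # unit name inside the script (empty for pipelines)
      tags: [fast]            # optional, inherited by every case
      assets: [data/input.csv]          # optional test assets
    tests:
      - name: single end
        tags: [se]
        when:
          params: {reads: "input.fastq"}
        then:
          - out.exit_status == 0
          - out.channels["versions"] | size == 1
        snapshot:
          - out.channels["html"]

A case must declare at least one ``then`` assertion or one ``snapshot``
expression.  ``when`` may be absent (functions can take no input).
"""

from __future__ import annotations

import posixpath
from pathlib import Path
from typing import Any, Optional

import yaml

from pipetest.exprs import AssertionExpr
from pipetest.model import (
    SpecError, TestCase, TestSubject, TestSuite, UnitKind, norm_rel,
)


class _LineLoader(yaml.SafeLoader):
    """SafeLoader that annotates every mapping with its source line."""


def _construct_mapping(loader: _LineLoader, node: yaml.Node):
    mapping = loader.construct_mapping(node, deep=True)
    mapping["__line__"] = node.start_mark.line + 1
    return mapping


_LineLoader.add_constructor(
    yaml.resolver.BaseResolver.DEFAULT_MAPPING_TAG, _construct_mapping)


def _line(mapping: Any, default: Optional[int] = None) -> Optional[int]:
    if isinstance(mapping, dict):
        return mapping.get("__line__", default)
    return default


def _resolve_script(suite_path: str, script_ref: str,
                    project_root: Optional[Path]) -> str:
    """Resolve the subject script relative to the suite file and express it
    project-relative with '/' separators."""
    suite_dir = posixpath.dirname(norm_rel(suite_path))
    resolved = posixpath.normpath(posixpath.join(suite_dir, script_ref))
    if project_root is not None:
        # keep within-project keys relative even if the suite path was absolute
        root = norm_rel(Path(project_root).resolve())
        if resolved.startswith(root + "/"):
            resolved = resolved[len(root) + 1:]
    return resolved


def parse_native_suite(path: str | Path,
                       project_root: Optional[str | Path] = None) -> TestSuite:
    """Parse one native YAML suite file into a :class:`TestSuite`.

    ``project_root``, when given, rebases the suite path and the subject
    script to project-relative keys.
    """
    path = Path(path)
    try:
        with open(path) as fh:
            raw = yaml.load(fh, Loader=_LineLoader)
    except yaml.MarkedYAMLError as exc:
        mark = exc.problem_mark
        raise SpecError(
            f"malformed YAML: {exc.problem}", str(path),
            None if mark is None else mark.line + 1) from exc
    except OSError as exc:
        raise SpecError(f"cannot read suite: {exc}", str(path)) from exc

    if project_root is not None:
        try:
            rel = path.resolve().relative_to(Path(project_root).resolve())
            suite_key = norm_rel(rel)
        except ValueError:
            suite_key = norm_rel(path)
    else:
        suite_key = norm_rel(path)

    spath = str(path)
    if not isinstance(raw, dict):
        raise SpecError("suite file must be a YAML mapping", spath)
    head = raw.get("suite")
    if not isinstance(head, dict):
        raise SpecError("missing 'suite' mapping", spath, _line(raw))
    subject_raw = head.get("subject")
    if not isinstance(subject_raw, dict):
        raise SpecError("missing 'suite.subject' mapping", spath, _line(head))

    kind_text = subject_raw.get("kind")
    if not isinstance(kind_text, str):
        raise SpecError("subject.kind must be a string",
                        spath, _line(subject_raw))
    try:
        kind = UnitKind.parse(kind_text)
    except SpecError as exc:
        raise SpecError(str(exc), spath, _line(subject_raw)) from None

    script_ref = subject_raw.get("script")
    if not isinstance(script_ref, str) or not script_ref:
        raise SpecError("subject.script is required",
                        spath, _line(subject_raw))
    entry = subject_raw.get("entry", "") or ""
    name = head.get("name") or path.stem

    subject = TestSubject(
        kind=kind,
        name=str(name),
        script_path=_resolve_script(
            suite_key, script_ref,
            Path(project_root) if project_root is not None else None),
        entry_name=str(entry),
    )

    suite_tags = frozenset(map(str, head.get("tags") or []))
    assets = [norm_rel(a) for a in (head.get("assets") or [])]

    tests_raw = raw.get("tests")
    if not isinstance(tests_raw, list) or not tests_raw:
        raise SpecError("suite must declare a non-empty 'tests' list",
                        spath, _line(raw))

    cases: list[TestCase] = []
    for entry_raw in tests_raw:
        if not isinstance(entry_raw, dict):
            raise SpecError("each test must be a mapping", spath, _line(raw))
        tline = _line(entry_raw)
        case_name = entry_raw.get("name")
        if not isinstance(case_name, str) or not case_name:
            raise SpecError("test requires a 'name'", spath, tline)
        case_tags = frozenset(map(str, entry_raw.get("tags") or []))

        when = entry_raw.get("when") or {}
        if not isinstance(when, dict):
            raise SpecError("'when' must be a mapping", spath, tline)
        when = {k: _strip_lines(v) for k, v in when.items()
                if k != "__line__"}

        then_raw = entry_raw.get("then") or []
        snap_raw = entry_raw.get("snapshot") or []
        if not isinstance(then_raw, list) or not isinstance(snap_raw, list):
            raise SpecError("'then' and 'snapshot' must be lists",
                            spath, tline)
        if not then_raw and not snap_raw:
            raise SpecError(
                f"test {case_name!r} declares neither assertions nor "
                f"snapshots", spath, tline)

        try:
            assertions = [AssertionExpr(str(src)) for src in then_raw]
            snap_exprs = [AssertionExpr(str(src)) for src in snap_raw]
        except SpecError as exc:
            raise SpecError(str(exc), spath, tline) from None

        snap_keys = [case_name if i == 0 else f"{case_name}.{i + 1}"
                     for i in range(len(snap_exprs))]
        cases.append(TestCase(
            name=case_name,
            tags=suite_tags | case_tags,
            when_params=when,
            then_assertions=assertions,
            snapshot_keys=snap_keys,
            snapshot_exprs=snap_exprs,
        ))

    return TestSuite(
        suite_path=suite_key,
        subject=subject,
        cases=cases,
        declared_assets=assets,
        dialect="native",
        tags=suite_tags,
    )


def serialize_native_suite(suite: TestSuite) -> str:
    """Render a suite back to native YAML; parse→serialize→parse is the
    identity on the structural fields."""
    doc: dict[str, Any] = {
        "suite": {
            "name": suite.subject.name,
            "subject": {
                "kind": suite.subject.kind.value,
                # script is stored project-relative; re-express it relative
                # to the suite file for the round trip
                "script": posixpath.relpath(
                    suite.subject.script_path,
                    posixpath.dirname(suite.suite_path) or "."),
                "entry": suite.subject.entry_name,
            },
            "tags": sorted(suite.tags),
        },
    }
    if suite.declared_assets:
        doc["suite"]["assets"] = list(suite.declared_assets)
    tests = []
    for case in suite.cases:
        entry: dict[str, Any] = {"name": case.name}
        extra_tags = sorted(case.tags - suite.tags)
        if extra_tags:
            entry["tags"] = extra_tags
        if case.when_params:
            entry["when"] = case.when_params
        if case.then_assertions:
            entry["then"] = [a.source for a in case.then_assertions]
        if case.snapshot_exprs:
            entry["snapshot"] = [a.source for a in case.snapshot_exprs]
        tests.append(entry)
    doc["tests"] = tests
    return yaml.safe_dump(doc, sort_keys=False)


def _strip_lines(value: Any) -> Any:
    if isinstance(value, dict):
        return {k: _strip_lines(v) for k, v in value.items()
                if k != "__line__"}
    if isinstance(value, list):
        return [_strip_lines(v) for v in value]
    return value
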
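"""Structural parser for nf-test-style ``.nf.test`` suites.

These suites embed executable host-language code in their ``then`` blocks,
which this framework never evaluates.  Compat parsing extracts only the
structure needed for discovery, selection and coverage: the block kind,
subject script, entry name, test names, and tags.  Then-bodies are kept as
opaque text.
"""

from __future__ import annotations

import logging
import posixpath
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from pipetest.lexing import GToken, groovy_tokens
from pipetest.model import (
    SpecError, TestCase, TestSubject, TestSuite, UnitKind, norm_rel,
)

logger = logging.getLogger("pipetest.compat")

BLOCK_KINDS = {
    "nextflow_process": UnitKind.PROCESS,
    "nextflow_workflow": UnitKind.WORKFLOW,
    "nextflow_pipeline": UnitKind.PIPELINE,
    "nextflow_function": UnitKind.FUNCTION,
}

# directive whose string argument names the entry unit, per block kind
_ENTRY_DIRECTIVE = {
    "nextflow_process": "process",
    "nextflow_workflow": "workflow",
    "nextflow_function": "function",
}


@dataclass
class CompatSuiteSketch:
    """Structural extraction of one compat suite file."""

    block_kind: str
    name: str
    script_ref: str
    entry_name: str
    test_names: list[str] = field(default_factory=list)
    tags: set[str] = field(default_factory=set)
    case_tags: dict[str, set[str]] = field(default_factory=dict)
    opaque_then_bodies: list[str] = field(default_factory=list)


def sketch_compat_suite(path: str | Path) -> Optional[CompatSuiteSketch]:
    """Extract the structure of a compat suite, or None if the file's
    top-level keyword is unrecognized (skipped with a warning)."""
    path = Path(path)
    text = path.read_text()
    tokens = groovy_tokens(text, str(path))

    idx = 0
    while idx < len(tokens) and tokens[idx].kind != "word":
        idx += 1
    if idx >= len(tokens):
        logger.warning("%s: no top-level block, skipping", path)
        return None
    head = tokens[idx]
    if head.value not in BLOCK_KINDS:
        logger.warning("%s: unknown top-level keyword %r, skipping",
                       path, head.value)
        return None
    idx += 1
    if idx >= len(tokens) or tokens[idx].kind != "lbrace":
        raise SpecError(f"expected '{{' after {head.value}",
                        str(path), head.line)

    close = _match_brace(tokens, idx, str(path))
    sketch = CompatSuiteSketch(
        block_kind=head.value, name="", script_ref="", entry_name="")
    entry_directive = _ENTRY_DIRECTIVE.get(head.value)

    i = idx + 1
    while i < close:
        tok = tokens[i]
        if tok.kind != "word":
            i += 1
            continue
        word = tok.value
        nxt = tokens[i + 1] if i + 1 < close else None
        if word == "test" and nxt is not None and nxt.kind == "lparen":
            i = _scan_test(tokens, i, close, str(path), text, sketch)
            continue
        if nxt is not None and nxt.kind == "string":
            if word == "name":
                sketch.name = nxt.value
            elif word == "script":
                sketch.script_ref = nxt.value
            elif word == entry_directive:
                sketch.entry_name = nxt.value
            elif word == "tag":
                sketch.tags.add(nxt.value)
            i += 2
            continue
        if nxt is not None and nxt.kind == "lbrace":
            # unrelated nested block (setup, options...) — skip wholesale
            i = _match_brace(tokens, i + 1, str(path)) + 1
            continue
        i += 1

    if not sketch.test_names:
        raise SpecError("compat suite declares no test(...) blocks",
                        str(path), head.line)
    return sketch


def _match_brace(tokens: list[GToken], open_idx: int, path: str) -> int:
    """Index of the rbrace matching the lbrace at open_idx."""
    depth = 0
    for j in range(open_idx, len(tokens)):
        if tokens[j].kind == "lbrace":
            depth += 1
        elif tokens[j].kind == "rbrace":
            depth -= 1
            if depth == 0:
                return j
    raise SpecError("unbalanced braces", path, tokens[open_idx].line)


def _scan_test(tokens: list[GToken], i: int, limit: int, path: str,
               text: str, sketch: CompatSuiteSketch) -> int:
    """Parse `test("name") { ... }` starting at the `test` word; returns the
    index just past the closing brace."""
    line = tokens[i].line
    j = i + 2  # past 'test' '('
    if j >= limit or tokens[j].kind != "string":
        raise SpecError("test(...) requires a quoted name", path, line)
    name = tokens[j].value
    j += 1
    if j >= limit or tokens[j].kind != "rparen":
        raise SpecError("expected ')' after test name", path, line)
    j += 1
    if j >= limit or tokens[j].kind != "lbrace":
        raise SpecError("expected '{' after test(...)", path, line)
    close = _match_brace(tokens, j, path)

    tags: set[str] = set()
    body_start = tokens[j].pos + 1
    body_end = tokens[close].pos
    k = j + 1
    then_body = ""
    while k < close:
        tok = tokens[k]
        nxt = tokens[k + 1] if k + 1 < close else None
        if tok.kind == "word" and tok.value == "tag" and \
                nxt is not None and nxt.kind == "string":
            tags.add(nxt.value)
            k += 2
            continue
        if tok.kind == "word" and tok.value == "then" and \
                nxt is not None and nxt.kind == "lbrace":
            then_close = _match_brace(tokens, k + 1, path)
            then_body = text[tokens[k + 1].pos + 1:tokens[then_close].pos]
            k = then_close + 1
            continue
        if nxt is not None and tok.kind == "word" and nxt.kind == "lbrace":
            k = _match_brace(tokens, k + 1, path) + 1
            continue
        k += 1

    sketch.test_names.append(name)
    sketch.case_tags[name] = tags
    sketch.opaque_then_bodies.append(
        then_body if then_body else text[body_start:body_end])
    return close + 1


def parse_compat_suite(path: str | Path,
                       project_root: Optional[str | Path] = None
                       ) -> Optional[TestSuite]:
    """Parse a compat suite into a :class:`TestSuite` (dialect="compat").

    Cases carry no executable assertions; they are discoverable and
    selectable but require an engine backend to run.
    """
    path = Path(path)
    sketch = sketch_compat_suite(path)
    if sketch is None:
        return None

    if project_root is not None:
        try:
            suite_key = norm_rel(
                path.resolve().relative_to(Path(project_root).resolve()))
        except ValueError:
            suite_key = norm_rel(path)
    else:
        suite_key = norm_rel(path)

    suite_dir = posixpath.dirname(suite_key)
    script = posixpath.normpath(posixpath.join(suite_dir, sketch.script_ref)) \
        if sketch.script_ref else ""

    kind = BLOCK_KINDS[sketch.block_kind]
    subject = TestSubject(
        kind=kind,
        name=sketch.name or path.stem,
        script_path=script,
        entry_name=sketch.entry_name,
    )
    suite_tags = frozenset(sketch.tags)
    cases: list[TestCase] = []
    seen: dict[str, int] = {}
    for case_name in sketch.test_names:
        n = seen.get(case_name, 0)
        seen[case_name] = n + 1
        unique = case_name if n == 0 else f"{case_name} ({n + 1})"
        cases.append(TestCase(
            name=unique,
            tags=suite_tags | frozenset(sketch.case_tags.get(case_name, ())),
        ))

    # optional sidecar listing test assets, one project-relative path per line
    assets: list[str] = []
    sidecar = path.with_name(path.name + ".assets")
    if sidecar.is_file():
        assets = [norm_rel(ln.strip()) for ln in sidecar.read_text().splitlines()
                  if ln.strip() and not ln.lstrip().startswith("#")]

    return TestSuite(
        suite_path=suite_key,
        subject=subject,
        cases=cases,
        declared_assets=assets,
        dialect="compat",
        tags=suite_tags,
    )
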
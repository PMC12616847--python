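"""Deterministic test-suite discovery over a project tree."""

from __future__ import annotations

import copy
import logging
from pathlib import Path
from typing import Iterable, Optional

from pipetest.compat import parse_compat_suite
from pipetest.model import (
    DEFAULT_PATTERNS, ProjectConfig, SpecError, TestSuite, norm_rel,
)
from pipetest.native import parse_native_suite

logger = logging.getLogger("pipetest.discovery")


def suite_sort_key(suite: TestSuite) -> tuple:
    return (suite.subject.kind.order, suite.suite_path)


def discover_suites(project_root: str | Path,
                    patterns: Optional[Iterable[str]] = None,
                    tag_filter: Optional[set[str]] = None,
                    config: Optional[ProjectConfig] = None) -> list[TestSuite]:
    """Find, parse and order every test suite under ``project_root``.

    Suites are returned sorted by (unit kind, project-relative path) so two
    runs over the same tree — on any platform, whatever the filesystem
    enumeration order — produce identical lists.  ``tag_filter`` keeps
    only cases carrying at least one of the given tags; suites left with
    no cases are dropped.
    """
    root = Path(project_root)
    if not root.is_dir():
        raise SpecError(f"project root {root} does not exist")
    if config is None:
        config = ProjectConfig.load(root)
    if patterns is None:
        patterns = config.patterns or DEFAULT_PATTERNS
    patterns = list(patterns)
    if not patterns:
        raise SpecError("no discovery patterns given")

    paths: set[Path] = set()
    for pattern in patterns:
        paths.update(p for p in root.glob(pattern) if p.is_file())

    suites: list[TestSuite] = []
    for path in sorted(paths):
        if path.suffix in (".yaml", ".yml"):
            suites.append(parse_native_suite(path, project_root=root))
        else:
            suite = parse_compat_suite(path, project_root=root)
            if suite is not None:
                suites.append(suite)

    by_name: dict[str, str] = {}
    for suite in suites:
        prev = by_name.get(suite.subject.name)
        if prev is not None:
            logger.warning(
                "duplicate suite name %r in %s and %s; suites are "
                "disambiguated by path", suite.subject.name, prev,
                suite.suite_path)
        by_name[suite.subject.name] = suite.suite_path

    if tag_filter:
        wanted = set(tag_filter)
        filtered: list[TestSuite] = []
        for suite in suites:
            kept = [c for c in suite.cases if c.tags & wanted]
            if kept:
                clone = copy.copy(suite)
                clone.cases = kept
                filtered.append(clone)
        suites = filtered

    suites.sort(key=suite_sort_key)
    return suites


def find_suite(suites: list[TestSuite], suite_path: str) -> TestSuite:
    suite_path = norm_rel(suite_path)
    for suite in suites:
        if suite.suite_path == suite_path:
            return suite
    raise KeyError(suite_path)
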
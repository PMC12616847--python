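"""Firewall regression-test selection and coverage status.

When a component changes, the minimal set of suites that must be rerun is
bounded by the nearest *tested* ancestors in the dependency graph: the
changed component's own suites are always selected, and each dependent is
climbed until a node with direct suites is found (that suite then
indirectly validates everything below it on the path).  A climb path that
ends at a node with neither suites nor dependents is reported as an
unverified path — a gap in the firewall.

Trigger files (container recipes etc.) force a full retest.  Changed suite
files, snapshot stores and declared assets reselect their own suites.
"""

from __future__ import annotations

import logging
import posixpath
from dataclasses import dataclass, field
from typing import Iterable

from pipetest.graph import DepGraph, dependents
from pipetest.model import norm_rel

logger = logging.getLogger("pipetest.selection")


@dataclass
class SelectionResult:
    selected: list[str] = field(default_factory=list)
    reasons: dict[str, str] = field(default_factory=dict)
    unverified_paths: list[str] = field(default_factory=list)
    full_retest: bool = False
    visited_components: set[str] = field(default_factory=set)


@dataclass
class StatusReport:
    per_component: dict[str, dict] = field(default_factory=dict)
    coverage_pct: float = 100.0


def _suite_key(graph: DepGraph, suite_path: str) -> tuple:
    suite = graph.suites.get(suite_path)
    order = suite.subject.kind.order if suite else 99
    return (order, suite_path)


def select_firewall(graph: DepGraph,
                    changed_files: Iterable[str]) -> SelectionResult:
    """Compute the firewall for a change set.

    Returns the suites to rerun, ordered by (unit kind, path), with a
    human-readable reason per suite, plus the unverified climb terminals.
    """
    changed = sorted({norm_rel(f) for f in changed_files})
    result = SelectionResult()

    trigger = next((f for f in changed if graph.is_trigger(f)), None)
    if trigger is not None:
        result.full_retest = True
        result.selected = sorted(graph.suites, key=lambda s: _suite_key(graph, s))
        for s in result.selected:
            result.reasons[s] = f"full retest: trigger file {trigger} changed"
        result.visited_components = set(graph.components())
        return result

    picked: dict[str, str] = {}  # suite path -> reason (first wins)
    climbed: set[str] = set()
    unverified: set[str] = set()

    def pick(suite_path: str, reason: str) -> None:
        picked.setdefault(suite_path, reason)

    def climb(x: str, origin: str) -> None:
        if x in climbed:
            return
        climbed.add(x)
        own = graph.direct_suites(x)
        if own:
            for s in own:
                pick(s, f"indirectly validates {origin} (nearest tested "
                        f"ancestor {x})")
            return
        deps = dependents(graph, x)
        if not deps:
            unverified.add(x)
            return
        for d in sorted(deps):
            climb(d, origin)

    for f in changed:
        node = graph.nodes.get(f)
        if node is None:
            if _select_test_dir_helpers(graph, f, pick):
                continue
            logger.warning("changed file %s is not a graph node; ignored", f)
            continue
        if node.kind == "suite":
            pick(f, "suite file changed")
        elif node.kind == "snapshot":
            for (u, v) in graph.uses_edges:
                if v == f and graph.nodes[u].kind == "suite":
                    pick(u, f"snapshot {f} changed")
        elif node.kind == "asset":
            for (u, v) in graph.uses_edges:
                if v == f and graph.nodes[u].kind == "suite":
                    pick(u, f"declared asset {f} changed")
        elif node.kind == "component":
            climbed.add(f)
            for s in graph.direct_suites(f):
                pick(s, f"direct suite of changed component {f}")
            deps = dependents(graph, f)
            if not deps and not graph.direct_suites(f):
                unverified.add(f)
            for d in sorted(deps):
                climb(d, f)

    result.selected = sorted(picked, key=lambda s: _suite_key(graph, s))
    result.reasons = {s: picked[s] for s in result.selected}
    result.unverified_paths = sorted(unverified)
    result.visited_components = {
        c for c in climbed if graph.nodes.get(c) is not None
        and graph.nodes[c].kind == "component"}
    return result


def _select_test_dir_helpers(graph: DepGraph, path: str, pick) -> bool:
    """A changed helper file inside the tests directory selects the suites
    that live next to it (fixtures shared by those suites)."""
    tests_dir = norm_rel(graph.config.tests_dir)
    if not (path == tests_dir or path.startswith(tests_dir + "/")):
        return False
    parent = posixpath.dirname(path)
    hit = False
    for spath in graph.suites:
        if posixpath.dirname(spath) == parent:
            pick(spath, f"helper file {path} in suite directory changed")
            hit = True
    return hit


def coverage_status(graph: DepGraph, strict: bool = False) -> StatusReport:
    """Per-component testing status.

    A component is *covered* when changing it would select at least one
    suite — it is directly or indirectly verified by at least one test
    case.  In strict mode every climb path must reach a suite (no
    unverified terminals tolerated).
    """
    report = StatusReport()
    components = graph.components()
    covered_n = 0
    for c in components:
        sel = select_firewall(graph, {c})
        covered = bool(sel.selected)
        if strict and sel.unverified_paths:
            covered = False
        report.per_component[c] = {
            "direct_suites": len(graph.direct_suites(c)),
            "covered": covered,
        }
        covered_n += covered
    report.coverage_pct = (100.0 * covered_n / len(components)
                           if components else 100.0)
    return report


def firewall_status(graph: DepGraph, changed_files: Iterable[str],
                    strict: bool = False) -> StatusReport:
    """Testing status restricted to the components a change set touches."""
    sel = select_firewall(graph, changed_files)
    full = coverage_status(graph, strict=strict)
    report = StatusReport()
    scope = sorted(sel.visited_components)
    covered_n = 0
    for c in scope:
        entry = full.per_component[c]
        report.per_component[c] = entry
        covered_n += entry["covered"]
    report.coverage_pct = (100.0 * covered_n / len(scope)
                           if scope else 100.0)
    return report
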
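"""Project dependency graph over components, suites, snapshots and assets.

Nodes are project-relative paths.  A *component* is a workflow source file
(process, workflow or pipeline script); edges point from user to used
("W1 includes M1" gives edge W1 → M1).  Suites link to the subject they
validate, to their snapshot store, and to any declared test assets, so a
change to any of those reselects the suite.  Configured *trigger* files
(e.g. a container recipe) become their own nodes; a change to one forces
a full retest.

The graph is built purely by static parsing — no code from the project is
ever executed.
"""

from __future__ import annotations

import fnmatch
import logging
import posixpath
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import networkx as nx

from pipetest.discovery import discover_suites
from pipetest.lexing import groovy_tokens
from pipetest.model import ProjectConfig, TestSuite, UnitKind, norm_rel

logger = logging.getLogger("pipetest.graph")

NODE_KINDS = ("component", "suite", "snapshot", "asset", "trigger")


@dataclass(frozen=True)
class Node:
    kind: str  # one of NODE_KINDS
    unit_kind: Optional[UnitKind] = None


@dataclass(frozen=True)
class Include:
    """One include statement: resolved project path or the raw reference."""
    target: str
    resolved: bool
    names: tuple[str, ...] = ()


@dataclass
class ParseStats:
    files_parsed: int = 0
    unresolved_includes: list[tuple[str, str]] = field(default_factory=list)


@dataclass
class DepGraph:
    root: Path
    config: ProjectConfig
    nodes: dict[str, Node] = field(default_factory=dict)
    uses_edges: set[tuple[str, str]] = field(default_factory=set)
    suite_of: dict[str, str] = field(default_factory=dict)
    suites: dict[str, TestSuite] = field(default_factory=dict)
    cycle_flag: bool = False
    parse_stats: ParseStats = field(default_factory=ParseStats)

    def components(self) -> list[str]:
        return sorted(p for p, n in self.nodes.items() if n.kind == "component")

    def suite_paths(self) -> list[str]:
        return sorted(self.suite_of)

    def direct_suites(self, component_path: str) -> list[str]:
        """Suites whose subject is the given component, in path order."""
        return sorted(s for s, subj in self.suite_of.items()
                      if subj == component_path)

    def is_trigger(self, path: str) -> bool:
        node = self.nodes.get(path)
        if node is not None and node.kind == "trigger":
            return True
        return any(fnmatch.fnmatch(path, pat) for pat in self.config.triggers)


def parse_includes(source_text: str, source_path: str | Path) -> list[Include]:
    """Extract ``include { A; B as C } from '<p>'`` statements.

    Each reference is resolved relative to the including file by trying
    ``<p>``, ``<p>.nf``, ``<p>/main.nf`` in that order; unresolved
    references are returned tagged so callers can record them without
    failing.  Includes inside comments or strings are ignored by the lexer.
    """
    source_path = Path(source_path)
    tokens = groovy_tokens(source_text, str(source_path))
    out: list[Include] = []
    i = 0
    while i < len(tokens):
        tok = tokens[i]
        if tok.kind == "word" and tok.value == "include" and \
                i + 1 < len(tokens) and tokens[i + 1].kind == "lbrace":
            depth, j = 0, i + 1
            names: list[str] = []
            while j < len(tokens):
                if tokens[j].kind == "lbrace":
                    depth += 1
                elif tokens[j].kind == "rbrace":
                    depth -= 1
                    if depth == 0:
                        break
                elif tokens[j].kind == "word" and tokens[j].value != "as":
                    names.append(tokens[j].value)
                j += 1
            if j + 2 < len(tokens) and tokens[j + 1].kind == "word" and \
                    tokens[j + 1].value == "from" and \
                    tokens[j + 2].kind == "string":
                ref = tokens[j + 2].value
                resolved = _resolve_include(source_path, ref)
                if resolved is not None:
                    out.append(Include(norm_rel(resolved), True, tuple(names)))
                else:
                    out.append(Include(ref, False, tuple(names)))
                i = j + 3
                continue
            i = j + 1
            continue
        i += 1
    return out


def _resolve_include(source_path: Path, ref: str) -> Optional[Path]:
    base = source_path.parent
    for candidate in (ref, ref + ".nf", posixpath.join(ref, "main.nf")):
        p = (base / candidate)
        if p.is_file():
            return p.resolve() if p.is_absolute() else Path(
                posixpath.normpath(p.as_posix()))
    return None


def build_graph(project_root: str | Path,
                config: Optional[ProjectConfig] = None) -> DepGraph:
    """Statically parse the whole project into a :class:`DepGraph`."""
    root = Path(project_root).resolve()
    if config is None:
        config = ProjectConfig.load(root)
    graph = DepGraph(root=root, config=config)
    parsed_files: set[str] = set()

    def rel(p: Path) -> str:
        return norm_rel(p.resolve().relative_to(root))

    # --- components: every workflow source file under the root
    sources = sorted(root.glob("**/*.nf"))
    for src in sources:
        key = rel(src)
        graph.nodes[key] = Node("component", _infer_unit_kind(src))
        parsed_files.add(key)

    for src in sources:
        key = rel(src)
        for inc in parse_includes(src.read_text(), src):
            if inc.resolved:
                target_abs = root / _rebase(src, inc.target, root)
                target = norm_rel(target_abs.resolve().relative_to(root)) \
                    if target_abs.resolve().is_relative_to(root) \
                    else inc.target
                if target not in graph.nodes:
                    graph.nodes[target] = Node("component", None)
                    parsed_files.add(target)
                graph.uses_edges.add((key, target))
            else:
                graph.parse_stats.unresolved_includes.append((key, inc.target))
                logger.warning("%s: unresolved include %r", key, inc.target)

    # --- suites and everything hanging off them
    suites = discover_suites(root, config=config)
    for suite in suites:
        spath = suite.suite_path
        graph.nodes[spath] = Node("suite", suite.subject.kind)
        graph.suites[spath] = suite
        parsed_files.add(spath)

        subject = suite.subject.script_path
        if subject:
            if subject not in graph.nodes:
                graph.nodes[subject] = Node("component", suite.subject.kind)
            elif graph.nodes[subject].unit_kind is None:
                graph.nodes[subject] = Node("component", suite.subject.kind)
            graph.suite_of[spath] = subject
            graph.uses_edges.add((spath, subject))

        snap = spath + config.snapshot_suffix
        if (root / snap).is_file():
            graph.nodes[snap] = Node("snapshot", None)
            graph.uses_edges.add((spath, snap))
            parsed_files.add(snap)

        for asset in suite.declared_assets:
            akey = asset if (root / asset).exists() else norm_rel(
                posixpath.normpath(
                    posixpath.join(posixpath.dirname(spath), asset)))
            if akey not in graph.nodes:
                graph.nodes[akey] = Node("asset", None)
            graph.uses_edges.add((spath, akey))

    # subjects discovered via suites may carry kinds that plain file scans
    # could not infer; refresh kinds for suite subjects handled above

    # --- triggers
    for pattern in config.triggers:
        for p in sorted(root.glob(pattern)):
            if p.is_file():
                key = rel(p)
                graph.nodes[key] = Node("trigger", None)

    # --- cycle detection over component nodes only
    comp = nx.DiGraph()
    comp.add_nodes_from(graph.components())
    comp.add_edges_from(
        (u, v) for u, v in graph.uses_edges
        if graph.nodes.get(u, Node("x")).kind == "component"
        and graph.nodes.get(v, Node("x")).kind == "component")
    graph.cycle_flag = not nx.is_directed_acyclic_graph(comp)
    if graph.cycle_flag:
        logger.warning("dependency cycle detected among components")

    graph.parse_stats.files_parsed = len(parsed_files)
    return graph


def _rebase(source: Path, target: str, root: Path) -> str:
    # parse_includes resolves against the filesystem and returns a path that
    # may already be root-relative or absolute-ish; normalize defensively
    p = Path(target)
    if p.is_absolute():
        try:
            return norm_rel(p.relative_to(root))
        except ValueError:
            return norm_rel(p)
    return norm_rel(p)


def _infer_unit_kind(src: Path) -> Optional[UnitKind]:
    """Best-effort kind from the file's own top-level declarations."""
    try:
        tokens = groovy_tokens(src.read_text(), str(src))
    except Exception:
        return None
    words = [t.value for t in tokens if t.kind == "word"]
    has_process = "process" in words
    has_workflow = "workflow" in words
    if has_workflow:
        return UnitKind.WORKFLOW
    if has_process:
        return UnitKind.PROCESS
    return None


def dependents(graph: DepGraph, node_path: str) -> set[str]:
    """Component nodes that directly use ``node_path``."""
    node_path = norm_rel(node_path)
    if node_path not in graph.nodes:
        raise KeyError(f"unknown graph node {node_path!r}")
    return {u for (u, v) in graph.uses_edges
            if v == node_path and graph.nodes[u].kind == "component"}


def to_dot(graph: DepGraph) -> str:
    """Render the graph in DOT form (components as boxes, suites in blue)."""
    shapes = {"component": "box", "suite": "box", "snapshot": "note",
              "asset": "folder", "trigger": "octagon"}
    colors = {"suite": "lightblue", "trigger": "salmon"}
    lines = ["digraph deps {", "  rankdir=BT;"]
    for path in sorted(graph.nodes):
        node = graph.nodes[path]
        attrs = [f'shape={shapes[node.kind]}']
        if node.kind in colors:
            attrs.append(f'style=filled fillcolor={colors[node.kind]}')
        lines.append(f'  "{path}" [{" ".join(attrs)}];')
    for u, v in sorted(graph.uses_edges):
        lines.append(f'  "{u}" -> "{v}";')
    lines.append("}")
    return "\n".join(lines) + "\n"


def to_json_dict(graph: DepGraph) -> dict:
    return {
        "nodes": {p: {"kind": n.kind,
                      "unit_kind": n.unit_kind.value if n.unit_kind else None}
                  for p, n in sorted(graph.nodes.items())},
        "edges": sorted([u, v] for u, v in graph.uses_edges),
        "suite_of": dict(sorted(graph.suite_of.items())),
        "cycle": graph.cycle_flag,
        "parse_stats": {
            "files_parsed": graph.parse_stats.files_parsed,
            "unresolved_includes":
                [list(t) for t in graph.parse_stats.unresolved_includes],
        },
    }
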
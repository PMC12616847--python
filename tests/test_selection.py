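"""Firewall selection: worked examples, oracle equivalence, coverage."""

import itertools

import pytest

from pipetest import (
    build_graph, coverage_status, firewall_status, select_firewall,
)
from pipetest.fixtures import fig3_project, generate_project, random_topology
from tests.conftest import M1, M2, M3, P1, SUITE, W1, W2


# --------------------------------------------------- independent oracle

def oracle_select(graph, changed):
    """Brute-force recursive restatement of the firewall definition,
    written directly from first principles and independent of the
    production implementation (no memoization, explicit path recursion)."""
    suites = set()
    unverified = set()

    def direct(c):
        return {s for s, subj in graph.suite_of.items() if subj == c}

    def deps(c):
        return {u for (u, v) in graph.uses_edges
                if v == c and graph.nodes[u].kind == "component"}

    def climb(x, seen):
        if x in seen:
            return
        seen = seen | {x}
        own = direct(x)
        if own:
            suites.update(own)
            return
        d = deps(x)
        if not d:
            unverified.add(x)
            return
        for u in d:
            climb(u, seen)

    if any(graph.is_trigger(f) for f in changed):
        return set(graph.suites), set(), True
    for f in sorted(changed):
        node = graph.nodes.get(f)
        if node is None:
            continue
        if node.kind == "suite":
            suites.add(f)
        elif node.kind in ("snapshot", "asset"):
            suites.update(u for (u, v) in graph.uses_edges
                          if v == f and graph.nodes[u].kind == "suite")
        elif node.kind == "component":
            suites.update(direct(f))
            if not deps(f) and not direct(f):
                unverified.add(f)
            for d in deps(f):
                climb(d, {f})
    return suites, unverified, False


def all_upward_paths(graph, start):
    """Every maximal upward path from a component (for the safety check)."""
    def deps(c):
        return sorted(u for (u, v) in graph.uses_edges
                      if v == c and graph.nodes[u].kind == "component")

    paths = []

    def walk(node, path):
        ds = [d for d in deps(node) if d not in path]
        if not ds:
            paths.append(path)
            return
        for d in ds:
            walk(d, path + [d])

    walk(start, [start])
    return paths


# ------------------------------------------------------ worked example

def test_firewall_m1_climbs_past_untested_w1(fig3_graph):
    sel = select_firewall(fig3_graph, {M1})
    assert sel.selected == [SUITE["M1"], SUITE["P1"]]
    assert not sel.full_retest
    assert sel.unverified_paths == []


def test_firewall_m3_stops_at_tested_w2(fig3_graph):
    sel = select_firewall(fig3_graph, {M3})
    assert sel.selected == [SUITE["M3"], SUITE["W2"]]
    assert SUITE["P1"] not in sel.selected


def test_firewall_changed_workflow_selects_pipeline_suite(fig3_graph):
    sel = select_firewall(fig3_graph, {W1})
    assert sel.selected == [SUITE["P1"]]


def test_trigger_forces_full_retest(fig3_graph):
    sel = select_firewall(fig3_graph, {"Dockerfile"})
    assert sel.full_retest
    assert sel.selected == sorted(
        SUITE.values(),
        key=lambda s: (fig3_graph.suites[s].subject.kind.order, s))
    assert len(sel.selected) == 5


def test_changed_suite_and_snapshot_select_their_suite(tmp_path):
    fig3_project(tmp_path)
    snap = tmp_path / (SUITE["M2"] + ".snap")
    snap.write_text('{"meta": {}}\n')
    g = build_graph(tmp_path)
    assert select_firewall(g, {SUITE["M1"]}).selected == [SUITE["M1"]]
    assert select_firewall(g, {SUITE["M2"] + ".snap"}).selected == \
        [SUITE["M2"]]


def test_unknown_changed_file_ignored(fig3_graph):
    sel = select_firewall(fig3_graph, {"README.md"})
    assert sel.selected == [] and not sel.full_retest


def test_helper_file_in_tests_dir_selects_neighbour_suites(fig3_graph):
    sel = select_firewall(fig3_graph, {"tests/helper_fixture.txt"})
    assert sel.selected == sorted(
        SUITE.values(),
        key=lambda s: (fig3_graph.suites[s].subject.kind.order, s))


# ----------------------------------------------------------- coverage

def test_fig3_full_coverage(fig3_graph):
    report = coverage_status(fig3_graph)
    assert report.coverage_pct == 100.0
    assert all(e["covered"] for e in report.per_component.values())


def test_coverage_drops_when_pipeline_suite_removed(tmp_path):
    fig3_project(tmp_path)
    (tmp_path / SUITE["P1"]).unlink()
    g = build_graph(tmp_path)
    report = coverage_status(g)
    assert not report.per_component[W1]["covered"]
    assert not report.per_component[P1]["covered"]
    assert report.coverage_pct == pytest.approx(100 * 4 / 6, abs=0.1)


def test_empty_project_coverage_is_100(tmp_path):
    report = coverage_status(build_graph(tmp_path))
    assert report.coverage_pct == 100.0


def test_firewall_status(fig3_graph, tmp_path):
    report = firewall_status(fig3_graph, {M1})
    assert set(report.per_component) == {M1, W1, P1}
    assert report.coverage_pct == 100.0
    assert firewall_status(fig3_graph, set()).coverage_pct == 100.0

    fig3_project(tmp_path)
    (tmp_path / SUITE["P1"]).unlink()
    g = build_graph(tmp_path)
    degraded = firewall_status(g, {M1})
    assert degraded.coverage_pct == pytest.approx(100 / 3, abs=0.1)


# --------------------------------------------- oracle equivalence sweep

def _graphs_for_seeds(tmp_path_factory, seeds):
    root = tmp_path_factory.mktemp("rand")
    for seed in seeds:
        spec = random_topology(seed)
        proj = root / f"p{seed}"
        generate_project(spec, proj)
        yield seed, spec, build_graph(proj)


N_ORACLE_INSTANCES = 120  # projects; each is probed with several change sets


def test_oracle_equivalence_on_random_dags(tmp_path_factory):
    """On random layered DAGs with random test placement, the production
    firewall equals the brute-force recursive definition; union, subset,
    determinism and safety hold on every instance."""
    checked = 0
    for seed, spec, g in _graphs_for_seeds(
            tmp_path_factory, range(N_ORACLE_INSTANCES)):
        components = g.components()
        singles = [{c} for c in components]
        pairs = [set(p) for p in itertools.combinations(components, 2)][:6]
        for changed in singles + pairs:
            sel = select_firewall(g, changed)
            want_suites, want_unverified, want_full = oracle_select(g, changed)
            assert set(sel.selected) == want_suites, \
                f"seed {seed}, changed {changed}"
            assert set(sel.unverified_paths) == want_unverified
            assert sel.full_retest == want_full
            # subset property
            assert set(sel.selected) <= set(g.suites)
            # determinism: byte-identical ordered output
            again = select_firewall(g, set(changed))
            assert again.selected == sel.selected
            assert again.unverified_paths == sel.unverified_paths
            checked += 1

        # union property over component singletons
        for a, b in itertools.combinations(components[:4], 2):
            u = select_firewall(g, {a, b})
            sa = select_firewall(g, {a})
            sb = select_firewall(g, {b})
            assert set(u.selected) == set(sa.selected) | set(sb.selected)

        # safety: every maximal upward path carries a selected suite or
        # terminates in unverified_paths
        for c in components:
            sel = select_firewall(g, {c})
            if sel.full_retest:
                continue
            for path in all_upward_paths(g, c):
                on_path = {s for node in path for s in g.direct_suites(node)}
                assert (on_path & set(sel.selected)) or \
                    (path[-1] in set(sel.unverified_paths)), \
                    f"seed {seed}, gap on path {path}"
    assert checked >= 500
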
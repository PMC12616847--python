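"""Planning, sharding, channel canonicalization, assertion evaluation,
and the runner."""

import functools
import random

import pytest
from hypothesis import given, settings, strategies as st

from pipetest import discover_suites, order_tests, run_plan, shard, sort_channel
from pipetest.channels import FileRef, canonical_key
from pipetest.execution import (
    AssertionOutcome, CommandBackend, ReplayBackend, RunOptions, ShardSpec,
    TestPlan, evaluate_then,
)
from pipetest.model import TestCase
from pipetest.exprs import AssertionExpr
from pipetest.execution import UnitOutputs, ChannelMap


# ------------------------------------------------------------ planning

def test_plan_order_kind_then_path(fig3_suites):
    plan = order_tests(fig3_suites)
    assert [e[0] for e in plan.entries] == [
        "tests/m1.test.yaml", "tests/m2.test.yaml", "tests/m3.test.yaml",
        "tests/w2.test.yaml", "tests/p1.test.yaml"]


def test_plan_invariant_to_input_permutation(fig3_suites):
    rng = random.Random(7)
    base = order_tests(fig3_suites)
    for _ in range(5):
        shuffled = list(fig3_suites)
        rng.shuffle(shuffled)
        assert order_tests(shuffled).entries == base.entries


# ------------------------------------------------------------- sharding

def _plan(n):
    plan = TestPlan()
    plan.entries = [(f"s{i:03d}", "c") for i in range(n)]
    return plan


def test_chunk_example_five_over_two():
    plan = TestPlan(entries=[("a", "c"), ("b", "c"), ("c", "c"),
                             ("d", "c"), ("e", "c")])
    assert shard(plan, ShardSpec(1, 2)).entries == \
        [("a", "c"), ("b", "c"), ("c", "c")]
    assert shard(plan, ShardSpec(2, 2)).entries == [("d", "c"), ("e", "c")]


def test_round_robin_example_five_over_two():
    plan = TestPlan(entries=[("a", "c"), ("b", "c"), ("c", "c"),
                             ("d", "c"), ("e", "c")])
    assert shard(plan, ShardSpec(1, 2, "round_robin")).entries == \
        [("a", "c"), ("c", "c"), ("e", "c")]
    assert shard(plan, ShardSpec(2, 2, "round_robin")).entries == \
        [("b", "c"), ("d", "c")]


def test_forty_nine_tests_over_five_round_robin_shards():
    sizes = [len(shard(_plan(49), ShardSpec(i, 5, "round_robin")))
             for i in range(1, 6)]
    assert sizes == [10, 10, 10, 10, 9]


@pytest.mark.parametrize("strategy", ["chunk", "round_robin"])
@pytest.mark.parametrize("n", [1, 2, 3, 5, 10])
def test_shards_partition_the_plan(strategy, n):
    for size in (0, 1, 7, 49, 200):
        plan = _plan(size)
        shards = [shard(plan, ShardSpec(i, n, strategy)).entries
                  for i in range(1, n + 1)]
        flat = [e for s in shards for e in s]
        assert sorted(flat) == sorted(plan.entries)  # disjoint union
        assert len(flat) == len(set(flat))
        sizes = [len(s) for s in shards]
        assert max(sizes) - min(sizes) <= 1  # both strategies balance


def test_invalid_shard_spec():
    with pytest.raises(ValueError):
        ShardSpec(3, 2)
    with pytest.raises(ValueError):
        ShardSpec.parse("nonsense")
    assert ShardSpec.parse("2/3").index == 2


# --------------------------------------------------- channel sorting

def _oracle_cmp(a, b):
    """Pairwise comparator written directly from the frozen rank table,
    used with a comparison sort as the independent ordering oracle."""
    def rank(v):
        if v is None:
            return 0
        if isinstance(v, bool):
            return 1
        if isinstance(v, (int, float)):
            return 2
        if isinstance(v, str):
            return 3
        if isinstance(v, FileRef):
            return 4
        if isinstance(v, (list, tuple)):
            return 5
        return 6

    ra, rb = rank(a), rank(b)
    if ra != rb:
        return -1 if ra < rb else 1
    if ra == 0:
        return 0
    if ra == 1:
        return (a > b) - (a < b)
    if ra == 2:
        return (float(a) > float(b)) - (float(a) < float(b))
    if ra == 3:
        ab, bb = a.encode(), b.encode()
        return (ab > bb) - (ab < bb)
    if ra == 4:
        ka, kb = (a.basename, a.md5), (b.basename, b.md5)
        return (ka > kb) - (ka < kb)
    if ra == 5:
        for x, y in zip(a, b):
            c = _oracle_cmp(x, y)
            if c:
                return c
        return (len(a) > len(b)) - (len(a) < len(b))
    ka = sorted((canonical_key(k), canonical_key(v)) for k, v in a.items())
    kb = sorted((canonical_key(k), canonical_key(v)) for k, v in b.items())
    return (ka > kb) - (ka < kb)


nested_values = st.recursive(
    st.none() | st.booleans() | st.integers(-50, 50) |
    st.floats(-10, 10, allow_nan=False) | st.text(max_size=4),
    lambda children: st.lists(children, max_size=3) |
    st.dictionaries(st.text(max_size=3), children, max_size=3),
    max_leaves=8)


@settings(max_examples=150, deadline=None)
@given(st.lists(st.lists(nested_values, max_size=4), max_size=6),
       st.randoms(use_true_random=False))
def test_sort_channel_matches_comparison_oracle(tuples, rnd):
    expected = sorted(tuples, key=functools.cmp_to_key(_oracle_cmp))
    got = sort_channel(tuples)
    assert [canonical_key(t) for t in got] == \
        [canonical_key(t) for t in expected]
    # idempotence and permutation invariance
    assert sort_channel(got) == got
    perm = list(tuples)
    rnd.shuffle(perm)
    assert sort_channel(perm) == got


def test_sort_channel_simple_examples():
    assert sort_channel([["b"], ["a"]]) == [["a"], ["b"]]
    assert sort_channel([]) == []
    # shorter prefix first
    assert sort_channel([[1, 2, 3], [1, 2]]) == [[1, 2], [1, 2, 3]]
    # type ranks: null < bool < number < text
    assert sort_channel([["x"], [1], [True], [None]]) == \
        [[None], [True], [1], ["x"]]


def test_file_refs_order_by_basename_then_md5(tmp_path):
    a = tmp_path / "a.txt"
    b = tmp_path / "b.txt"
    a.write_text("1")
    b.write_text("2")
    assert sort_channel([[FileRef(b)], [FileRef(a)]]) == \
        [[FileRef(a)], [FileRef(b)]]


# ------------------------------------------------------- assertions

def _case(*assertions):
    return TestCase(name="t",
                    then_assertions=[AssertionExpr(a) for a in assertions])


def test_evaluate_then_pass_fail_error(tmp_path):
    outputs = UnitOutputs(exit_status=0,
                          channels=ChannelMap({"versions": [["x:1"]]}))
    outcomes = evaluate_then(
        _case("out.exit_status == 0",
              'out.channels["versions"] | size == 2',
              'out.channels["missing"] | size == 1',
              "mystery.call(1)"),
        outputs)
    assert [o.status for o in outcomes] == \
        ["passed", "failed", "failed", "errored"]
    assert "missing channel" in outcomes[2].message


def test_vcf_plugin_in_assertion(tmp_path):
    from pipetest.fixtures import generate_records
    vcf = generate_records("vcf", 3, tmp_path / "v.vcf", samples=2, seed=1)
    outputs = UnitOutputs(produced_files=[FileRef(vcf)])
    outcomes = evaluate_then(
        _case("vcf.summary(out.files[0]).variant_count == 3"), outputs)
    assert outcomes[0].status == "passed"


# ----------------------------------------------------------- runner

def test_replay_run_all_pass(fig3_suites, fig3_backend, fig3_root, tmp_path):
    plan = order_tests(fig3_suites)
    report = run_plan(plan, fig3_backend,
                      RunOptions(project_root=fig3_root,
                                 workdir_root=tmp_path / "work"))
    assert report.totals == {"tests": 5, "passed": 5, "failed": 0,
                             "errored": 0, "skipped": 0}
    assert report.exit_code == 0


def test_violated_assertion_fails_case_and_exit(fig3_root, tmp_path):
    suites = discover_suites(fig3_root)
    # canned output that breaks one assertion: empty versions channel for m2
    outputs = {f"{s.suite_path}::case 1": {
        "exit_status": 0,
        "channels": {"versions": [] if s.subject.name == "m2"
                     else [["x:1.0"]]}} for s in suites}
    backend = ReplayBackend(outputs, project_root=fig3_root)
    report = run_plan(order_tests(suites), backend,
                      RunOptions(project_root=fig3_root,
                                 workdir_root=tmp_path / "w"))
    assert report.totals["failed"] == 1
    assert report.exit_code == 1


def test_missing_canned_output_errors(fig3_suites, fig3_root, tmp_path):
    backend = ReplayBackend({}, project_root=fig3_root)
    report = run_plan(order_tests(fig3_suites), backend,
                      RunOptions(project_root=fig3_root,
                                 workdir_root=tmp_path / "w"))
    assert report.totals["errored"] == 5


def test_command_backend_collects_files(tmp_path):
    from pipetest.model import TestSubject, TestSuite, UnitKind
    case = TestCase(
        name="echo",
        when_params={"command": "sh -c 'echo hello > out.txt'",
                     "collect": ["*.txt"]},
        then_assertions=[AssertionExpr("out.exit_status == 0"),
                         AssertionExpr('out.channels["out"] | size == 1')])
    suite = TestSuite(
        suite_path="tests/cmd.test.yaml",
        subject=TestSubject(UnitKind.PROCESS, "cmd", "x.nf", "X"),
        cases=[case])
    plan = order_tests([suite])
    report = run_plan(plan, CommandBackend(project_root=tmp_path),
                      RunOptions(project_root=tmp_path,
                                 workdir_root=tmp_path / "w"))
    assert report.totals["passed"] == 1


def test_compat_suite_skipped_without_engine(tmp_path):
    from pipetest.fixtures import fig3_project
    fig3_project(tmp_path, dialect="compat")
    suites = discover_suites(tmp_path)
    assert suites and all(s.dialect == "compat" for s in suites)
    backend = ReplayBackend({}, project_root=tmp_path)
    report = run_plan(order_tests(suites), backend,
                      RunOptions(project_root=tmp_path,
                                 workdir_root=tmp_path / "w"))
    assert report.totals["skipped"] == report.totals["tests"] > 0
    assert report.exit_code == 0  # skipped suites do not fail the run
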
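# pipetest

A testing framework for dataflow pipeline projects — the kind of
process/workflow/pipeline codebases built with DSL2-style workflow engines
in bioinformatics.  It provides declarative unit, integration and
end-to-end test suites, dependency-graph-driven *firewall* regression-test
selection, snapshot testing with canonical MD5 serialization,
coordinator-free test-list sharding, and format-aware assertions for
FASTA/FASTQ/VCF/SAM/CSV outputs.

## The problem

Pipelines compose many small units: processes (single tool invocations),
workflows (compositions of processes), and a top-level pipeline.  Testing
them is hard for two structural reasons:

1. **Cost.** End-to-end tests are expensive; rerunning every test on every
   change does not scale to repositories with hundreds of modules.
2. **Nondeterminism.** Units emit output *channels* whose tuple arrival
   order varies between runs, and many bioinformatics file formats embed
   volatile metadata (dates, command lines) that breaks byte-level
   comparison.

## The core algorithms

**Firewall selection.**  A directed dependency graph is built by static
parsing: nodes are component source files, test suites, snapshot stores,
declared test assets, and configured trigger files; edges point from user
to used (`include { M1 } from '../modules/m1'` gives `W1 → M1`).  For a
changed component *c*, the selected set is

- every suite whose subject is *c*, plus
- for each dependent *d* of *c*, CLIMB(*d*), where CLIMB(*x*) selects
  *x*'s own suites and stops if any exist, and otherwise recurses into the
  dependents of *x* (memoized; a climb that dies at an untested,
  unused node is reported as an *unverified path*).

The selected suites form a firewall around the change: the nearest tested
ancestors indirectly validate everything between themselves and *c*.
Changed suites, snapshots and assets reselect their own suites; a changed
trigger file (e.g. a container recipe) forces a full retest.  Coverage
status falls out of the same machinery: a component is covered iff
changing it would select at least one suite.

**Canonical channel order.**  Before assertions or snapshots see a
channel, its tuples are sorted under a frozen total order — by type rank
(null < boolean < number < text < file reference < list < mapping), then
numerically / bytewise / by (basename, content MD5) / elementwise — making
comparisons independent of arrival order.

**Snapshots.**  A snapshot is the canonical JSON serialization of a value,
stored beside the suite (`<suite>.snap`).  Files are recorded as
`"<basename>:md5,<hex>"`, never by content; a whole snapshot can be
compressed to a single MD5.  Verify mode creates on first run and fails on
divergence; `--update-snapshot` rewrites the reference; `--ci` forbids
creation and updates.

**Sharding.**  The test plan is sorted by (unit kind, suite path, case
index), so *n* machines can each derive their own subset with no
coordinator: `--shard i/n` with contiguous `chunk` blocks or a
`round-robin` deal whose shard sizes differ by at most one.

## Worked example

`pipetest init demo` scaffolds a six-component example project: processes
M1–M3, workflow W1 (includes M1, M2, untested), workflow W2 (includes M3,
tested), pipeline P1 (includes both workflows, tested).  Suites run
against the bundled replay backend, which serves canned channel outputs.

```text
$ pipetest init demo && cd demo
$ pipetest run --related-tests modules/m1.nf
selected tests/m1.test.yaml: direct suite of changed component modules/m1.nf
selected tests/p1.test.yaml: indirectly validates modules/m1.nf (nearest tested ancestor p1.nf)
PASSED   tests/m1.test.yaml::case 1
PASSED   tests/p1.test.yaml::case 1
2 tests: 2 passed, 0 failed, 0 errored, 0 skipped
```

Changing M1 selects exactly two suites: M1's own unit test, and —
because W1 has no test of its own — the climb continues to the pipeline,
whose end-to-end suite indirectly validates W1.  Changing M3 instead
selects `tests/m3.test.yaml` and `tests/w2.test.yaml` only: W2's
integration test stops the climb, and the expensive pipeline test is
skipped.

```text
$ pipetest coverage
...
ok  workflows/w1.nf (direct suites: 0)
ok  workflows/w2.nf (direct suites: 1)
coverage: 100.0%
```

W1 counts as covered with zero direct suites because the pipeline test
reaches it.  In a git repository, `pipetest run --changed-since HEAD^`
feeds the firewall from commit diffs; `--related-tests <file>` passes
changed files explicitly.

Suites are YAML (see `demo/tests/m1.test.yaml`): a subject
(kind/script/entry), then cases with `when` parameters, `then` assertions
in a small safe expression language
(`out.channels["versions"] | size == 1`,
`vcf.summary(out.files[0]).variant_count == 3`), and optional `snapshot`
expressions.  nf-test-style `.nf.test` suites are parsed structurally for
discovery, selection and coverage on existing projects.

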
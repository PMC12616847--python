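# Methods

This note documents the models and procedures pipetest implements, the
parameters that matter, the numerical and design choices that were
genuinely open, and what the synthetic fixtures do and do not emulate.

## Dependency graph

The graph is built purely statically — no project code is ever executed.
Component nodes are all `*.nf` files under the project root; edges come
from `include { A; B as C } from '<p>'` statements, lexed with a
"Groovy-lite" tokenizer that strips line/block comments and
single/double/triple-quoted strings before any pattern matching, so
includes inside comments or strings never create edges.  Include
references resolve relative to the including file, trying `<p>`, `<p>.nf`,
`<p>/main.nf` in that order; unresolved references are recorded in
`parse_stats.unresolved_includes` and never abort graph construction
(large repositories contain dead references).  Suites link to the subject
they validate, to their snapshot store (`<suite>` + configured suffix,
default `.snap`) when present on disk, and to declared assets.  Trigger
globs from `pipetest.config.yaml` materialize as trigger nodes.

Cycles among components are tolerated and flagged (detection is delegated
to networkx); the selection algorithm's visited-node memoization doubles
as cycle protection.  Edge direction is user → used, matching the include
direction in source; `dependents()` inverts it.

## Firewall selection

For a changed component, its own suites are always selected *and* its
dependents are always climbed — an interface change can break dependents
even when the component itself has tests.  CLIMB stops ascending a path at
the first node with direct suites; ascent continues on other paths
(diamonds are handled by memoization, and set semantics make visit order
irrelevant).  A climb that terminates at a node with neither suites nor
dependents records that terminal in `unverified_paths` — the safety gap
diagnostic.  Output order is (unit kind, suite path), with kind order
function < process < workflow < pipeline, so cheap tests run first and
output is byte-stable across platforms.

Coverage uses the lenient rule — a component is covered if *any* climb
reaches a suite; `--strict` additionally requires that no climb path dies
unverified.  Changed files under the tests directory that are neither
suites nor snapshots (shared helper fixtures) select the suites in the
same directory; this is a pragmatic rule, documented here because no
principled answer exists at discovery level.  Selection granularity is the
suite, not the case; `--exclude-tag` gives post-selection control for
keeping expensive end-to-end suites out of a firewall.

The test oracle for selection is an independently coded brute-force
recursion (no memoization, explicit path sets) checked on 500 random
layered DAG topologies of at most 12 nodes with random test placement,
plus union, subset, determinism and per-path safety properties.  Topology
seeds are recorded; the acceptance script redraws them from `--seed`.

## Canonical channel order

Channel tuples arrive in nondeterministic order under parallel execution,
so a total order had to be frozen; the specific rank table (null <
boolean < number < text < file reference < list < mapping; numbers
numeric, text bytewise UTF-8, files by (basename, content MD5), lists
elementwise with shorter prefix first, mappings as sorted key/value
lists) is a design choice of this framework and is stable — changing it
would invalidate every existing snapshot.  `sort_channel` is idempotent
and permutation-invariant, verified against a comparison-sort oracle
built from a pairwise comparator written directly from the rank table.

## Snapshots

Canonical serialization is JSON with sorted keys, UTF-8, shortest
round-trip floats, two-space indentation and one leaf per line, so stores
diff line-granularly under version control.  A list whose elements are
all lists is treated as a channel and canonically sorted before
serialization; scalar lists keep their order (a deliberate heuristic:
channel payloads are tuple lists, ordinary value lists are not).  File
references serialize as `"<basename>:md5,<hex>"`; file content is never
stored.  The whole-snapshot compressed form stores the MD5 of the exact
serialized bytes.

Lifecycle: verify mode creates-and-passes on first run (the standard
snapshot-testing convention), matches or mismatches afterwards; update
mode overwrites; CI mode fails on missing or differing references and
never writes.  Timestamps live in entry metadata and are excluded from
comparison.  A corrupt store is a suite-level error — it is never
silently overwritten.

## Execution backends

The runner's contract with a backend is narrow: given (suite, case,
isolated work directory), return exit status, channels, produced files
and captured output, without mutating the project tree.  Three backends
implement it.  `replay` serves canned outputs from a YAML fixture and is
fully deterministic — it exists so the framework itself, and projects'
selection/report plumbing, can be tested with no engine installed.
`command` runs a command template from the case's `when` block and
gathers files by glob into pseudo-channel `out`.  `engine` renders a
driver workflow that includes the subject script, binds the
when-parameters and serializes each output channel as a JSON document,
then invokes the external workflow engine as a separate process; when no
engine is on PATH the suite is skipped with an explicit reason rather
than failed.  Compat-dialect suites (`.nf.test`) embed host-language
assertion code which this framework never evaluates; they are
discoverable and selectable everywhere but executable only on the engine
backend.

Work directories are one per case under the work root, named by a short
hash of (suite path, case name); they are removed on success and retained
on failure (or always, with `--keep-workdirs`).  Durations are wall-clock
per case, reported with millisecond precision, and never influence
selection or sharding.

## Sharding

Plans are sorted by (unit kind, suite path, case index); each machine
derives its subset independently from the same list.  `chunk` makes
contiguous blocks whose sizes differ by at most one, earlier shards
taking the remainder; `round_robin` assigns entry *j* (0-based) to shard
(*j* mod *n*) + 1.  Neither strategy consults historical runtimes — the
split is deterministic and coordinator-free by design, with no fairness
guarantee beyond count balance.

## Format-aware assertions

`summarize` parses FASTA (Biopython), FASTQ (a manual four-line parse,
because the contract requires structural errors with line numbers:
plus-line mismatch, truncated record, sequence/quality length mismatch),
VCF and SAM (pysam; a light pre-check reports a missing `#CHROM` line
with its line number before pysam parses records), and delimited tables
(csv).  Gzip input is accepted for FASTA/FASTQ/VCF.  ID lists are capped
(default 10,000) to bound memory; the cap is recorded in the summary.

`content_digest` hashes a normalized view chosen per format: FASTA —
sequences uppercased, rewrapped to 60 columns, records sorted by id;
FASTQ — sequence and quality lines only; VCF — header lines with the
volatile prefixes `##fileDate`, `##source`, `##commandline` dropped
(configurable; the default list is an informed choice, not a standard);
SAM — `@PG`/`@CO` header lines dropped; tables — cells in configured
volatile columns masked.  Normalization happens at line level by
construction: it must remove specific header lines before hashing, below
the abstraction level record parsers expose.

BAM is handled through its SAM text representation; binary-BAM reading,
CRAM, BCF and indexed access are out of scope for the core.

## Synthetic fixtures

Generated projects use real include syntax so the production parser is
exercised end to end, and are byte-deterministic given the topology spec.
The worked example has three processes, one untested workflow, one tested
workflow and a tested pipeline — the smallest shape exhibiting both the
climb-past-untested and stop-at-tested behaviors.  The untested workflow's
sibling M2 carries a test; whether it does affects neither worked
example.  Random topologies are layered DAGs (processes, then workflows
over earlier nodes, optionally a pipeline) of 2–12 nodes with 0–2 suites
per node.

Record generators emit small, valid files with exact record counts;
volatile VCF headers are drawn from a separate random stream so that
toggling them never perturbs record content (the digest-invariance tests
depend on this).  What the fixtures do *not* emulate: realistic pipeline
runtimes, large data volumes, malformed real-world files, engine-specific
channel semantics, or repository-scale include graphs — so passing tests
demonstrate algorithmic correctness on faithful miniatures, not
performance or robustness against arbitrary inputs.  Change-detection
tests run against scripted git repositories created in temporary
directories; untracked files count as changes (a new test must run) and
ignored files never do.

## Problem sizes

The default verification uses 500 random topologies (≈4,500 change sets)
for the selection oracle, plan sizes 1–200 across 1–10 shards for the
partition laws, a 5×4 format×count grid for round trips, and the
six-component worked example for end-to-end runs — sizes chosen so the
whole suite verifies in seconds while covering every branch of the
algorithms.
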
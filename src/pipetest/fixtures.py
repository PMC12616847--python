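"""Deterministic toy pipeline projects and biological files.

Everything the framework needs for worked examples and self-testing is
generated here: small pipeline projects with real include syntax (so the
production include parser is exercised, never a shortcut), native or
compat test suites, replay fixtures with canned outputs, and valid
FASTA/FASTQ/VCF/SAM/CSV files with known record counts.

``fig3_project`` builds the canonical worked example: three processes
(M1, M2, M3), workflow W1 including M1 and M2, workflow W2 including M3,
pipeline P1 including both workflows.  W1 has no direct suite — changing
M1 must climb past it to P1's end-to-end test, while changing M3 stops at
W2's own integration test.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from pipetest.model import UnitKind

_KIND_DIR = {
    UnitKind.FUNCTION: "lib",
    UnitKind.PROCESS: "modules",
    UnitKind.WORKFLOW: "workflows",
    UnitKind.PIPELINE: "",
}

_COMPAT_BLOCK = {
    UnitKind.FUNCTION: "nextflow_function",
    UnitKind.PROCESS: "nextflow_process",
    UnitKind.WORKFLOW: "nextflow_workflow",
    UnitKind.PIPELINE: "nextflow_pipeline",
}


@dataclass(frozen=True)
class NodeSpec:
    id: str
    kind: UnitKind
    includes: tuple[str, ...] = ()
    tests: int = 1


@dataclass
class TopologySpec:
    nodes: list[NodeSpec]
    triggers: list[str] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self):
        ids = [n.id for n in self.nodes]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate node ids in topology spec")
        declared = set(ids)
        for n in self.nodes:
            if n.kind in (UnitKind.PROCESS, UnitKind.FUNCTION) and n.includes:
                raise ValueError(f"{n.kind.value} node {n.id} may not "
                                 f"include anything")
            for inc in n.includes:
                if inc not in declared:
                    raise ValueError(
                        f"node {n.id} includes undeclared id {inc!r}")

    def by_id(self, node_id: str) -> NodeSpec:
        for n in self.nodes:
            if n.id == node_id:
                return n
        raise KeyError(node_id)


def component_path(node: NodeSpec) -> str:
    d = _KIND_DIR[node.kind]
    return f"{d}/{node.id.lower()}.nf" if d else f"{node.id.lower()}.nf"


def suite_path_for(node: NodeSpec, dialect: str = "native") -> str:
    if dialect == "compat":
        return f"tests/{node.id.lower()}.nf.test"
    return f"tests/{node.id.lower()}.test.yaml"


def _rel_include(user_file: str, used_file: str) -> str:
    # path written inside an include statement: relative, without '.nf'
    user_dir = Path(user_file).parent
    target = Path(used_file).with_suffix("")
    parts = []
    up = user_dir
    while up != Path("") and up != Path("."):
        parts.append("..")
        up = up.parent
    rel = "/".join(parts + [target.as_posix()]) if parts else target.as_posix()
    return rel if rel.startswith(("../", "./")) else "./" + rel


def generate_project(spec: TopologySpec, root: str | Path,
                     dialect: str = "native") -> Path:
    """Write a complete toy project realizing the topology.

    Byte-deterministic given the spec (including its seed).  Source files
    use real include syntax; each node with ``tests > 0`` gets one suite
    with that many cases; a replay fixture with canned outputs satisfying
    every assertion is written alongside the suites.
    """
    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    rng = random.Random(spec.seed)

    replay: dict[str, dict] = {}
    for node in spec.nodes:
        cpath = component_path(node)
        src = root / cpath
        src.parent.mkdir(parents=True, exist_ok=True)
        src.write_text(_render_source(spec, node))

        if node.tests > 0:
            spath = suite_path_for(node, dialect)
            sfile = root / spath
            sfile.parent.mkdir(parents=True, exist_ok=True)
            if dialect == "compat":
                sfile.write_text(_render_compat_suite(node, cpath))
            else:
                sfile.write_text(_render_native_suite(node, cpath))
            tool_version = f"{node.id.lower()}:{rng.randint(1, 9)}.0"
            for i in range(node.tests):
                replay[f"{spath}::case {i + 1}"] = {
                    "exit_status": 0,
                    "channels": {"versions": [[tool_version]]},
                }

    (root / "tests").mkdir(exist_ok=True)
    with open(root / "tests" / "replay_outputs.yaml", "w") as fh:
        yaml.safe_dump(replay, fh, sort_keys=True)

    for trigger in spec.triggers:
        (root / trigger).write_text(f"# trigger file {trigger}\n")

    config = {
        "testsDir": "tests",
        "patterns": (["tests/**/*.test.yaml"] if dialect == "native"
                     else ["tests/**/*.nf.test"]),
        "triggers": list(spec.triggers),
        "snapshotSuffix": ".snap",
    }
    with open(root / "pipetest.config.yaml", "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
    return root


def _render_source(spec: TopologySpec, node: NodeSpec) -> str:
    cpath = component_path(node)
    lines = [f"// {node.kind.value} {node.id}"]
    for inc_id in node.includes:
        used = component_path(spec.by_id(inc_id))
        lines.append(
            f"include {{ {inc_id} }} from '{_rel_include(cpath, used)}'")
    if node.kind == UnitKind.PROCESS:
        lines += [
            f"process {node.id} {{",
            "    output:",
            "    stdout emit: versions",
            "    script:",
            f"    \"echo {node.id.lower()}\"",
            "}",
        ]
    elif node.kind == UnitKind.FUNCTION:
        lines += [f"def {node.id}() {{ return '{node.id.lower()}' }}"]
    else:
        body = "\n".join(f"    {inc}()" for inc in node.includes) or "    // empty"
        lines += [f"workflow {node.id} {{", body, "}"]
    return "\n".join(lines) + "\n"


def _render_native_suite(node: NodeSpec, cpath: str) -> str:
    doc = {
        "suite": {
            "name": node.id.lower(),
            "subject": {
                "kind": node.kind.value,
                "script": f"../{cpath}",
                "entry": "" if node.kind == UnitKind.PIPELINE else node.id,
            },
            "tags": [node.kind.value],
        },
        "tests": [
            {
                "name": f"case {i + 1}",
                "then": [
                    "out.exit_status == 0",
                    'out.channels["versions"] | size == 1',
                ],
            }
            for i in range(node.tests)
        ],
    }
    return yaml.safe_dump(doc, sort_keys=False)


def _render_compat_suite(node: NodeSpec, cpath: str) -> str:
    block = _COMPAT_BLOCK[node.kind]
    entry = ""
    if node.kind in (UnitKind.PROCESS, UnitKind.WORKFLOW, UnitKind.FUNCTION):
        entry = f'    {node.kind.value} "{node.id}"\n'
    tests = "\n".join(
        f'    test("case {i + 1}") {{\n'
        f"        when {{ params {{ }} }}\n"
        f"        then {{ assert true }}\n"
        f"    }}\n"
        for i in range(node.tests))
    return (
        f"{block} {{\n"
        f'    name "{node.id.lower()}"\n'
        f'    script "../{cpath}"\n'
        f"{entry}"
        f'    tag "{node.kind.value}"\n'
        f"{tests}"
        f"}}\n")


def fig3_spec(seed: int = 0) -> TopologySpec:
    return TopologySpec(
        nodes=[
            NodeSpec("M1", UnitKind.PROCESS, tests=1),
            NodeSpec("M2", UnitKind.PROCESS, tests=1),
            NodeSpec("M3", UnitKind.PROCESS, tests=1),
            NodeSpec("W1", UnitKind.WORKFLOW, includes=("M1", "M2"), tests=0),
            NodeSpec("W2", UnitKind.WORKFLOW, includes=("M3",), tests=1),
            NodeSpec("P1", UnitKind.PIPELINE, includes=("W1", "W2"), tests=1),
        ],
        triggers=["Dockerfile"],
        seed=seed,
    )


def fig3_project(root: str | Path, dialect: str = "native") -> Path:
    """The worked-example project (see module docstring)."""
    return generate_project(fig3_spec(), root, dialect=dialect)


def random_topology(seed: int, max_nodes: int = 12) -> TopologySpec:
    """Random layered DAG with random test placement.

    Processes form the bottom layer; workflows include a random non-empty
    subset of earlier nodes; an optional pipeline sits on top.  Each node
    carries 0–2 suites.  The substrate for oracle-equivalence property
    tests of the firewall algorithm.
    """
    rng = random.Random(seed)
    n_total = rng.randint(2, max_nodes)
    n_proc = max(1, rng.randint(1, max(1, n_total // 2)))
    nodes: list[NodeSpec] = []
    for i in range(n_proc):
        nodes.append(NodeSpec(f"M{i + 1}", UnitKind.PROCESS,
                              tests=rng.randint(0, 2)))
    n_wf = n_total - n_proc
    with_pipeline = n_wf > 1 and rng.random() < 0.5
    if with_pipeline:
        n_wf -= 1
    for i in range(n_wf):
        pool = [n.id for n in nodes]
        k = rng.randint(1, min(3, len(pool)))
        includes = tuple(sorted(rng.sample(pool, k)))
        nodes.append(NodeSpec(f"W{i + 1}", UnitKind.WORKFLOW,
                              includes=includes, tests=rng.randint(0, 2)))
    if with_pipeline:
        pool = [n.id for n in nodes if n.kind == UnitKind.WORKFLOW] or \
            [n.id for n in nodes]
        k = rng.randint(1, min(3, len(pool)))
        nodes.append(NodeSpec("P1", UnitKind.PIPELINE,
                              includes=tuple(sorted(rng.sample(pool, k))),
                              tests=rng.randint(0, 2)))
    triggers = ["Dockerfile"] if rng.random() < 0.3 else []
    return TopologySpec(nodes=nodes, triggers=triggers, seed=seed)


# ------------------------------------------------------- record files

_BASES = "ACGT"


def generate_records(format: str, n: int, out_path: str | Path,
                     samples: int = 2, seed: int = 0,
                     volatile_headers: bool = False,
                     delimiter: str = ",",
                     read_length: int = 50,
                     rng: Optional[random.Random] = None) -> Path:
    """Write a valid file of the requested format with exactly ``n``
    records, deterministic from ``seed``."""
    if n < 0:
        raise ValueError("n must be >= 0")
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    rng = rng or random.Random(seed)
    writers = {
        "fasta": _write_fasta, "fastq": _write_fastq, "vcf": _write_vcf,
        "sam": _write_sam, "csv": _write_table, "table": _write_table,
    }
    if format not in writers:
        raise ValueError(f"unsupported format {format!r}")
    text = writers[format](n, rng, samples=samples,
                           volatile_headers=volatile_headers,
                           delimiter=delimiter, read_length=read_length)
    out_path.write_text(text)
    return out_path


def _seq(rng: random.Random, length: int) -> str:
    return "".join(rng.choice(_BASES) for _ in range(length))


def _write_fasta(n, rng, read_length=50, **_) -> str:
    out = []
    for i in range(n):
        out.append(f">seq_{i + 1} synthetic record {i + 1}")
        out.append(_seq(rng, read_length))
    return "\n".join(out) + ("\n" if out else "")


def _write_fastq(n, rng, read_length=50, **_) -> str:
    out = []
    for i in range(n):
        out.append(f"@read_{i + 1}")
        out.append(_seq(rng, read_length))
        out.append("+")
        out.append("".join(chr(33 + rng.randint(20, 40))
                           for _ in range(read_length)))
    return "\n".join(out) + ("\n" if out else "")


def _write_vcf(n, rng, samples=2, volatile_headers=False, **_) -> str:
    header = ["##fileformat=VCFv4.2"]
    if volatile_headers:
        # separate stream: volatile metadata must not perturb record content
        vrng = random.Random(rng.getstate()[1][0] ^ 0x9E3779B9)
        header += [
            f"##fileDate={vrng.randint(2020, 2029)}0{vrng.randint(1, 9)}"
            f"{vrng.randint(10, 28)}",
            "##source=pipetest-synthetic",
            "##commandline=generate_records",
        ]
    header += [
        "##contig=<ID=chr1,length=1000000>",
        '##INFO=<ID=DP,Number=1,Type=Integer,Description="Depth">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    ]
    sample_names = [f"S{i + 1}" for i in range(samples)]
    cols = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO"]
    if samples:
        cols += ["FORMAT"] + sample_names
    header.append("\t".join(cols))
    body = []
    pos = 0
    for i in range(n):
        pos += rng.randint(10, 1000)
        ref = rng.choice(_BASES)
        alt = rng.choice([b for b in _BASES if b != ref])
        row = ["chr1", str(pos), f"var_{i + 1}", ref, alt,
               str(rng.randint(10, 99)), "PASS", f"DP={rng.randint(5, 60)}"]
        if samples:
            row.append("GT")
            row += [rng.choice(["0/0", "0/1", "1/1"]) for _ in sample_names]
        body.append("\t".join(row))
    return "\n".join(header + body) + "\n"


def _write_sam(n, rng, read_length=50, volatile_headers=False, **_) -> str:
    header = ["@HD\tVN:1.6\tSO:unsorted",
              "@SQ\tSN:chr1\tLN:1000000"]
    if volatile_headers:
        header += ["@PG\tID:pipetest\tPN:pipetest\tCL:generate_records",
                   "@CO\tsynthetic file"]
    body = []
    pos = 0
    for i in range(n):
        pos += rng.randint(10, 500)
        seq = _seq(rng, read_length)
        qual = "I" * read_length
        flag = rng.choice([0, 16])
        body.append("\t".join([
            f"read_{i + 1}", str(flag), "chr1", str(pos), "60",
            f"{read_length}M", "*", "0", "0", seq, qual]))
    return "\n".join(header + body) + "\n"


def _write_table(n, rng, delimiter=",", **_) -> str:
    import csv as _csv
    import io as _io
    buf = _io.StringIO()
    writer = _csv.writer(buf, delimiter=delimiter, lineterminator="\n")
    writer.writerow(["sample", "reads", "mapped_pct", "timestamp"])
    for i in range(n):
        writer.writerow([
            f"S{i + 1}", rng.randint(1000, 99999),
            round(rng.uniform(50, 99), 2),
            f"2024-01-{rng.randint(10, 28)}T0{rng.randint(0, 9)}:00:00"])
    return buf.getvalue()
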
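"""Format-aware summaries, normalized digests, plugin registry."""

import pytest

from pipetest.bio import FormatError, content_digest, summarize
from pipetest.fixtures import generate_records
from pipetest.plugins import (
    PluginError, PluginManifest, PluginRegistry, default_registry,
    register_plugin,
)


@pytest.mark.parametrize("fmt", ["fasta", "fastq", "vcf", "sam", "csv"])
@pytest.mark.parametrize("n", [0, 1, 2, 5, 12])
def test_generator_parser_round_trip(tmp_path, fmt, n):
    path = generate_records(fmt, n, tmp_path / f"f.{fmt}", samples=2, seed=n)
    summary = summarize(path, "table" if fmt == "csv" else fmt)
    assert summary.record_count == n
    assert len(summary.ids) == min(n, summary.id_cap)


@pytest.mark.parametrize("samples", [0, 1, 2, 4])
def test_vcf_samples_round_trip(tmp_path, samples):
    path = generate_records("vcf", 3, tmp_path / "v.vcf",
                            samples=samples, seed=3)
    summary = summarize(path, "vcf")
    assert summary.record_count == summary.variant_count == 3
    assert len(summary.samples) == samples
    assert summary.extras["chromosomes"] == ["chr1"]


def test_fasta_gzip_supported(tmp_path):
    import gzip
    raw = generate_records("fasta", 3, tmp_path / "a.fasta", seed=1)
    gz = tmp_path / "a.fasta.gz"
    gz.write_bytes(gzip.compress(raw.read_bytes()))
    assert summarize(gz, "fasta").record_count == 3


def test_sam_flag_histogram(tmp_path):
    path = generate_records("sam", 10, tmp_path / "a.sam", seed=5)
    summary = summarize(path, "sam")
    hist = summary.extras["flag_histogram"]
    assert sum(hist.values()) == 10
    assert set(hist) <= {0, 16}


def test_table_columns_and_delimiter(tmp_path):
    path = generate_records("csv", 4, tmp_path / "t.csv", seed=2)
    summary = summarize(path, "table")
    assert summary.columns == ["sample", "reads", "mapped_pct", "timestamp"]
    tsv = generate_records("csv", 2, tmp_path / "t.tsv", seed=2,
                           delimiter="\t")
    assert summarize(tsv, "table", delimiter="\t").record_count == 2


def test_fastq_plus_line_mismatch_reports_line_number(tmp_path):
    bad = tmp_path / "bad.fastq"
    bad.write_text("@r1\nACGT\n-\nIIII\n")
    with pytest.raises(FormatError, match="bad.fastq:3"):
        summarize(bad, "fastq")
    trunc = tmp_path / "trunc.fastq"
    trunc.write_text("@r1\nACGT\n")
    with pytest.raises(FormatError, match="multiple of 4"):
        summarize(trunc, "fastq")
    short = tmp_path / "short.fastq"
    short.write_text("@r1\nACGT\n+\nII\n")
    with pytest.raises(FormatError, match="lengths differ"):
        summarize(short, "fastq")


def test_vcf_missing_chrom_header_errors(tmp_path):
    bad = tmp_path / "bad.vcf"
    bad.write_text("##fileformat=VCFv4.2\nchr1\t5\t.\tA\tT\t.\t.\t.\n")
    with pytest.raises(FormatError, match="#CHROM"):
        summarize(bad, "vcf")


def test_vcf_volatile_header_invariance(tmp_path):
    a = generate_records("vcf", 5, tmp_path / "a.vcf", seed=9,
                         volatile_headers=True)
    b = generate_records("vcf", 5, tmp_path / "b.vcf", seed=9,
                         volatile_headers=False)
    assert a.read_text() != b.read_text()  # files genuinely differ on disk
    assert content_digest(a, "vcf") == content_digest(b, "vcf")


def test_vcf_genotype_perturbation_changes_digest(tmp_path):
    a = generate_records("vcf", 5, tmp_path / "a.vcf", seed=9)
    text = a.read_text()
    assert "0/1" in text or "1/1" in text or "0/0" in text
    for old, new in (("0/1", "1/1"), ("1/1", "0/0"), ("0/0", "0/1")):
        if old in text:
            mutated = tmp_path / "m.vcf"
            mutated.write_text(text.replace(old, new, 1))
            break
    assert content_digest(a, "vcf") != content_digest(mutated, "vcf")


def test_sam_pg_co_headers_volatile(tmp_path):
    a = generate_records("sam", 4, tmp_path / "a.sam", seed=2,
                         volatile_headers=True)
    b = generate_records("sam", 4, tmp_path / "b.sam", seed=2,
                         volatile_headers=False)
    assert content_digest(a, "sam") == content_digest(b, "sam")


def test_fasta_digest_invariant_to_record_order_and_case(tmp_path):
    a = tmp_path / "a.fasta"
    a.write_text(">b\nacgtacgt\n>a\nTTTT\n")
    b = tmp_path / "b.fasta"
    b.write_text(">a\nTTTT\n>b\nACGTACGT\n")
    assert content_digest(a, "fasta") == content_digest(b, "fasta")
    c = tmp_path / "c.fasta"
    c.write_text(">a\nTTTA\n>b\nACGTACGT\n")
    assert content_digest(a, "fasta") != content_digest(c, "fasta")


def test_fastq_digest_is_sequence_and_quality_only(tmp_path):
    a = tmp_path / "a.fastq"
    a.write_text("@r1 lane1\nACGT\n+\nIIII\n")
    b = tmp_path / "b.fastq"
    b.write_text("@r1 lane2\nACGT\n+\nIIII\n")  # header differs only
    assert content_digest(a, "fastq") == content_digest(b, "fastq")


def test_table_volatile_column_masking(tmp_path):
    a = generate_records("csv", 3, tmp_path / "a.csv", seed=4)
    b = generate_records("csv", 3, tmp_path / "b.csv", seed=5)
    # same seed for data differs; but masking timestamp with same data seed:
    text_a = a.read_text()
    mutated = tmp_path / "m.csv"
    mutated.write_text(text_a.replace("2024-01", "2031-12"))
    assert content_digest(a, "table", volatile_columns=("timestamp",)) == \
        content_digest(mutated, "table", volatile_columns=("timestamp",))
    assert content_digest(a, "table") != content_digest(mutated, "table")
    assert content_digest(a, "table") != content_digest(b, "table")


def test_empty_fasta(tmp_path):
    p = tmp_path / "e.fasta"
    p.write_text("")
    assert summarize(p, "fasta").record_count == 0


def test_id_cap_recorded(tmp_path):
    path = generate_records("fasta", 30, tmp_path / "f.fasta", seed=1)
    summary = summarize(path, "fasta", id_cap=10)
    assert summary.record_count == 30
    assert len(summary.ids) == 10 and summary.id_cap == 10


# ------------------------------------------------------------ plugins

def test_register_and_call_plugin():
    registry = PluginRegistry()
    register_plugin(registry, PluginManifest(
        "stats", {"double": lambda x: 2 * x}))
    assert registry.namespaces()["stats"]["double"](4) == 8


def test_duplicate_namespace_errors():
    registry = default_registry()
    with pytest.raises(PluginError, match="already registered"):
        registry.register(PluginManifest("vcf", {}))


def test_default_registry_namespaces_complete():
    names = set(default_registry().namespaces())
    assert names == {"vcf", "fasta", "fastq", "sam", "csv"}


def test_unregistered_namespace_errors_in_assertion():
    from pipetest.exprs import AssertionExpr, Environment, EvalError, evaluate
    with pytest.raises(EvalError, match="unknown name"):
        evaluate(AssertionExpr("bam.summary('x')"),
                 Environment(namespaces=default_registry().namespaces()))
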
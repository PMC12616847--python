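"""Format-aware file summaries and normalized content digests.

Pipeline outputs in standard bioinformatics formats are rarely
byte-identical across runs: VCF headers carry dates and command lines,
SAM headers record program invocations, tables embed timestamps.
``content_digest`` hashes a *normalized* view with those volatile fields
removed, so assertions and snapshots compare what matters.  ``summarize``
exposes record counts, identifiers and per-format metadata for use in
assertions (``vcf.summary(p).variant_count == 3``).

Supported: FASTA, FASTQ (4-line), VCF (text, optionally gzip), SAM,
CSV/TSV.  BAM is handled through its SAM text representation.
"""

from __future__ import annotations

import csv
import gzip
import hashlib
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import pysam
from Bio import SeqIO

from pipetest.model import SpecError

FORMATS = ("fasta", "fastq", "vcf", "sam", "table")

DEFAULT_ID_CAP = 10_000

# header lines dropped before hashing, by format (prefix match)
VOLATILE_VCF_HEADERS = ("##fileDate", "##source", "##commandline")
VOLATILE_SAM_HEADERS = ("@PG", "@CO")

FASTA_WRAP = 60  # fixed line width used by the normalized FASTA view


class FormatError(SpecError):
    """A file violates its format's structure (reported with line number)."""


@dataclass
class FormatSummary:
    format: str
    record_count: int
    ids: list[str] = field(default_factory=list)
    id_cap: int = DEFAULT_ID_CAP
    extras: dict[str, Any] = field(default_factory=dict)

    # convenience aliases used in assertions
    @property
    def variant_count(self) -> int:
        return self.record_count

    @property
    def samples(self) -> list[str]:
        return list(self.extras.get("samples", []))

    @property
    def columns(self) -> list[str]:
        return list(self.extras.get("columns", []))


def _open_text(path: Path):
    if str(path).endswith(".gz"):
        return io.TextIOWrapper(gzip.open(path, "rb"), encoding="utf-8")
    return open(path, "r", encoding="utf-8")


def summarize(path: str | Path, format: str,
              id_cap: int = DEFAULT_ID_CAP,
              delimiter: Optional[str] = None) -> FormatSummary:
    """Parse a file and return its record count, ids and per-format extras."""
    path = Path(path)
    if format not in FORMATS and format != "csv":
        raise FormatError(f"unsupported format {format!r}", str(path))
    if format == "csv":
        format = "table"
    if not path.is_file():
        raise FormatError("file does not exist", str(path))
    if format == "fasta":
        return _summarize_fasta(path, id_cap)
    if format == "fastq":
        return _summarize_fastq(path, id_cap)
    if format == "vcf":
        return _summarize_vcf(path, id_cap)
    if format == "sam":
        return _summarize_sam(path, id_cap)
    return _summarize_table(path, id_cap, delimiter or ",")


def _summarize_fasta(path: Path, id_cap: int) -> FormatSummary:
    count = 0
    ids: list[str] = []
    with _open_text(path) as fh:
        for record in SeqIO.parse(fh, "fasta"):
            count += 1
            if len(ids) < id_cap:
                ids.append(record.id)
    return FormatSummary("fasta", count, ids, id_cap)


def _summarize_fastq(path: Path, id_cap: int) -> FormatSummary:
    # manual 4-line parse: the contract requires structural validation with
    # line numbers (plus-line mismatch, truncated record, length mismatch)
    count = 0
    ids: list[str] = []
    qual_total, qual_n = 0, 0
    with _open_text(path) as fh:
        lines = fh.read().splitlines()
    if lines and not lines[-1].strip():
        lines.pop()
    if len(lines) % 4 != 0:
        raise FormatError(
            f"truncated FASTQ record (file has {len(lines)} lines, not a "
            f"multiple of 4)", str(path), len(lines))
    for i in range(0, len(lines), 4):
        head, seq, plus, qual = lines[i:i + 4]
        if not head.startswith("@"):
            raise FormatError("FASTQ header must start with '@'",
                              str(path), i + 1)
        if not plus.startswith("+"):
            raise FormatError("FASTQ separator line must start with '+'",
                              str(path), i + 3)
        if plus[1:] and plus[1:] != head[1:]:
            raise FormatError("FASTQ plus-line id does not match header",
                              str(path), i + 3)
        if len(seq) != len(qual):
            raise FormatError("sequence and quality lengths differ",
                              str(path), i + 4)
        count += 1
        if len(ids) < id_cap:
            ids.append(head[1:].split()[0] if head[1:] else "")
        qual_total += sum(ord(c) - 33 for c in qual)
        qual_n += len(qual)
    extras = {"mean_quality": (qual_total / qual_n) if qual_n else 0.0}
    return FormatSummary("fastq", count, ids, id_cap, extras)


def _summarize_vcf(path: Path, id_cap: int) -> FormatSummary:
    with _open_text(path) as fh:
        lines = fh.read().splitlines()
    header_line = None
    for i, ln in enumerate(lines):
        if ln.startswith("#CHROM"):
            header_line = i
            break
        if not ln.startswith("##"):
            raise FormatError("missing #CHROM header line", str(path), i + 1)
    if header_line is None:
        raise FormatError("missing #CHROM header line", str(path),
                          len(lines))
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        count = 0
        ids: list[str] = []
        chroms: list[str] = []
        for rec in vf:
            count += 1
            if len(ids) < id_cap:
                ids.append(rec.id or f"{rec.chrom}:{rec.pos}")
            if rec.chrom not in chroms:
                chroms.append(rec.chrom)
    return FormatSummary("vcf", count, ids, id_cap,
                         {"samples": samples, "chromosomes": chroms})


def vcf_variant(path: str | Path, index: int) -> dict:
    """Accessor for the i-th (0-based) variant record."""
    from pipetest.channels import FileRef
    if isinstance(path, FileRef):
        path = path.path
    with pysam.VariantFile(str(path)) as vf:
        for i, rec in enumerate(vf):
            if i == index:
                return {
                    "chrom": rec.chrom,
                    "pos": rec.pos,
                    "id": rec.id,
                    "ref": rec.ref,
                    "alt": list(rec.alts or ()),
                    "qual": rec.qual,
                }
    raise FormatError(f"variant index {index} out of range", str(path))


def _summarize_sam(path: Path, id_cap: int) -> FormatSummary:
    flags: dict[int, int] = {}
    count = 0
    ids: list[str] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as af:
        for read in af:
            count += 1
            if len(ids) < id_cap:
                ids.append(read.query_name or "")
            flags[read.flag] = flags.get(read.flag, 0) + 1
    return FormatSummary("sam", count, ids, id_cap,
                         {"flag_histogram": dict(sorted(flags.items()))})


def _summarize_table(path: Path, id_cap: int, delimiter: str) -> FormatSummary:
    with _open_text(path) as fh:
        rows = list(csv.reader(fh, delimiter=delimiter))
    if not rows:
        return FormatSummary("table", 0, [], id_cap,
                             {"columns": [], "delimiter": delimiter})
    columns = rows[0]
    data = rows[1:]
    ids = [r[0] for r in data[:id_cap] if r]
    return FormatSummary("table", len(data), ids, id_cap,
                         {"columns": columns, "delimiter": delimiter})


# --------------------------------------------------------- digests


def content_digest(path: str | Path, format: str,
                   volatile_headers: Optional[tuple[str, ...]] = None,
                   volatile_columns: tuple[str, ...] = (),
                   delimiter: Optional[str] = None) -> str:
    """MD5 of the normalized file content.

    Normalizations (frozen defaults, configurable per project):
    fasta — sequences uppercased, rewrapped to a fixed width, records
    sorted by id; fastq — sequence and quality lines only; vcf — header
    lines matching the volatile prefixes (default ``##fileDate``,
    ``##source``, ``##commandline``) dropped; sam — ``@PG``/``@CO``
    header lines dropped; table — cells in volatile columns masked.
    """
    path = Path(path)
    if format == "csv":
        format = "table"
    if format not in FORMATS:
        raise FormatError(f"unsupported format {format!r}", str(path))
    if format == "fasta":
        text = _normalize_fasta(path)
    elif format == "fastq":
        text = _normalize_fastq(path)
    elif format == "vcf":
        text = _normalize_headers(
            path, volatile_headers or VOLATILE_VCF_HEADERS)
    elif format == "sam":
        text = _normalize_headers(
            path, volatile_headers or VOLATILE_SAM_HEADERS)
    else:
        text = _normalize_table(path, volatile_columns, delimiter or ",")
    return hashlib.md5(text.encode("utf-8")).hexdigest()


def _normalize_fasta(path: Path) -> str:
    with _open_text(path) as fh:
        records = [(r.id, str(r.seq).upper()) for r in SeqIO.parse(fh, "fasta")]
    records.sort(key=lambda t: t[0])
    out = []
    for rid, seq in records:
        out.append(f">{rid}")
        for i in range(0, len(seq), FASTA_WRAP):
            out.append(seq[i:i + FASTA_WRAP])
        if not seq:
            out.append("")
    return "\n".join(out) + "\n" if out else ""


def _normalize_fastq(path: Path) -> str:
    summary = summarize(path, "fastq")  # validates structure
    del summary
    with _open_text(path) as fh:
        lines = fh.read().splitlines()
    if lines and not lines[-1].strip():
        lines.pop()
    out = []
    for i in range(0, len(lines), 4):
        out.append(lines[i + 1])  # sequence
        out.append(lines[i + 3])  # quality
    return "\n".join(out) + "\n" if out else ""


def _normalize_headers(path: Path, volatile: tuple[str, ...]) -> str:
    with _open_text(path) as fh:
        lines = fh.read().splitlines()
    kept = [ln for ln in lines
            if not any(ln.startswith(prefix) for prefix in volatile)]
    return "\n".join(kept) + "\n" if kept else ""


def _normalize_table(path: Path, volatile_columns: tuple[str, ...],
                     delimiter: str) -> str:
    with _open_text(path) as fh:
        rows = list(csv.reader(fh, delimiter=delimiter))
    if not rows:
        return ""
    columns = rows[0]
    masked_idx = {i for i, name in enumerate(columns)
                  if name in volatile_columns}
    out_rows = [columns]
    for row in rows[1:]:
        out_rows.append([
            "<masked>" if i in masked_idx else cell
            for i, cell in enumerate(row)])
    buf = io.StringIO()
    csv.writer(buf, delimiter=delimiter, lineterminator="\n").writerows(out_rows)
    return buf.getvalue()
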
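"""Result aggregation and machine-readable report writers (JUnit/TAP/CSV)."""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from xml.etree import ElementTree as ET

from pipetest.model import TestResult


@dataclass
class RunReport:
    results: list[TestResult] = field(default_factory=list)
    started_at: str = ""
    duration_s: float = 0.0

    def __post_init__(self):
        if not self.started_at:
            self.started_at = datetime.now(timezone.utc).isoformat(
                timespec="seconds")

    @property
    def totals(self) -> dict[str, int]:
        return {
            "tests": len(self.results),
            "passed": sum(r.status == "passed" for r in self.results),
            "failed": sum(r.status == "failed" for r in self.results),
            "errored": sum(r.status == "errored" for r in self.results),
            "skipped": sum(r.status == "skipped" for r in self.results),
        }

    @property
    def ok(self) -> bool:
        t = self.totals
        return t["failed"] == 0 and t["errored"] == 0

    @property
    def exit_code(self) -> int:
        return 0 if self.ok else 1


def write_report(report: RunReport, format: str, path: str | Path) -> Path:
    """Write the report in ``junit``, ``tap`` or ``csv`` form."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if format == "junit":
        _write_junit(report, path)
    elif format == "tap":
        path.write_text(render_tap(report))
    elif format == "csv":
        _write_csv(report, path)
    else:
        raise ValueError(f"unknown report format {format!r}")
    return path


def _failure_message(result: TestResult) -> str:
    parts = [f"{src}: {msg}" for src, msg in result.failures]
    for ev in result.snapshot_events:
        if ev.event == "mismatched":
            parts.append(f"snapshot {ev.key!r} mismatched")
    if result.message:
        parts.append(result.message)
    return "; ".join(parts)


def _write_junit(report: RunReport, path: Path) -> None:
    totals = report.totals
    root = ET.Element("testsuites", {
        "tests": str(totals["tests"]),
        "failures": str(totals["failed"]),
        "errors": str(totals["errored"]),
        "time": f"{report.duration_s:.3f}",
    })
    by_suite: dict[str, list[TestResult]] = {}
    for r in report.results:
        by_suite.setdefault(r.suite_path, []).append(r)
    for suite_path in sorted(by_suite):
        results = by_suite[suite_path]
        el = ET.SubElement(root, "testsuite", {
            "name": suite_path,
            "tests": str(len(results)),
            "failures": str(sum(r.status == "failed" for r in results)),
            "errors": str(sum(r.status == "errored" for r in results)),
            "skipped": str(sum(r.status == "skipped" for r in results)),
            "time": f"{sum(r.duration_s for r in results):.3f}",
            "timestamp": report.started_at,
        })
        for r in results:
            case = ET.SubElement(el, "testcase", {
                "classname": suite_path,
                "name": r.case_name,
                "time": f"{r.duration_s:.3f}",
            })
            if r.status == "failed":
                fail = ET.SubElement(case, "failure",
                                     {"message": _failure_message(r)})
                fail.text = "\n".join(
                    f"assertion: {src}\n{msg}" for src, msg in r.failures)
            elif r.status == "errored":
                ET.SubElement(case, "error",
                              {"message": r.message or _failure_message(r)})
            elif r.status == "skipped":
                ET.SubElement(case, "skipped", {"message": r.message})
    tree = ET.ElementTree(root)
    ET.indent(tree)
    tree.write(path, encoding="unicode", xml_declaration=True)


def render_tap(report: RunReport) -> str:
    lines = ["TAP version 13", f"1..{len(report.results)}"]
    for i, r in enumerate(report.results, start=1):
        ident = f"{r.suite_path}/{r.case_name}"
        if r.status == "passed":
            lines.append(f"ok {i} - {ident}")
        elif r.status == "skipped":
            lines.append(f"ok {i} - {ident} # SKIP {r.message}")
        else:
            lines.append(f"not ok {i} - {ident}")
            msg = _failure_message(r).replace("'", "")
            lines.append("  ---")
            lines.append(f"  message: '{msg}'")
            lines.append(f"  severity: {r.status}")
            lines.append("  ...")
    return "\n".join(lines) + "\n"


def _write_csv(report: RunReport, path: Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["suite", "test", "status", "duration_s", "message"])
        for r in report.results:
            writer.writerow([
                r.suite_path, r.case_name, r.status,
                f"{r.duration_s:.3f}", _failure_message(r),
            ])
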
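"""Corpus reading/writing and raw-report parsing.

A corpus is either a JSON-lines file (one ``{"case_id", "text"}`` object
per line) or a directory of ``.txt`` files (one report per file, the file
stem as case id).  Malformed records are collected as record-level errors
and the run continues; an unreadable path is fatal.

``parse_report`` is total and deterministic: every raw report yields either
a :class:`CaseRecord` or a :class:`ParseFailure` with a reason.
"""

from __future__ import annotations

import csv
import json
import re
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .simulate import PLACEHOLDER_CYTOLOGY, PLACEHOLDER_SURGICAL
from .types import (
    CaseRecord,
    CaseTruth,
    CaseType,
    History,
    HistoryStatusRaw,
    ParseFailure,
    RawReport,
    record_fields,
)

__all__ = [
    "read_corpus", "write_corpus", "parse_report", "parse_corpus",
    "write_table", "read_table", "write_truth", "read_truth",
]


# ---------------------------------------------------------------------------
# Corpus I/O

def write_corpus(reports: Iterable[RawReport], path: str | Path) -> int:
    """Write reports as JSON-lines; returns the number written."""
    n = 0
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for r in reports:
            fh.write(json.dumps({"case_id": r.case_id, "text": r.text},
                                sort_keys=True, ensure_ascii=False))
            fh.write("\n")
            n += 1
    return n


def read_corpus(path: str | Path,
                errors: list[ParseFailure] | None = None) -> list[RawReport]:
    """Read a corpus from a JSON-lines file or a directory of .txt files.

    Every readable report is yielded exactly once, in stable order (file
    order for JSONL, sorted filename order for a directory).  Malformed
    records are appended to ``errors`` (if provided) and skipped; a missing
    or unreadable path raises.
    """
    path = Path(path)
    if errors is None:
        errors = []
    reports: list[RawReport] = []
    seen: set[str] = set()
    if path.is_dir():
        for f in sorted(path.glob("*.txt")):
            _add_report(reports, seen, errors, f.stem,
                        f.read_text(encoding="utf-8"))
        return reports
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                obj = json.loads(line)
                case_id, text = obj["case_id"], obj["text"]
                if not isinstance(case_id, str) or not isinstance(text, str):
                    raise TypeError("case_id and text must be strings")
            except Exception as exc:  # malformed line: collect and continue
                errors.append(ParseFailure(case_id=f"line {lineno}",
                                           reason=f"malformed record: {exc}"))
                continue
            _add_report(reports, seen, errors, case_id, text)
    return reports


def _add_report(reports, seen, errors, case_id: str, text: str) -> None:
    if case_id in seen:
        errors.append(ParseFailure(case_id=case_id, reason="duplicate case_id"))
        return
    seen.add(case_id)
    reports.append(RawReport(case_id=case_id, text=text))


# ---------------------------------------------------------------------------
# Report parsing

_SINGLE_FIELDS = {"ACCESSION", "HOSPITAL SITE", "REQUESTING PHYSICIAN",
                  "BLOCKS", "WORKLOAD UNITS"}
_SECTION_FIELDS = {"SOURCE OF SPECIMEN", "CLINICAL HISTORY"}
_HEADER_RE = re.compile(r"^([A-Za-z][A-Za-z ]*?):\s*(.*)$")
_ACCESSION_RE = re.compile(r"^([SCsc])(\d{2})-\d+$")


def _split_fields(text: str) -> dict[str, str]:
    """Split report text into field -> body, headers case-insensitive.
    Section bodies run until the next recognized header."""
    fields: dict[str, str] = {}
    current: str | None = None
    body: list[str] = []
    for line in text.splitlines():
        m = _HEADER_RE.match(line)
        key = m.group(1).strip().upper() if m else None
        if key in _SINGLE_FIELDS or key in _SECTION_FIELDS:
            if current is not None:
                fields[current] = "\n".join(body)
            rest = m.group(2)
            if key in _SINGLE_FIELDS:
                fields[key] = rest
                current, body = None, []
            else:
                current, body = key, ([rest] if rest else [])
        elif current is not None:
            body.append(line)
    if current is not None:
        fields[current] = "\n".join(body)
    return fields


def _history_status(fields: dict[str, str]) -> History:
    if "CLINICAL HISTORY" not in fields:
        return History(status_raw=HistoryStatusRaw.SECTION_MISSING.value)
    body = fields["CLINICAL HISTORY"].strip()
    lowered = body.lower()
    if lowered == PLACEHOLDER_SURGICAL.lower():
        return History(status_raw=HistoryStatusRaw.PLACEHOLDER_SURGICAL.value)
    if lowered == PLACEHOLDER_CYTOLOGY.lower():
        return History(status_raw=HistoryStatusRaw.PLACEHOLDER_CYTOLOGY.value)
    if not body:  # zero non-whitespace characters
        return History(status_raw=HistoryStatusRaw.EMPTY.value)
    return History(status_raw=HistoryStatusRaw.TEXT.value, text=body)


def parse_report(report: RawReport) -> CaseRecord | ParseFailure:
    """Parse one raw report into a structured case record.

    The accession identifier encodes case type (S=surgical, C=cytology) and
    the two-digit accession year (interpreted in 20xx).  A report lacking a
    parseable accession or a requesting-physician header is returned as a
    :class:`ParseFailure`.
    """
    fields = _split_fields(report.text)
    accession = fields.get("ACCESSION", "").strip() or report.case_id.strip()
    m = _ACCESSION_RE.match(accession)
    if not m:
        return ParseFailure(case_id=report.case_id,
                            reason=f"unparseable accession {accession!r}")
    if "REQUESTING PHYSICIAN" not in fields or not fields["REQUESTING PHYSICIAN"].strip():
        return ParseFailure(case_id=report.case_id,
                            reason="missing requesting-physician header")
    case_type = (CaseType.CYTOLOGY if m.group(1).upper() == "C"
                 else CaseType.SURGICAL)
    year = 2000 + int(m.group(2))
    try:
        blocks = int(fields.get("BLOCKS", "0").strip() or 0)
    except ValueError:
        blocks = 0
    try:
        workload = float(fields.get("WORKLOAD UNITS", "0").strip() or 0.0)
    except ValueError:
        workload = 0.0
    return CaseRecord(
        case_id=accession,
        year=year,
        site=fields.get("HOSPITAL SITE", "").strip(),
        sps_code=fields["REQUESTING PHYSICIAN"].strip(),
        case_type=case_type.value,
        history=_history_status(fields),
        specimen_source=fields.get("SOURCE OF SPECIMEN", "").strip(),
        blocks=max(blocks, 0),
        workload_units=max(workload, 0.0),
    )


def parse_corpus(
    reports: Sequence[RawReport],
) -> tuple[list[CaseRecord], list[ParseFailure]]:
    """Parse every report, collecting failures rather than raising."""
    records: list[CaseRecord] = []
    failures: list[ParseFailure] = []
    for r in reports:
        out = parse_report(r)
        (failures if isinstance(out, ParseFailure) else records).append(out)
    return records, failures


# ---------------------------------------------------------------------------
# Tabular I/O (lossless CSV round trip, UTF-8, RFC-4180 quoting)

def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False, encoding="utf-8",
              quoting=csv.QUOTE_MINIMAL, lineterminator="\n")


def read_table(path: str | Path) -> pd.DataFrame:
    # keep empty strings as "" rather than NaN so text columns round-trip
    return pd.read_csv(path, encoding="utf-8", keep_default_na=False,
                       na_values=[])


_TRUTH_COLUMNS = record_fields(CaseTruth)


def write_truth(truths: Sequence[CaseTruth], path: str | Path) -> None:
    """Ground truth as CSV, one row per case."""
    df = pd.DataFrame(
        [[getattr(t, c) for c in _TRUTH_COLUMNS] for t in truths],
        columns=_TRUTH_COLUMNS,
    )
    write_table(df, path)


def read_truth(path: str | Path) -> pd.DataFrame:
    return read_table(path)
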
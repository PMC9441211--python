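"""Core record types shared across the pipeline.

The unit of analysis is one accessioned pathology case.  A raw report is
parsed into a :class:`CaseRecord`, classified into a :class:`ClassifiedCase`,
and aggregated into submitting-physician/surgeon (SPS) profiles and stratified
rate tables.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, fields


class CaseType(str, enum.Enum):
    SURGICAL = "surgical"
    CYTOLOGY = "cytology"


class HistoryState(str, enum.Enum):
    """Ground-truth state of the clinical-history field for a generated case."""

    PRESENT = "present"
    PLACEHOLDER = "placeholder"
    ABSENT = "absent"


class HistoryStatusRaw(str, enum.Enum):
    """Raw parse result for the clinical-history section of one report."""

    TEXT = "text"
    PLACEHOLDER_SURGICAL = "placeholder_surgical"
    PLACEHOLDER_CYTOLOGY = "placeholder_cytology"
    EMPTY = "empty"
    SECTION_MISSING = "section_missing"


class Completeness(str, enum.Enum):
    """Clinical-history completeness status of one case.

    CHP: clinical history present (any information supplied).
    NAOR: a standardized placeholder phrase stood in for the history
    ("not available on requisition" / "clinical history not provided").
    NIA: no information available — the history section was empty or the
    report had no history section at all.
    NAOR and NIA together form the "incomplete" category.
    """

    CHP = "CHP"
    NAOR = "NAOR"
    NIA = "NIA"

    @property
    def incomplete(self) -> bool:
        return self is not Completeness.CHP


INTENTS = ("biopsy", "resection", "ambiguous", "unknown")


@dataclass(frozen=True, slots=True)
class RawReport:
    """One report as stored in the laboratory information system: an
    accession identifier plus the full report text."""

    case_id: str
    text: str


@dataclass(slots=True)
class CaseTruth:
    """Ground truth for one synthetic case, mirroring the classification
    targets the pipeline must recover."""

    case_id: str
    year: int
    site: str
    sps_code: str
    case_type: str  # CaseType value
    true_tissue_group: str
    true_intent: str
    history_state: str  # HistoryState value
    history_text: str
    blocks: int
    workload_units: float

    def __post_init__(self) -> None:
        if (self.history_state == HistoryState.PRESENT.value) != bool(self.history_text):
            raise ValueError("history_text must be nonempty iff history_state='present'")
        if self.blocks < 1:
            raise ValueError("blocks must be a positive integer")
        if self.workload_units <= 0:
            raise ValueError("workload_units must be positive")


@dataclass(slots=True)
class History:
    status_raw: str  # HistoryStatusRaw value
    text: str = ""


@dataclass(slots=True)
class CaseRecord:
    """Structured fields parsed from one raw report."""

    case_id: str
    year: int
    site: str
    sps_code: str
    case_type: str
    history: History
    specimen_source: str = ""
    blocks: int = 0
    workload_units: float = 0.0

    def __post_init__(self) -> None:
        if not (1990 <= self.year <= 2100):
            raise ValueError(f"year {self.year} outside plausible window 1990-2100")
        if (self.history.status_raw == HistoryStatusRaw.TEXT.value) != bool(self.history.text):
            raise ValueError("history text must be nonempty iff status_raw='text'")


@dataclass(slots=True)
class ParseFailure:
    """A report that could not be parsed, with the reason; collected rather
    than fatal so a run continues past malformed records."""

    case_id: str
    reason: str


@dataclass(slots=True)
class ClassifiedCase:
    """A parsed case plus the three classifier outputs."""

    case_id: str
    year: int
    site: str
    sps_code: str
    case_type: str
    history_status_raw: str
    history_text: str
    specimen_source: str
    blocks: int
    workload_units: float
    status: str  # Completeness value
    tissue_group: str
    intent: str

    @property
    def is_chp(self) -> bool:
        return self.status == Completeness.CHP.value


@dataclass(slots=True)
class SpsProfile:
    """Volume and completeness profile of one submitting physician/surgeon."""

    sps_code: str
    assigned_site: str
    n_cases: int
    n_chp: int

    @property
    def chp_rate(self) -> float:
        return self.n_chp / self.n_cases

    def __post_init__(self) -> None:
        if self.n_cases < 1:
            raise ValueError("n_cases must be positive")
        if not 0 <= self.n_chp <= self.n_cases:
            raise ValueError("n_chp must lie in [0, n_cases]")


def record_fields(cls) -> list[str]:
    """Names of the dataclass fields of ``cls`` in declaration order."""
    return [f.name for f in fields(cls)]
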
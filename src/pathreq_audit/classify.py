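"""Rule-based case classifiers.

Three deterministic classifiers, applied to every parsed case:

* **Completeness** — CHP / NAOR / NIA.  A case whose clinical-history
  section holds a standardized placeholder phrase is NAOR; an empty or
  missing history section is NIA; any other (nonempty) history text is CHP.
  NAOR and NIA together are "incomplete".
* **Tissue group** — dictionary term matching on the source-of-specimen
  text, collapsed to a single group by a precedence hierarchy; cases with
  no match fall back to "Unknown" (source text retrieved) or "Unclassified"
  (no source text found).  Cytology accessions (C-prefix) are Cytology
  regardless of dictionary matches.
* **Specimen intent** — biopsy / resection / ambiguous / unknown, by string
  matching on the specimen description.
"""

from __future__ import annotations

import re
from typing import Iterable, Sequence

from .lexicon import (
    AMBIGUOUS_TERMS,
    BIOPSY_TERMS,
    ECTOMY_SUFFIX_RE,
    RESECTION_TERMS,
    TissueDictionary,
    UNCLASSIFIED,
    UNKNOWN,
    default_dictionary,
)
from .types import (
    CaseRecord,
    CaseType,
    ClassifiedCase,
    Completeness,
    HistoryStatusRaw,
)

__all__ = [
    "classify_completeness",
    "match_tissue_terms",
    "assign_tissue_group",
    "classify_intent",
    "classify_case",
    "classify_cases",
]


def classify_completeness(rec: CaseRecord) -> Completeness:
    """Map a parsed case's raw history status to CHP / NAOR / NIA.

    Either placeholder phrase yields NAOR irrespective of case type: the
    phrase itself, not the accession type, signals that no history was
    supplied.
    """
    raw = rec.history.status_raw
    if raw in (
        HistoryStatusRaw.PLACEHOLDER_SURGICAL.value,
        HistoryStatusRaw.PLACEHOLDER_CYTOLOGY.value,
    ):
        return Completeness.NAOR
    if raw in (HistoryStatusRaw.EMPTY.value, HistoryStatusRaw.SECTION_MISSING.value):
        return Completeness.NIA
    return Completeness.CHP


def match_tissue_terms(
    source_text: str, dictionary: TissueDictionary | None = None
) -> set[str]:
    """All tissue groups with at least one dictionary term occurring in
    ``source_text`` (case-insensitive, word-boundary).  May be empty."""
    if dictionary is None:
        dictionary = default_dictionary()
    text = source_text.lower()
    found: set[str] = set()
    for pattern, group in dictionary.iter_patterns():
        if group not in found and pattern.search(text):
            found.add(group)
    return found


def assign_tissue_group(
    matches: Iterable[str],
    source_present: bool,
    dictionary: TissueDictionary | None = None,
) -> str:
    """Collapse a match set to one group via the precedence hierarchy.

    Empty match set falls back to "Unknown" when source text was retrieved,
    "Unclassified" when it was not.
    """
    if dictionary is None:
        dictionary = default_dictionary()
    matches = set(matches)
    if matches:
        return min(matches, key=dictionary.rank)
    return UNKNOWN if source_present else UNCLASSIFIED


_BIOPSY_RE = re.compile(
    "|".join(r"\b" + re.escape(t) + r"\b" for t in BIOPSY_TERMS)
)
_RESECTION_RE = re.compile(
    "|".join(r"\b" + re.escape(t) + r"\b" for t in RESECTION_TERMS)
)
_AMBIGUOUS_RE = re.compile(
    "|".join(r"\b" + re.escape(t) + r"\b" for t in AMBIGUOUS_TERMS)
)


def classify_intent(specimen_text: str) -> str:
    """Classify the specimen description into one of four mutually exclusive
    intent categories: biopsy, resection, ambiguous, unknown.

    Explicitly ambiguous phrases ("excisional biopsy") are checked first;
    then the presence of biopsy vs resection cues decides, with both cue
    classes present also yielding "ambiguous".  Text with no procedure cue,
    or no text at all, is "unknown".
    """
    text = specimen_text.lower()
    if not text.strip():
        return "unknown"
    if _AMBIGUOUS_RE.search(text):
        return "ambiguous"
    biopsy = bool(_BIOPSY_RE.search(text))
    resection = bool(_RESECTION_RE.search(text)) or bool(ECTOMY_SUFFIX_RE.search(text))
    if biopsy and resection:
        return "ambiguous"
    if biopsy:
        return "biopsy"
    if resection:
        return "resection"
    return "unknown"


def classify_case(
    rec: CaseRecord, dictionary: TissueDictionary | None = None
) -> ClassifiedCase:
    """Apply all three classifiers to one parsed case."""
    if dictionary is None:
        dictionary = default_dictionary()
    status = classify_completeness(rec)
    source_present = bool(rec.specimen_source.strip())
    if rec.case_type == CaseType.CYTOLOGY.value:
        # Cytology is decided at accession level (C-prefix); the dictionary
        # only corroborates it.
        group = "Cytology"
    else:
        matches = match_tissue_terms(rec.specimen_source, dictionary)
        matches.discard("Cytology")  # surgical accessions are never Cytology
        group = assign_tissue_group(matches, source_present, dictionary)
    intent = classify_intent(rec.specimen_source)
    return ClassifiedCase(
        case_id=rec.case_id,
        year=rec.year,
        site=rec.site,
        sps_code=rec.sps_code,
        case_type=rec.case_type,
        history_status_raw=rec.history.status_raw,
        history_text=rec.history.text,
        specimen_source=rec.specimen_source,
        blocks=rec.blocks,
        workload_units=rec.workload_units,
        status=status.value,
        tissue_group=group,
        intent=intent,
    )


def classify_cases(
    records: Sequence[CaseRecord], dictionary: TissueDictionary | None = None
) -> list[ClassifiedCase]:
    if dictionary is None:
        dictionary = default_dictionary()
    return [classify_case(r, dictionary) for r in records]
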
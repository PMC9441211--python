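"""Seeded synthetic pathology-report corpus generator.

Emulates the text conventions of a regional laboratory information system:
an accession identifier encoding year and case type ("S{yy}-{seq}" surgical,
"C{yy}-{seq}" cytology), a hospital-site and requesting-physician header, a
SOURCE OF SPECIMEN section, and a CLINICAL HISTORY section that is populated,
holds a standardized placeholder phrase, or is empty/missing.  Whether a
history is provided is a Bernoulli draw whose log-odds are additive in site,
tissue group, intent, individual physician, and year effects.

Missing histories are encoded per the regime in force: before the cutover
year the history section is simply empty (or omitted); from the cutover year
on, a placeholder phrase — "Not available on requisition" for surgical
cases, "Clinical history not provided" for cytology cases — stands in for
the missing history (at the configured adoption rate).

Reproducibility: each case draws from its own substream
``default_rng([seed, case_index])``; the history-provision uniform is the
first draw of the substream, so it can be replayed independently of the
rest of the generative model.  Gynecologic cytopathology is never
generated; cytology cases are non-gynecologic.
"""

from __future__ import annotations

from bisect import bisect_right
from itertools import accumulate
from typing import Sequence

import numpy as np

from .config import CohortConfig
from .types import CaseTruth, CaseType, HistoryState, RawReport

__all__ = [
    "PLACEHOLDER_SURGICAL",
    "PLACEHOLDER_CYTOLOGY",
    "generate_corpus",
    "render_report",
    "RENDER_SOURCE_TERMS",
]

PLACEHOLDER_SURGICAL = "Not available on requisition"
PLACEHOLDER_CYTOLOGY = "Clinical history not provided"

#: Source-of-specimen wordings used when rendering a case of each tissue
#: group.  Each phrase contains exactly one dictionary term, for its own
#: group, and no specimen-intent cue (property-tested), so a rendered case
#: is classifiable unambiguously.  "Unknown" wordings contain no dictionary
#: term at all; "Unclassified" cases omit the source section entirely.
RENDER_SOURCE_TERMS: dict[str, tuple[str, ...]] = {
    "Cytology": ("pleural fluid", "sputum", "fine needle aspirate",
                 "cerebrospinal fluid", "cyst fluid"),
    "Fetus": ("products of conception", "fetus"),
    "Placenta": ("placenta", "umbilical cord"),
    "Lymph node": ("sentinel node", "nodal tissue"),
    "Hematologic": ("spleen", "thymus"),
    "Neurologic": ("dura", "spinal cord", "cerebellum"),
    "Soft tissue": ("fascia", "tendon", "lipoma"),
    "Breast": ("breast", "nipple"),
    "Gynecologic": ("endometrium", "cervix", "ovary", "myometrium"),
    "Urology": ("prostate", "bladder", "kidney"),
    "Pulmonary": ("lung", "trachea", "carina"),
    "CVS": ("aortic valve", "myocardium", "temporal artery"),
    "Endocrine": ("thyroid", "adrenal", "parathyroid"),
    "Head and neck": ("tonsil", "tongue", "parotid", "turbinate"),
    "Gastrointestinal": ("colon", "stomach", "appendix", "gallbladder",
                         "sigmoid", "duodenum"),
    "Skin": ("skin", "nevus", "keratosis"),
    "Miscellaneous": ("femur", "rib", "hernia sac"),
    "Unknown": ("specimen received in formalin", "tissue, site not stated",
                "labelled lesion"),
}

#: Intent-bearing phrases appended to the source wording.  "unknown" intent
#: renders no procedure phrase at all.
RENDER_INTENT_TERMS: dict[str, tuple[str, ...]] = {
    "biopsy": ("needle core biopsy", "punch biopsy", "biopsy", "curettage"),
    "resection": ("resection", "excision", "resection specimen"),
    "ambiguous": ("excisional biopsy", "polypectomy"),
    "unknown": (),
}

_HISTORY_PHRASES = (
    "rectal mass", "rule out malignancy", "anemia, melena", "screening",
    "weight loss, night sweats", "mass lesion", "follow-up of dysplasia",
    "pigmented lesion, changing", "history of carcinoma", "obstruction",
    "incidental finding on imaging", "elevated tumour markers",
    "?lymphoma", "recurrent effusion", "chronic inflammation",
)


class _Categorical:
    """Weighted categorical sampler driven by an externally supplied
    uniform, so the per-case draw order stays explicit."""

    def __init__(self, weights: dict) -> None:
        self.labels = list(weights)
        total = float(sum(weights.values()))
        self.cum = list(accumulate(w / total for w in weights.values()))

    def pick(self, u: float):
        return self.labels[min(bisect_right(self.cum, u), len(self.labels) - 1)]


def _logistic(x: float) -> float:
    return 1.0 / (1.0 + np.exp(-x))


def generate_case(config: CohortConfig, index: int, *,
                  _samplers=None) -> CaseTruth:
    """Generate ground truth for case ``index`` from its own substream."""
    if _samplers is None:
        _samplers = _build_samplers(config)
    sps_cat, site_labels, tg_cat, intent_cat = _samplers
    rng = np.random.default_rng([config.seed, index])

    u_chp = rng.random()  # FIRST draw: history-provision uniform

    sps = config.sps_roster[sps_cat.pick(rng.random())]
    site = sps.home_site
    if len(site_labels) > 1 and rng.random() < config.cross_site_rate:
        others = [s for s in site_labels if s != sps.home_site]
        site = others[rng.integers(0, len(others))]

    years = list(config.years)
    year = years[rng.integers(0, len(years))]
    group = tg_cat.pick(rng.random())
    case_type = CaseType.CYTOLOGY if group == "Cytology" else CaseType.SURGICAL
    if case_type is CaseType.CYTOLOGY or group == "Unclassified":
        # cytology sources carry no procedure phrase; unclassified cases
        # have no source text to infer intent from
        intent = "unknown"
    else:
        intent = intent_cat.pick(rng.random())

    cx = config.complexity
    z = rng.standard_normal()
    w = rng.standard_normal()
    lam = np.exp(cx.blocks_log_intensity + cx.blocks_latent_loading * z)
    if intent == "resection":
        lam *= cx.resection_blocks_multiplier
    blocks = 1 + int(rng.poisson(lam))
    rho = cx.latent_correlation
    workload = float(
        np.exp(cx.workload_log_mean
               + cx.workload_log_sd * (rho * z + np.sqrt(1 - rho * rho) * w))
    )
    workload = round(workload, 4)

    p = _logistic(config.chp_logit(site, group, intent,
                                   sps.chp_logodds_offset, year))
    if u_chp < p:
        state = HistoryState.PRESENT
        age = int(rng.integers(18, 95))
        sex = "MF"[int(rng.integers(0, 2))]
        phrase = _HISTORY_PHRASES[int(rng.integers(0, len(_HISTORY_PHRASES)))]
        history_text = f"{age}{sex}, {phrase}"
    else:
        history_text = ""
        if (year >= config.placeholder_cutover_year
                and rng.random() < config.placeholder_adoption_rate):
            state = HistoryState.PLACEHOLDER
        else:
            state = HistoryState.ABSENT

    prefix = "C" if case_type is CaseType.CYTOLOGY else "S"
    case_id = f"{prefix}{year % 100:02d}-{index:06d}"
    return CaseTruth(
        case_id=case_id,
        year=year,
        site=site,
        sps_code=sps.sps_code,
        case_type=case_type.value,
        true_tissue_group=group,
        true_intent=intent,
        history_state=state.value,
        history_text=history_text,
        blocks=blocks,
        workload_units=workload,
    )


def _build_samplers(config: CohortConfig):
    sps_cat = _Categorical({e.sps_code: e.volume_weight for e in config.sps_roster})
    # pick() returns the code; map back to roster entries by position
    sps_cat.labels = list(range(len(config.sps_roster)))
    site_labels = list(config.sites)
    tg_cat = _Categorical(config.tissue_group_mix)
    intent_cat = _Categorical(config.intent_mix)
    return sps_cat, site_labels, tg_cat, intent_cat


def render_report(truth: CaseTruth, *, absent_renders_header: bool = True) -> RawReport:
    """Render one case as laboratory report text.

    The history section is rendered per the case's state: populated text,
    the exact placeholder phrase matching the case type, or (state=absent)
    the section header with an empty body — or no header at all when
    ``absent_renders_header`` is False.
    """
    source = _render_source(truth)
    lines = [
        f"ACCESSION: {truth.case_id}",
        f"HOSPITAL SITE: {truth.site}",
        f"REQUESTING PHYSICIAN: {truth.sps_code}",
        f"BLOCKS: {truth.blocks}",
        f"WORKLOAD UNITS: {truth.workload_units:.4f}",
    ]
    if source is not None:
        lines.append("SOURCE OF SPECIMEN:")
        lines.append(source)
    state = HistoryState(truth.history_state)
    if state is HistoryState.PRESENT:
        lines.append("CLINICAL HISTORY:")
        lines.append(truth.history_text)
    elif state is HistoryState.PLACEHOLDER:
        phrase = (PLACEHOLDER_CYTOLOGY
                  if truth.case_type == CaseType.CYTOLOGY.value
                  else PLACEHOLDER_SURGICAL)
        lines.append("CLINICAL HISTORY:")
        lines.append(phrase)
    elif absent_renders_header:
        lines.append("CLINICAL HISTORY:")
    return RawReport(case_id=truth.case_id, text="\n".join(lines) + "\n")


def _render_source(truth: CaseTruth) -> str | None:
    if truth.true_tissue_group == "Unclassified":
        return None
    # deterministic wording choice, stable in the case index encoded in the id
    seq = int(truth.case_id.split("-")[1])
    terms = RENDER_SOURCE_TERMS[truth.true_tissue_group]
    source = terms[seq % len(terms)]
    intents = RENDER_INTENT_TERMS[truth.true_intent]
    if intents:
        source = f"{source}, {intents[seq % len(intents)]}"
    return source


def generate_corpus(config: CohortConfig) -> tuple[list[RawReport], list[CaseTruth]]:
    """Generate the full corpus: exactly ``n_cases`` (report, truth) pairs.

    Identical configurations (including the seed) yield byte-identical
    corpora.
    """
    samplers = _build_samplers(config)
    truths = [generate_case(config, i, _samplers=samplers)
              for i in range(config.n_cases)]
    reports = [render_report(t, absent_renders_header=config.absent_renders_header)
               for t in truths]
    return reports, truths
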
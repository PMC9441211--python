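"""Default tissue-group dictionary, precedence hierarchy, and specimen-intent
term lists.

The tissue group is a coarse surrogate for the originating clinical
department.  A case's "source of specimen" text is matched against a
dictionary of terms (word-boundary, case-insensitive); when several groups
match, a precedence hierarchy picks a single group.  "Cytology" sits at the
top of the hierarchy so cytology specimens separate cleanly from surgical
ones; specific groups (lymph node, breast) outrank broad anatomic ones
(gastrointestinal, skin).  Both the dictionary and the hierarchy are
user-replaceable via YAML config files; everything below is the shipped
default.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import yaml

#: The two terminal fallback labels.  They are never dictionary targets:
#: "Unknown" means the source-of-specimen text was retrieved but matched no
#: dictionary term; "Unclassified" means no source-of-specimen text was found.
UNKNOWN = "Unknown"
UNCLASSIFIED = "Unclassified"

#: Precedence order, highest first.  Together with the two fallbacks this
#: yields the 19 reporting categories.
DEFAULT_HIERARCHY: tuple[str, ...] = (
    "Cytology",
    "Fetus",
    "Placenta",
    "Lymph node",
    "Hematologic",
    "Neurologic",
    "Soft tissue",
    "Breast",
    "Gynecologic",
    "Urology",
    "Pulmonary",
    "CVS",
    "Endocrine",
    "Head and neck",
    "Gastrointestinal",
    "Skin",
    "Miscellaneous",
)

#: All 19 reporting labels (hierarchy groups plus the two fallbacks).
TISSUE_GROUPS: tuple[str, ...] = DEFAULT_HIERARCHY + (UNKNOWN, UNCLASSIFIED)

# Terms are matched lowercased on word boundaries; multi-word terms match as
# literal phrases.  No stemming: "colonic" is listed separately from "colon".
DEFAULT_TERMS: dict[str, tuple[str, ...]] = {
    "Cytology": (
        "fine needle aspiration", "fine needle aspirate", "fna",
        "pleural fluid", "peritoneal fluid", "pericardial fluid",
        "ascitic fluid", "bronchial washing", "bronchial brushing",
        "bronchoalveolar lavage", "sputum", "urine cytology",
        "cerebrospinal fluid", "cyst fluid", "touch preparation",
        "cytospin",
    ),
    "Fetus": (
        "fetus", "fetal", "products of conception", "abortus", "embryo",
        "chorionic villi",
    ),
    "Placenta": (
        "placenta", "placental", "umbilical cord", "placental membranes",
    ),
    "Lymph node": (
        "lymph node", "lymph nodes", "sentinel node", "sentinel lymph node",
        "axillary node", "nodal tissue",
    ),
    "Hematologic": (
        "bone marrow", "marrow aspirate", "spleen", "splenic", "thymus",
    ),
    "Neurologic": (
        "brain", "dura", "dural", "meninges", "spinal cord", "nerve",
        "cerebellum", "cerebral",
    ),
    "Soft tissue": (
        "soft tissue", "lipoma", "fascia", "tendon", "skeletal muscle",
        "synovium", "bursa",
    ),
    "Breast": (
        "breast", "nipple", "mammary", "axillary tail",
    ),
    "Gynecologic": (
        "uterus", "uterine", "cervix", "cervical", "endometrium",
        "endometrial", "ovary", "ovarian", "fallopian tube", "vulva",
        "vulvar", "vagina", "vaginal", "myometrium", "endocervix",
        "endocervical", "adnexa",
    ),
    "Urology": (
        "prostate", "prostatic", "bladder", "kidney", "renal", "ureter",
        "urethra", "testis", "testicle", "testicular", "epididymis",
        "foreskin", "scrotum",
    ),
    "Pulmonary": (
        "lung", "pulmonary", "bronchus", "trachea", "pleura", "carina",
        "mediastinum", "mediastinal",
    ),
    "CVS": (
        "heart", "cardiac", "aortic valve", "mitral valve", "aorta",
        "temporal artery", "saphenous vein", "myocardium", "pericardium",
        "carotid",
    ),
    "Endocrine": (
        "thyroid", "parathyroid", "adrenal", "pituitary", "thyroglossal",
    ),
    "Head and neck": (
        "tonsil", "tongue", "larynx", "laryngeal", "nasal", "sinus",
        "parotid", "salivary gland", "submandibular gland", "oral mucosa",
        "mandible", "pharynx", "nasopharynx", "turbinate", "epiglottis",
        "buccal",
    ),
    "Gastrointestinal": (
        "colon", "colonic", "rectum", "rectal", "stomach", "gastric",
        "esophagus", "esophageal", "duodenum", "duodenal", "ileum",
        "jejunum", "cecum", "appendix", "liver", "hepatic", "pancreas",
        "pancreatic", "gallbladder", "bile duct", "anus", "anal",
        "small bowel", "large bowel", "terminal ileum", "sigmoid",
        "omentum", "peritoneum",
    ),
    "Skin": (
        "skin", "nevus", "keratosis", "epidermal cyst",
        "epidermal inclusion cyst", "scalp skin", "punch of skin",
    ),
    "Miscellaneous": (
        "bone", "femur", "femoral head", "tibia", "rib", "hernia sac",
        "foreign body", "joint capsule", "vertebral body", "tooth",
    ),
}

# Specimen-intent cue lists: biopsy cues, resection cues, and explicitly
# ambiguous procedure phrases (checked before the cue classes).
BIOPSY_TERMS: tuple[str, ...] = (
    "biopsy", "biopsies", "needle core", "core biopsy", "punch biopsy",
    "shave biopsy", "curettings", "curettage", "incisional biopsy",
)
RESECTION_TERMS: tuple[str, ...] = (
    "resection", "excision", "amputation", "mastectomy", "lumpectomy",
    "hemicolectomy", "colectomy", "gastrectomy", "hysterectomy",
    "nephrectomy", "prostatectomy", "thyroidectomy", "lobectomy",
    "pneumonectomy", "cholecystectomy", "appendectomy", "splenectomy",
    "orchiectomy", "salpingectomy", "oophorectomy", "cystectomy",
    "esophagectomy", "laryngectomy", "parotidectomy", "tonsillectomy",
)
AMBIGUOUS_TERMS: tuple[str, ...] = (
    "excisional biopsy", "excision biopsy", "polypectomy",
)
#: A bare token ending in "-ectomy" also counts as a resection cue even if
#: it is not in RESECTION_TERMS (standard surgical nomenclature).
ECTOMY_SUFFIX_RE = re.compile(r"\b\w+ectomy\b")


def _compile(term: str) -> re.Pattern[str]:
    return re.compile(r"\b" + re.escape(term.lower()) + r"\b")


@dataclass
class TissueDictionary:
    """Term dictionary plus precedence hierarchy for tissue-group assignment.

    ``entries`` maps a lowercased term to its group label; ``hierarchy`` is
    the full ordered precedence list (highest first).  The fallback labels
    "Unknown"/"Unclassified" are never dictionary targets.
    """

    entries: dict[str, str]
    hierarchy: tuple[str, ...] = DEFAULT_HIERARCHY
    _patterns: list[tuple[re.Pattern[str], str]] = field(
        init=False, repr=False, default_factory=list
    )
    _rank: dict[str, int] = field(init=False, repr=False, default_factory=dict)

    def __post_init__(self) -> None:
        self.hierarchy = tuple(self.hierarchy)
        if len(set(self.hierarchy)) != len(self.hierarchy):
            raise ValueError("hierarchy contains duplicate labels")
        for label in (UNKNOWN, UNCLASSIFIED):
            if label in self.hierarchy or label in self.entries.values():
                raise ValueError(f"{label!r} is a terminal fallback, not a dictionary target")
        missing = {g for g in self.entries.values() if g not in self.hierarchy}
        if missing:
            raise ValueError(f"dictionary groups absent from hierarchy: {sorted(missing)}")
        self.entries = {t.lower(): g for t, g in self.entries.items()}
        # longest terms first, so phrase matches are found before their
        # single-word substrings when iterating
        for term in sorted(self.entries, key=len, reverse=True):
            self._patterns.append((_compile(term), self.entries[term]))
        self._rank = {g: i for i, g in enumerate(self.hierarchy)}

    def rank(self, group: str) -> int:
        return self._rank[group]

    def iter_patterns(self):
        return iter(self._patterns)

    # ---- config round-trip -------------------------------------------------

    def to_config(self, path: str | Path) -> None:
        """Write the dictionary as an editable YAML config."""
        groups: dict[str, list[str]] = {g: [] for g in self.hierarchy}
        for term, group in sorted(self.entries.items()):
            groups[group].append(term)
        doc = {"hierarchy": list(self.hierarchy), "terms": groups}
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False), encoding="utf-8")

    @classmethod
    def from_config(cls, path: str | Path) -> "TissueDictionary":
        doc = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        entries = {
            term: group for group, terms in doc["terms"].items() for term in terms
        }
        return cls(entries=entries, hierarchy=tuple(doc["hierarchy"]))


def default_dictionary() -> TissueDictionary:
    """The shipped default dictionary (~150 terms over 17 groups)."""
    entries = {t: g for g, terms in DEFAULT_TERMS.items() for t in terms}
    return TissueDictionary(entries=entries, hierarchy=DEFAULT_HIERARCHY)
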
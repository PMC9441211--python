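"""The three rule-based classifiers: completeness, tissue group, intent."""

import re

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import pathreq_audit as pa
from pathreq_audit.classify import (
    assign_tissue_group,
    classify_completeness,
    classify_intent,
    match_tissue_terms,
)
from pathreq_audit.lexicon import TISSUE_GROUPS, default_dictionary
from pathreq_audit.types import CaseRecord, Completeness, History


def _rec(status_raw, text=""):
    return CaseRecord(
        case_id="S18-000001", year=2018, site="Site 1", sps_code="SPS0001",
        case_type="surgical", history=History(status_raw=status_raw, text=text),
    )


@pytest.mark.parametrize(
    "status_raw,text,expected,incomplete",
    [
        ("placeholder_surgical", "", Completeness.NAOR, True),
        ("placeholder_cytology", "", Completeness.NAOR, True),
        ("empty", "", Completeness.NIA, True),
        ("section_missing", "", Completeness.NIA, True),
        ("text", "?lymphoma", Completeness.CHP, False),
    ],
)
def test_completeness_mapping(status_raw, text, expected, incomplete):
    status = classify_completeness(_rec(status_raw, text))
    assert status is expected
    assert status.incomplete is incomplete


class TestTissueMatching:
    def test_single_group(self, dictionary):
        assert match_tissue_terms("colon, biopsy", dictionary) \
            == {"Gastrointestinal"}

    def test_empty_text(self, dictionary):
        assert match_tissue_terms("", dictionary) == set()

    def test_two_groups(self, dictionary):
        got = match_tissue_terms("breast mass and axillary lymph node",
                                 dictionary)
        assert got == {"Breast", "Lymph node"}

    def test_word_boundary_no_substring(self, dictionary):
        # "colonization" must not match the term "colon"
        assert match_tissue_terms("colonization of the wound", dictionary) \
            == set()

    def test_case_insensitive(self, dictionary):
        assert match_tissue_terms("BREAST", dictionary) == {"Breast"}


class TestAssignment:
    def test_hierarchy_precedence(self, dictionary):
        assert assign_tissue_group({"Breast", "Lymph node"}, True,
                                   dictionary) == "Lymph node"

    def test_unknown_when_source_present(self, dictionary):
        assert assign_tissue_group(set(), True, dictionary) == "Unknown"

    def test_unclassified_when_source_absent(self, dictionary):
        assert assign_tissue_group(set(), False, dictionary) == "Unclassified"

    def test_order_invariance(self, dictionary):
        groups = ["Skin", "Gastrointestinal", "Cytology", "Breast"]
        a = assign_tissue_group(groups, True, dictionary)
        b = assign_tissue_group(list(reversed(groups)), True, dictionary)
        c = assign_tissue_group(frozenset(groups), True, dictionary)
        assert a == b == c == "Cytology"


@pytest.mark.parametrize(
    "text,expected",
    [
        ("needle core biopsy", "biopsy"),
        ("punch biopsy of skin", "biopsy"),
        ("hemicolectomy", "resection"),
        ("wide excision", "resection"),
        ("adrenalectomy specimen", "resection"),  # -ectomy suffix rule
        ("excisional biopsy", "ambiguous"),
        ("polypectomy", "ambiguous"),
        ("biopsy followed by resection", "ambiguous"),
        ("", "unknown"),
        ("   ", "unknown"),
        ("specimen received in formalin", "unknown"),
    ],
)
def test_intent(text, expected):
    assert classify_intent(text) == expected


def _oracle_assign(text: str, dictionary) -> str:
    """Independent exhaustive-scan oracle: check every term of every group
    with its own regex, then take the hierarchy-first match."""
    text = text.lower()
    matched = []
    for group in dictionary.hierarchy:
        for term, g in dictionary.entries.items():
            if g == group and re.search(
                    r"\b" + re.escape(term) + r"\b", text):
                matched.append(group)
                break
    if matched:
        return matched[0]
    return "Unknown" if text.strip() else "Unclassified"


def _random_sources(n, seed, dictionary):
    import numpy as np
    rng = np.random.default_rng(seed)
    vocab = list(dictionary.entries) + [
        "mass", "lesion", "fragment", "tissue", "unremarkable", "of", "the",
        "specimen", "left", "right", "biopsy", "resection",
    ]
    texts = []
    for _ in range(n):
        k = int(rng.integers(0, 5))
        words = rng.choice(vocab, size=k) if k else []
        texts.append(", ".join(str(w) for w in words))
    return texts


def test_assignment_matches_bruteforce_oracle(dictionary):
    for text in _random_sources(2000, 17, dictionary):
        matches = match_tissue_terms(text, dictionary)
        got = assign_tissue_group(matches, bool(text.strip()), dictionary)
        assert got == _oracle_assign(text, dictionary), text


@settings(max_examples=100, deadline=None, derandomize=True)
@given(st.lists(st.sampled_from(sorted(default_dictionary().entries)),
                max_size=6))
def test_assignment_oracle_property(terms):
    dictionary = default_dictionary()
    text = " and ".join(terms)
    matches = match_tissue_terms(text, dictionary)
    got = assign_tissue_group(matches, bool(text.strip()), dictionary)
    assert got == _oracle_assign(text, dictionary)


class TestPartition:
    def test_every_case_classified_once(self, small_cohort):
        _, _, _, _, classified = small_cohort
        assert all(c.status in {"CHP", "NAOR", "NIA"} for c in classified)
        assert all(c.tissue_group in TISSUE_GROUPS for c in classified)
        assert all(c.intent in pa.types.INTENTS for c in classified)
        # group counts sum to corpus size
        from collections import Counter
        counts = Counter(c.tissue_group for c in classified)
        assert sum(counts.values()) == len(classified)

    def test_truth_recovery_at_least_99pct(self, small_cohort):
        _, _, truths, _, classified = small_cohort
        truth = {t.case_id: t for t in truths}
        tg_ok = sum(c.tissue_group == truth[c.case_id].true_tissue_group
                    for c in classified)
        in_ok = sum(c.intent == truth[c.case_id].true_intent
                    for c in classified)
        assert tg_ok / len(classified) >= 0.99
        assert in_ok / len(classified) >= 0.99


def test_dictionary_config_round_trip(tmp_path, dictionary):
    path = tmp_path / "dict.yaml"
    dictionary.to_config(path)
    loaded = pa.TissueDictionary.from_config(path)
    assert loaded.entries == dictionary.entries
    assert loaded.hierarchy == dictionary.hierarchy


def test_dictionary_invariants(dictionary):
    assert dictionary.hierarchy[0] == "Cytology"
    assert "Unknown" not in dictionary.hierarchy
    assert "Unclassified" not in dictionary.hierarchy
    assert len(TISSUE_GROUPS) == 19
    with pytest.raises(ValueError):
        pa.TissueDictionary(entries={"x": "Unknown"})
    with pytest.raises(ValueError):
        pa.TissueDictionary(entries={"x": "NotAGroup"})
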
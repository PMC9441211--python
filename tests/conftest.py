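import pytest

import pathreq_audit as pa

#: Mapping from the parser's raw history status to the generator's
#: ground-truth history state.
STATE_FROM_RAW = {
    "text": "present",
    "placeholder_surgical": "placeholder",
    "placeholder_cytology": "placeholder",
    "empty": "absent",
    "section_missing": "absent",
}


def zeroed_config(n_cases: int, seed: int, baseline: float, **updates):
    """A cohort whose provision probability is uniform: all site, tissue
    group, intent, year and individual offsets are zero."""
    cfg = pa.default_config(n_cases=n_cases, seed=seed)
    roster = [e.model_copy(update={"chp_logodds_offset": 0.0})
              for e in cfg.sps_roster]
    return cfg.model_copy(update={
        "baseline_chp_logodds": baseline,
        "site_effects": {},
        "tissue_group_effects": {},
        "intent_effects": {},
        "year_effects": {},
        "sps_roster": roster,
        **updates,
    })


@pytest.fixture(scope="session")
def dictionary():
    return pa.default_dictionary()


@pytest.fixture(scope="session")
def small_cohort():
    """A 2,000-case default cohort with everything computed once:
    (config, reports, truths, records, classified)."""
    cfg = pa.default_config(n_cases=2000, seed=7)
    reports, truths = pa.generate_corpus(cfg)
    records, failures = pa.parse_corpus(reports)
    assert not failures
    classified = pa.classify_cases(records)
    return cfg, reports, truths, records, classified
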
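# pathreq-audit

Audit of physician-to-pathologist communication, measured through the
clinical history supplied on pathology requisitions.

When a physician or surgeon submits a specimen to pathology, the requisition
form should carry the relevant clinical history; that free text becomes the
report's clinical-history section. In practice it is often missing, which
complicates triage, specimen handling and diagnosis. This package implements
a reproducible audit pipeline for that communication channel, aimed at
laboratory quality teams and health-services researchers: it classifies each
pathology report's history section, attributes each submitting
physician/surgeon (SPS) to a hospital site, and tabulates completeness rates
across the strata that drive them.

Because real laboratory data are confidential, the package ships a seeded
synthetic-corpus generator that emulates a regional laboratory information
system's report text, with known ground truth — so every stage of the
pipeline is testable end-to-end.

## The measurement model

Each case is assigned one **completeness status**:

- **CHP** (clinical history present) — the history section holds any text;
- **NAOR** — it holds a standardized placeholder phrase
  ("Not available on requisition" for surgical cases, "Clinical history not
  provided" for cytology cases) signalling that none was supplied;
- **NIA** (no information available) — the section is empty or absent
  (the encoding of missing history before the placeholder phrases were
  instituted in the cutover year).

NAOR ∪ NIA is "incomplete". Each case also gets a single **tissue group**
(one of 19 labels, a surrogate for the originating clinical department),
assigned by word-boundary dictionary matching on the source-of-specimen text
followed by a precedence hierarchy with Cytology at the top and
Unknown/Unclassified as terminal fallbacks; and a **specimen intent**
(biopsy / resection / ambiguous / unknown) by string matching.

Analyses follow the standard quality-indicator toolkit: stratified rate
tables (by year, site × year, tissue group, intent), per-SPS profiles with a
≥200-case volume filter, histogram and kernel-density summaries of provider
rates, Spearman rank correlation of volume against completeness, and
univariate logistic regressions

&nbsp;&nbsp;&nbsp;&nbsp;logit P(CHP) = β₀ + β₁·x

fit by IRLS, with likelihood-ratio tests against the intercept-only model.

In the generator, the probability that a history is provided is additive on
the log-odds scale: logit p = β₀ + site + tissue group + intent + year +
individual-SPS offsets, so stratum-level rates are known exactly and the
pipeline's estimates can be checked against them.

## Worked example

```python
import pathreq_audit as pa
from pathreq_audit import analytics, attribution

cfg = pa.default_config(n_cases=20_000, seed=42)
reports, truths = pa.generate_corpus(cfg)
records, failures = pa.parse_corpus(reports)
cases = pa.classify_cases(records)
df = analytics.cases_to_frame(cases)

print(f"overall CHP rate: {df['is_chp'].mean():.3f}")
print(analytics.present_rate_table(
    analytics.rate_table(df, ["site"])).to_string(index=False))
profiles = attribution.sps_profiles(cases, min_cases=200)
s = attribution.profile_summary(profiles)["chp_rate"]
print(f"{len(profiles)} SPS with >=200 cases; CHP rate "
      f"mean/median/sd/max/min = {s['mean']:.2f}/{s['median']:.2f}"
      f"/{s['sd']:.2f}/{s['max']:.2f}/{s['min']:.2f}")
```

prints

```
overall CHP rate: 0.763
  site  volume  chp  rate  fraction_of_total
Site 1    7014 4767 0.680              0.351
Site 2    7637 6285 0.823              0.382
Site 3    3888 2814 0.724              0.194
Site 4    1461 1389 0.951              0.073
26 SPS with >=200 cases; CHP rate mean/median/sd/max/min = 0.72/0.80/0.23/0.97/0.24
```

The per-site rates span the configured site effects (here roughly 0.68 to
0.95); the provider-level spread — median far above the mean, standard
deviation ~0.23 — reflects the wide individual offsets in the default
cohort: most physicians provide a history most of the time, while a low
tail rarely does.

The same pipeline is available from the shell:

```sh
pathreq-audit run --out results/ --seed 42 --n-cases 20000
```

which writes the corpus, ground truth, classified cases, all rate tables,
SPS profiles, regression results and a reproducibility manifest.

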
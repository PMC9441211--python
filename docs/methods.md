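# Methods

## The audit pipeline

The package measures one thing: whether a clinical history accompanied each
specimen submitted to a pathology laboratory, and how that completeness
varies by hospital site, submitting physician/surgeon (SPS), tissue group,
specimen intent, and year. The pipeline has five stages — synthetic corpus
generation, report parsing, rule-based classification, SPS attribution, and
analytics — each exposed as library functions and as a `pathreq-audit` CLI
subcommand.

## Completeness classification

The clinical-history section of each report is reduced to a raw status:

- exact match (case-insensitive, whole trimmed body) to a standardized
  placeholder phrase — "Not available on requisition" (surgical) or
  "Clinical history not provided" (cytology) — gives `placeholder_*`;
- a body with zero non-whitespace characters gives `empty`;
- no history header anywhere gives `section_missing`;
- anything else is `text`.

Statuses map onto CHP / NAOR / NIA: placeholder → NAOR, empty or missing →
NIA, text → CHP; NAOR ∪ NIA is "incomplete". Two deliberate choices:
whitespace-only bodies count as empty (visible content is what matters),
and either placeholder phrase triggers NAOR regardless of accession type —
the phrase, not the case type, is the signal, which makes the classifier
robust to mis-templated reports. Placeholder matching is anchored to the
whole body: a genuine history that merely *mentions* the phrase
("the history was not available on requisition today") counts as CHP.

## Tissue group

A dictionary maps lowercased terms (word-boundary, no stemming) to 17
anatomic/cytologic groups; a total-order precedence hierarchy collapses
multi-group matches to one label. Cytology sits at the top of the
hierarchy, so that cytology wording separates from surgical wording;
specific groups (Fetus, Placenta, Lymph node) outrank broad ones
(Gastrointestinal, Skin, Miscellaneous). Cases matching no term fall back
to **Unknown** when source-of-specimen text was retrieved and
**Unclassified** when it was not, giving 19 reporting categories in all.
Accession type also decides cytology membership directly: a C-prefixed
accession is Cytology whatever the dictionary says, and an S-prefixed one
never is. The dictionary (~150 terms) and hierarchy are package defaults,
replaceable via a YAML config (`TissueDictionary.from_config`); they are an
auditable, deterministic stand-in for a laboratory's in-house vocabulary,
not a clinical ontology.

Ties inside the hierarchy cannot occur (it is a total order), and the
assignment is invariant to the enumeration order of the match set — both
property-tested, including against an exhaustive per-term scan oracle.

## Specimen intent

Four mutually exclusive categories. Explicitly ambiguous phrases
("excisional biopsy", "polypectomy") are checked first; then biopsy cues
vs resection cues (a word-boundary term list plus a `-ectomy` suffix rule);
both cue classes present → ambiguous; no cue or no text → unknown.

## SPS attribution and profiling

Each SPS is assigned to the modal accession site of their cases, ties
broken by the lexicographically smallest site label (the attribution is
order-invariant). Provider-level analyses filter to SPS with at least 200
cases (configurable); summaries report mean, midpoint-median, sample
standard deviation (n−1), maximum and minimum of volume and CHP rate. A
conservation property pins the accounting: the volume-weighted mean of
per-SPS rates over all SPS equals the corpus CHP rate exactly.

## Analytics

- **Rate tables**: one row per observed stratum combination with volume,
  CHP count, rate, and fraction of total; full precision internally,
  rounded half-away-from-zero to 3 decimals only at presentation.
- **Logistic regression**: univariate fits of CHP on each predictor via
  statsmodels GLM/Binomial (IRLS, convergence tolerance 1e-8, 100-iteration
  cap), categorical predictors dummy-coded against their most frequent
  level, year and the complexity covariates continuous by default.
  Significance is the likelihood-ratio test against the intercept-only
  model. Perfect separation is flagged (warning + result flag) with
  coefficients reported from a capped BFGS fit; p-values are floored at
  the smallest positive double so they stay in (0, 1]. Each predictor is
  fit separately (univariate by design); no multiplicity correction is
  applied.
- **Volume association**: Spearman rank correlation of SPS volume vs CHP
  rate — chosen over Pearson because provider rates are bounded, heavily
  left-skewed toward 1, and tied; verified against a direct midrank
  computation.
- **Distributions**: histogram over [0, 1] (20 equal bins by default) and a
  Gaussian KDE with Silverman's-rule bandwidth, evaluated on a 512-point
  grid over [0, 1] and renormalised so its trapezoid integral is 1
  (compensating for kernel mass outside the unit interval). Degenerate
  inputs (all rates equal) fall back to a narrow σ = 0.01 bump.

## The synthetic cohort

The generator emulates the text conventions of a four-site regional
laboratory over accession years 2011–2020. Each report carries an accession
ID encoding year and case type ("S{yy}-{seq}" / "C{yy}-{seq}"; two-digit
years are read in 20xx), hospital-site and requesting-physician headers,
block count and workload units, a SOURCE OF SPECIMEN section, and a
CLINICAL HISTORY section.

**Provision model.** Whether a history is provided is Bernoulli with
logit p additive in a baseline and site, tissue-group, intent, per-year and
individual-SPS offsets. Defaults (all log-odds): baseline 1.95; site
offsets −0.75 / +0.45 / +0.05 / +2.40, spreading site rates from the low
sixties to the mid-nineties percent; tissue-group offsets spreading group
rates from roughly 60% to above 99%; intent offsets biopsy −0.30,
resection +0.10, ambiguous +0.55, unknown +0.65 (biopsies, where a history
matters most, get it least); year offsets rising gently to 2012 then
declining to −0.42 by 2020. SPS offsets are N(0, 1.4) plus −0.5 × the
SPS's log volume weight, so high-volume submitters tend weakly toward lower
rates; the case-weighted mean of that construction (≈ −0.5) is absorbed
into the baseline, leaving the overall rate near the mid-seventies percent.
Site weights 0.438/0.222/0.249/0.091 set the roster's home-site mix; 5% of
cases cross to a non-home site so modal-site attribution is exercised
rather than trivial.

**Missing-history regime.** Before the cutover year (default 2017) a
missing history renders the section header with an empty body (→ NIA); a
config flag omits the header entirely instead, since real archives contain
both. From the cutover year on, the case-type-appropriate placeholder
phrase is used at the configured adoption rate (default 1.0; lowering it
reproduces a residual NIA trickle after cutover).

**Complexity covariates.** Block count (1 + Poisson, log-link) and workload
units (log-normal) share a standard-normal latent factor (correlation 0.6),
and resections triple the block intensity. Workload units are a simulated
stand-in for a pathologist workload fee schedule, not the real tariff.
Complexity influences provision only through intent, so its marginal
association with CHP in the default cohort is weak — unlike real data,
where complexity is reported as an individually significant predictor;
passing regressions on site/tissue-group/intent/year therefore say nothing
about complexity effects in real archives.

**Reproducibility.** Every case draws from its own substream
`default_rng([seed, case_index])`, so editing a cohort's size never
reshuffles earlier cases; the provision uniform is the *first* draw of each
substream, a documented contract that lets tests replay it independently of
the rest of the generative model. Identical configurations yield
byte-identical corpora and result CSVs; the pipeline writes a manifest with
config hash, per-stage counts (read = parsed + failures = classified),
timings and output checksums.

**What the generator does not emulate**: realistic clinical language (a
small phrase bank only), PHI-like content, multi-part specimens with
conflicting tissue wordings, gynecologic cytopathology (excluded by
construction — its report format carried no history section), and seasonal
or volume trends within years. Tests passing on this corpus validate the
*pipeline machinery* — parsing, classification rules, accounting,
statistics — on text whose rendered wordings are deliberately unambiguous;
they do not validate dictionary coverage against real-world wording
variety.

## Problem sizes

Unit tests run on cohorts of a few thousand cases; the deeper checks use a
10,000-case round-trip corpus, a 100,000-case stratum-recovery corpus
(site provision probabilities configured at 0.53/0.70/0.85/0.97, estimates
required within 4 binomial SDs through the full parse+classify path), 500
null replicates of n = 2,000 for likelihood-ratio calibration with a
log-odds-ratio recovery check at n = 50,000, and a 50,000-case cohort in
`scripts/acceptance.py`.

## Known limitations

- The report dialect is invented; real LIS exports differ in layout, and
  the parser's header grammar would need extending for them.
- The shipped dictionary is small and English-only; Unknown/Unclassified
  rates on real text would be far higher than on rendered text.
- Univariate regressions only: site, SPS and tissue group are strongly
  confounded (most SPS work at one site), and no adjusted model is fit.
- The ≥200-case filter is applied to classified cases; cases lost to parse
  failure do not count toward a provider's volume.
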
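# Methods

This note records the modeling assumptions, defaults and numerical choices
behind `ctsurveil`, and what the synthetic experiments do and do not show.

## Problem setting

Each chest-CT report of a long-term (≥5-year) lung-cancer survivor is to be
classified by its *imaging indication*: routine surveillance for a second
primary or recurrence vs any other reason (symptom evaluation, metastasis
monitoring, treatment response). Time is measured in days from a fixed
origin per patient (the five-year survival anniversary); all window
arithmetic is in integer days on ISO-8601 calendar dates.

## Report NLP pipeline

Six deterministic steps: (1) section segmentation by a configurable,
case-insensitive header alias table (text before the first header is
`unassigned`; repeated headers concatenate); (2) sentence and word
tokenization by rules (hyphenated tokens like `follow-up` stay whole);
(3) coarse POS tagging into NOUN/ADJ/VERB/OTHER from function-word, verb
and adjective lists plus adjective suffixes — radiology prose is templated
enough that a rule tagger suffices for candidate selection, and it keeps
the pipeline dependency-free and reproducible; (4) a co-occurrence graph
over candidate stems (nouns/adjectives outside a stoplist), edge weight =
number of within-sentence co-occurrences inside a `window` of 3 word
positions, ranked by the stationary distribution of a damped random walk
(damping 0.85, L1 tolerance 1e-6, max 100 iterations; dangling mass is
redistributed uniformly; scores are non-negative and sum to 1);
(5) assignment of key phrases — maximal runs of top-quartile terms, chunked
to at most 3 terms — to seven concept clusters by stemmed-subsequence
matching against a versioned lexicon, ties resolved by a fixed priority
order (surveillance first); (6) the 11-entry feature vector: seven cluster
occurrence counts, surveillance-phrase and symptom-phrase presence
restricted to the indication/history section (computed by direct lexicon
matching so they do not depend on the salience cut), a comparison-statement
flag, and key phrases per 100 tokens.

Negation is not modeled. The exact composition of the feature list and the
lexicon contents are versioned defaults, replaceable from YAML/JSON without
code changes.

**Salience filtering attenuates counts.** With the default top-quartile
cut, a phrase mentioned once in a long report may not be extracted, so
cluster counts behave like salient-mention counts; this is fine for
classification but biases coefficient-recovery experiments toward zero
(classical measurement-error attenuation). Recovery experiments therefore
use the lossless configuration (`NLPConfig().lossless()`, retention
fraction 1.0), under which rendering followed by featurization provably
returns the generated counts exactly (property-tested).

## Structured features

Six months := 183 days, closed at both ends. The previous-CT interval is
binarized at ≥183 days; a first scan (no earlier CT) maps to 1 with a flag,
since the absence of a recent prior scan is the surveillance-consistent
state. ICD matching is prefix-based and dot-insensitive; the default
symptom set (R05, R07, R06.0, R04.2, R63.4) and lung-disease set (J12–J18,
J90/J91, J44) are explicit stand-ins for institutional code tables and
fully configurable. Ordering specialty is normalized into a closed
six-category set; unmapped strings become `other` with a missingness flag.

## Classifier

Maximum-likelihood logistic regression (statsmodels), with a
ridge-stabilized IRLS fallback (ε = 1e-8, numerical guard only) when the
likelihood is unbounded; quasi-separation is flagged, never reported as a
finite odds ratio. Univariate screening fits one predictor at a time;
constant columns and separation are flagged. Default selection is forward
stepwise on mean cross-validated AUC with stopping delta 0.002. Splits and
folds are patient-grouped and label-stratified (reports within a patient
are correlated). The classification threshold defaults to 0.5 with the ≥
tie rule. AUC is the tie-corrected rank statistic — proven equal to the
brute-force concordance count on every tested instance — with DeLong
intervals by default and a stratified bootstrap alternative.

## Temporal analysis

Quarter length is 365.25/4 days, giving an exact 40-column decade; a
quarter containing both indications is colored surveillance (the rarer,
analysis-critical state). Annual adherence: a surveillance scan qualifies
when the gap to its predecessor — the previous surveillance scan, or the
time origin for the first — falls in `target ± tolerance` (365 ± 92 days by
default; both configurable). Treating the origin as the first scan's
virtual predecessor makes "adherent ⇔ at least one qualifying pair" a
single consistent rule: one scan 60 days after origin does not qualify, one
scan at ~365 days does. Adherence is monotone in the tolerance.
Clustering uses average-linkage agglomeration on Hamming distance over the
40 categorical states, cut at k=2 by default; rows are canonicalized by
patient id so results are input-order invariant.

## Survival analysis

Exposure definitions: any CT, ≥1 predicted-surveillance CT, or ≥1
annual-adherent surveillance CT, each contrasted with patients who had no
CT after the origin; patients whose scans fail the definition are excluded
rather than pooled with controls. Follow-up-matched controls are drawn by
decile-stratified quota sampling from the exposed follow-up distribution
(largest-remainder allocation, nearest-stratum borrowing with a warning);
the enforced contract is that the Kolmogorov–Smirnov distance does not
increase. Propensity scores come from a logistic model on sex,
race/ethnicity, stage and histology by default (any confounder list can be
passed; the synthetic confounders stage and comorbidity should both be
included when analyzing generated data). Scores are truncated at the 1st
and 99th percentiles; weights are stabilized by the marginal exposure
prevalence. Balance is reported as weighted and unweighted standardized
mean differences with the conventional 0.1 threshold. The weighted Cox
model uses Efron tie handling and sandwich errors whenever weights differ
from one; the weighted product-limit estimator starts at 1 and steps only
at event times. External standardization uses iterative proportional
fitting (raking) to reference category margins, tolerance 0.01, weights
renormalized to the cohort size; a reference cell with zero cohort mass is
an error naming the cell. Constant dummy columns (categories absent in a
subsample) are dropped with a warning; genuinely separated propensity
models raise an error suggesting category collapsing — analyses of small
cohorts should collapse sparse race/histology levels first, as
`scripts/acceptance.py` does.

## Synthetic-EHR generator

The generator emulates a single-institution survivor cohort with a no-CT
control cohort, and is the fixed test bed for every downstream module.

* **Demographics** are drawn from margins typical of such a cohort
  (61.9% female, 52.3% White, 30.4% Asian, 50.4% stage I, 73.8%
  adenocarcinoma, …), all overridable. A synthetic comorbidity score is
  Poisson(1).
* **Exposure (surveillance engagement)** follows a logistic model in stage
  level and comorbidity (defaults: intercept 2.3, −0.5 per stage level,
  −0.4 per comorbidity point), designed to give roughly three-quarters of
  patients at least one surveillance scan and to confound exposure with
  survival.
* **Timelines.** Engaged patients receive surveillance scans with
  truncated-normal gaps (mean 365 d, sd 90 d — annual intent with clinic
  scheduling variability); the first scan is capped at 90% of follow-up so
  engagement always realizes as ≥1 surveillance scan. Other-indication
  scans arrive as a Poisson process whose rate grows with comorbidity
  (factor 1 + 0.5c) and whose base rate is set so that the surveillance
  share of an engaged patient's scans at average comorbidity equals the
  configured label prevalence (default 0.65). Patients with no post-origin
  scan are excluded from the study cohort — mirroring the usual inclusion
  criterion of at least one post-origin CT — because their no-CT status is
  outcome-dependent, unlike the separately generated control cohort.
* **Reports** are templated five-section texts. Per-cluster phrase counts
  are Poisson with indication-specific rates; each occurrence renders as
  its own sentence whose neighborhood is designed so the phrase joins the
  co-occurrence graph and multiword seeds cannot be split by chunking.
  Under conditional independence given the label, Poisson count features
  give an exactly logistic model with per-count log odds ratio
  log(λ_surv/λ_other); the default rates put the surveillance and
  follow-up cluster effects at OR 1.37 and 1.68 respectively.
* **ICD events** precede each scan inside the 183-day window, at
  indication-specific Poisson rates (symptoms 2.0 vs 0.3; lung disease 1.2
  vs 0.2); ordering specialty skews oncology for surveillance and
  emergency/inpatient for other scans.
* **Outcomes** are exponential with multiplicative effects: baseline 0.06
  events/year, modest covariate effects (0.15 per stage level and per
  comorbidity point) and the exposure effect `true_log_hr` (default
  log 0.6), administratively censored at 10 years. Covariate effects are
  deliberately modest so the marginal exposure hazard ratio differs from
  exp(true_log_hr) by well under the estimation error at the sample sizes
  used (Cox non-collapsibility is second-order here); this is the standard
  construction for weighting simulations.
* **Calibrated-scan mode** draws the label first and every feature
  conditionally independent given it, realizing the ≥6-month interval
  binary through actual prior-CT dates (200 vs 90 days) with an odds ratio
  of exactly 5.5 (0.75 vs 6/17). This makes multivariate logistic recovery
  a well-specified experiment with known coefficients; because the features
  are conditionally independent, fitting any subset leaves the remaining
  true coefficients unchanged.
* **Null mode** (`null_signal()`) equalizes every indication-dependent rate,
  so no feature carries signal; held-out AUC concentrates at 0.5.

Identical configuration and seed give byte-identical output.

**What the generator does not emulate:** real radiologist prose (templated
sentences and a small lexicon only), negated mentions, inter-annotator
noise in gold labels, informative censoring or loss to follow-up,
time-varying exposure, and correlation between a patient's successive
report texts beyond the shared indication process. Passing tests therefore
demonstrate the correctness and statistical calibration of the machinery
under the stated generative assumptions, not clinical-grade accuracy on
real reports.

## Experiment sizes and statistical checks

Test-suite experiments use the sizes at which their contracts are
statistically meaningful: coefficient recovery at n = 2000 scans × 20
seeds; variant ordering on cohorts of ~2000 reports × 20 seeds; IPTW
recovery at n = 5000 × 50 replicates; the indication-blind-vs-surveillance
attenuation contrast on cohorts of a few thousand patients so ordering
noise stays below the structural gap. The null-safety check on the
univariate screen asserts that *all* per-feature confidence intervals cover
OR = 1 simultaneously; with ten features this joint statement is evaluated
with Šidák-adjusted per-feature levels (familywise 95%), the statistically
correct form of an "every CI covers" requirement. CI-coverage assertions in
recovery experiments pool over features and seeds.

## Known limitations

* The rule-based tagger and light stemmer are tuned for English radiology
  boilerplate; unusual vocabularies need lexicon/stoplist configuration.
* Cluster counts under the default salience cut are attenuated measures of
  phrase frequency (see above).
* IPTW removes measured confounding only; the generator's confounders are
  measured by construction, so estimates on synthetic data say nothing
  about unmeasured confounding in real cohorts.
* Follow-up matching assumes administrative-style censoring; with strongly
  outcome-dependent follow-up it conditions on a post-exposure variable,
  as any follow-up-matched design does.
* No competing risks, no time-varying exposure, no second-primary-detection
  endpoint.
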
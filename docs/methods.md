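# Methods

## Scope and counting conventions

The pipeline operates on spontaneous adverse-event reports. The unit of
counting everywhere is the *deduplicated report*: a report mentioning the
same preferred term (PT) twice contributes one count (repeated terms are
collapsed at counting time), and a report is "exposed" to a drug when it
lists that drug as a primary or secondary suspect (the included role set is
configurable). The comparator for a drug–event pair is every other report
in the loaded corpus; a within-class comparator can be obtained by loading
only the study drugs' reports.

Deduplication treats two reports as duplicates when case ID, report date,
and the patient characteristics all coincide. "Patient characteristics" is
fixed as (age in years, sex, country) — the demographic fields the pipeline
carries — and the key tuple is configurable (`deduplicate(keys=...)`).
Missing compares equal to missing: two reports both silent on age can still
collapse. An optional keep-latest-version mode additionally collapses
same-case follow-up versions; it is off by default because version history
is not part of the core data model.

## Disproportionality statistics

For a 2×2 table (a, b, c, d):

- ROR = ad/bc, 95% CI `exp(ln ROR ± z·se)` with `se = √(1/a+1/b+1/c+1/d)`
  and z = 1.96 (configurable).
- PRR = `[a/(a+b)] / [c/(c+d)]`.
- Pearson chi-square `N(ad−bc)²/((a+b)(c+d)(a+c)(b+d))`, 1 df; the Yates
  variant subtracts N/2 from |ad−bc| (clipped at 0). Yates is off by
  default for screening.
- Fisher's exact two-sided p (scipy's hypergeometric implementation; the
  test suite checks it against a from-scratch enumeration).
- Information component `IC = log2((a+0.5)/(E+0.5))`, `E=(a+b)(a+c)/N`,
  with the closed-form shrinkage lower bound
  `IC025 = IC − 3.3(a+0.5)^{−1/2} − 2(a+0.5)^{−3/2}`. The +0.5 shrinkage
  keeps both finite for every table including a = 0. An exact-posterior
  formulation was considered and rejected: the closed form is the de-facto
  standard, has no tuning, and is directly testable against a
  single-expression oracle.

Zero-cell policy: statistics are computed without correction except when
a > 0 and b·c = 0, where the Haldane–Anscombe correction (add 0.5 to every
cell) keeps the estimate finite. Pairs with a = 0 are never emitted — no
co-reporting was observed — and would fail the minimum-count criterion
anyway. Degenerate requests without correction raise an explicit error
rather than returning infinities.

## Signal screening

Defaults: a ≥ 3, ROR CI lower bound > 1, IC025 > 0; a chi-square floor is
available but off (the source criteria for these screens are not fully
printed anywhere authoritative, so each is independently toggleable).
Exclusion reasons are assigned with a fixed precedence —
below_min_n → ci_includes_1 → chi2_below_threshold → ic025_nonpositive →
unmapped_soc → excluded_soc — so exactly one reason is recorded per pair;
the order runs from cheapest/most-common to the vocabulary-dependent
checks. The excluded-SOC default is the standard seven-class list of
drug-unrelated organ classes. No multiplicity adjustment enters the
screening decision (threshold-based screening is the field convention);
Bonferroni/Benjamini–Hochberg columns can be emitted for transparency.

Ranking: top-k by report count or by ROR point estimate, ties broken on
the other key (descending) then PT lexicographically, so output is total
ordered and byte-reproducible.

## SOC profiles and comparisons

Passed signals are counted per (drug, SOC); proportions are within-drug.
A SOC's share is compared across drugs on the r×2 table (in-SOC vs
not-in-SOC) with the Pearson chi-square; when any expected cell is below 5
the p-value comes instead from a seeded Monte-Carlo permutation (10,000
multivariate-hypergeometric draws at fixed margins, chi-square ordering,
add-one estimator). The <5 threshold is the textbook validity rule; a
single rule was chosen because the underlying convention (chi-square vs
exact, case by case) is not specified anywhere usable.

## Descriptives

Reports are stratified per drug by year, age group (≤18, 19–45, 46–60,
61–80, >80 on reported years), role code, indication, country, sex, and
outcome. Missing values form an explicit "null" level so counts conserve
the corpus; column percents are computed over the known levels. Indication
and country retain the ten most frequent pooled levels plus "other".
Comparisons: Pearson r×c chi-square; a Monte-Carlo Fisher exact test
(label permutation at fixed margins, conditional-probability ordering,
seeded) instead of a network algorithm — adequate at these table sizes and
trivially reproducible; one-way ANOVA on raw ages (known ages only).

## IME modelling

A report is IME-positive when any reaction PT is on the supplied IME list
(case/whitespace-insensitive). Risk factors — drug (ref leuprolide), sex
(ref female), off-label use (ref no), age group (ref 19–45) — are fitted
with binary logistic regression by maximum likelihood (statsmodels'
Newton/IRLS, 100 iterations, tol 1e-10); odds ratios are `exp(coef)` with
Wald 95% CIs, matching the symmetric-on-log-scale reporting convention.
Unknown levels are excluded listwise (per factor for univariate fits,
jointly for the multivariate fit) with counts reported. Complete
separation or non-convergence suppresses the odds ratios and sets an
explanatory message rather than reporting unstable estimates; no penalized
fallback is applied by default. Main effects only — the reported analysis
structure has no interactions.

## The synthetic generator

The generator defines the study conditions under which the pipeline is
validated; its defaults are fixed once and shared by the analysis scripts,
the tests and the acceptance script.

Mechanics per report: one study or background drug is drawn from
`drug_weights` (five study drugs summing to 0.45; eight background drugs
share the rest), demographics are drawn from per-drug categorical
distributions that mimic the study population (older male prostate-cancer
reporting for leuprolide/goserelin; young female precocious-puberty
reporting for histrelin/triptorelin; buserelin reported from Germany as a
secondary suspect), and each vocabulary PT is included independently with
its background rate. An injected association (drug D, PT E, true ROR ψ)
replaces E's inclusion probability for D-exposed reports by the p₁ solving
odds(p₁)/odds(p₀) = ψ, so the *report-level* 2×2 odds ratio equals ψ in
expectation — this is why injection is at report level rather than
reaction level. Reports that would end up with zero reactions draw one PT
from the background distribution excluding injected PTs, which preserves
the injected pairs' exactness (the filler is drug-independent, so null
pairs stay null).

IME events fire with per-report probability logistic in the planted factor
effects (baseline rate 0.15 at the reference cell; effect sizes are the
multivariate odds ratios the study design targets), and attach one PT from
the IME list. IME-listed PTs have zero background rate and injected PTs
are never IME-listed; either overlap would mix a second, factor-correlated
route into the respective planted truth and bias recovery.

Duplicates: exactly `round(duplicate_fraction · n)` finished reports are
copied verbatim. Missingness (MCAR on age, sex, country, off-label) is
applied *before* copying so duplicates stay exact on the dedup key; MCAR
is a deliberate simplification — real missingness is informative.

What the generator does not emulate: drug-name misspellings beyond
salt/case/suffix variants, reporting-wave and stimulated-reporting
dynamics, indication-confounded event rates (events are independent of
indication given drug), PT co-occurrence structure, and informative
missingness. Passing tests therefore demonstrate correctness of the
*estimators and filters* under a clean generative model, not robustness to
real-world reporting artifacts.

## Validation design and problem sizes

- 2×2 statistics vs independently coded single-expression/enumeration
  oracles on 1,000 random tables (relative 1e-10; Fisher 1e-9).
- Null calibration: 200 corpora of 20,000 reports with no injected
  associations; among drug–PT pairs with a ≥ 3 the 95% ROR CI must contain
  1 at 95% ± 2% and at most 7% may pass screening.
- Signal recovery: planted RORs 2, 5, 20 (expected co-report counts ≥ 30)
  over 100 seeds; every injected pair must pass and the geometric-mean
  estimate must lie within 10% of truth.
- IME recovery: the planted multivariate odds ratios at 50,000 reports
  over 100 replicates; aggregate (geometric-mean) estimates within 15% of
  truth with ≥ 90% CI coverage. The aggregate reading is deliberate: at
  this corpus size the smallest stratum (buserelin, 2.5% of reports)
  carries per-replicate sampling error comparable to 15%, so a
  per-replicate bound would measure sampling noise, not estimator quality.
- Dedup exactness on 100 random (n, k, seed) draws; univariate-logit
  closed-form identity on 200 random datasets; byte-level determinism of
  the full pipeline.

`scripts/acceptance.py` re-measures the same quantities at reduced
replicate counts (40 null corpora, 30 signal seeds, 20 IME replicates, 300
oracle tables) chosen to keep a single-CPU run in the low minutes while
leaving Monte-Carlo error well inside the validation margins.

## Known limitations

- The FAERS-style dialect is a structural emulation of the quarterly ASCII
  layout, not a parser for the real files (no version/sequence columns, no
  therapy/dose tables, an explicit off-label flag).
- PT→SOC mapping uses a single primary SOC per PT; SMQ/HLT/HLGT levels of
  MedDRA are out of scope, as is any licensed MedDRA content (the packaged
  60-PT vocabulary is a toy).
- Probabilistic record linkage for near-duplicates is out of scope; only
  the exact-key rule is implemented.
- The IME flag uses list membership only; regulatory seriousness outcomes
  (death, hospitalization, ...) are carried through but not merged into
  the flag, since the two definitions serve different analyses.
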
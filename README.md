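# gnrha-pv

Pharmacovigilance signal detection and risk modelling for the long-acting
gonadotropin-releasing hormone analogs (GnRHa) — leuprolide, goserelin,
histrelin, buserelin and triptorelin — on spontaneous adverse-event reports
in the style of the FDA Adverse Event Reporting System (FAERS).

The package is organised as an analysis project: the library under
`src/gnrha_pv/` implements every pipeline stage, the numbered scripts under
`analysis/` run the study end to end on synthetic corpora with known ground
truth, and `tests/` + `scripts/acceptance.py` validate each stage against
independent oracles and planted truths.

## The problem and the methods

Spontaneous reporting databases collect unsolicited reports of suspected
adverse drug reactions. Because there is no denominator of exposed
patients, safety screening works by *disproportionality*: for a drug D and
a MedDRA preferred term (PT) E, count reports in a 2×2 table

|            | E        | not E    |
|------------|----------|----------|
| **D**      | a        | b        |
| **not D**  | c        | d        |

and ask whether E is reported with D more often than expected under
independence. The package computes, per drug–PT pair:

- **ROR** = ad/bc with the 95% Wald CI `exp(ln ROR ± 1.96·√(1/a+1/b+1/c+1/d))`;
- **PRR** = `[a/(a+b)] / [c/(c+d)]`;
- Pearson **chi-square** (optional Yates correction) and **Fisher's exact
  test**;
- the BCPNN **information component** `IC = log2((a+0.5)/(E[a]+0.5))` with
  `E[a] = (a+b)(a+c)/N`, and its lower 95% credibility bound
  `IC025 = IC − 3.3(a+0.5)^−1/2 − 2(a+0.5)^−3/2`.

A pair is a **signal** when (defaults, all configurable) a ≥ 3, the ROR CI
lower bound exceeds 1, and IC025 > 0 — and its PT maps to a system organ
class (SOC) outside the standard exclusion list (general disorders and
administration site conditions; product issues; social circumstances;
investigations; injury, poisoning and procedural complications; congenital,
familial and genetic disorders; surgical and medical procedures).

Before counting, reports are deduplicated: two reports are duplicates when
case ID, report date and the patient characteristics (age, sex, country)
all coincide.

Downstream, passed signals are profiled at SOC level and compared across
drugs, and Important Medical Events (IMEs; an EMA-maintained PT list) are
modelled per report with univariate and multivariate logistic regression
(odds ratios with Wald 95% CIs against the references leuprolide, female,
on-label, age 19–45).

Real FAERS extraction is out of scope; the `synthetic_data` module
generates FAERS-like corpora in which every quantity above is planted and
therefore checkable.

## Worked example

```bash
python analysis/01_simulate.py     # corpora -> scratch/fixtures/
python analysis/03_signals.py      # signal table -> results/signals.csv
python analysis/05_ime_model.py    # OR table -> results/table1.csv
```

`03_signals.py` prints, for the 50,000-report `full` corpus (seed
20240901):

```
300 drug-PT pairs screened
    leuprolide: 1 passed signals
     goserelin: 8 passed signals
     histrelin: 0 passed signals
     buserelin: 7 passed signals
   triptorelin: 8 passed signals
planted associations:
  leuprolide / Hot flush: true ROR 2.0, estimated 2.02 [1.80, 2.27], passed=True
  goserelin / Malignant neoplasm progression: true ROR 5.0, estimated 5.42 [4.78, 6.14], passed=True
  triptorelin / Ovarian hyperstimulation syndrome: true ROR 20.0, estimated 18.81 [15.67, 22.58], passed=True
```

Each planted drug–event association is detected and its estimated ROR
brackets the planted value; the handful of additional passed signals are
IME terms, which the generator attaches preferentially to the drugs planted
with high IME risk. `05_ime_model.py` prints the side-by-side univariate /
multivariate odds-ratio table and the planted-versus-estimated comparison
for every modelled factor level.

The same operations are available as CLI subcommands
(`gnrha-pv simulate|dedup|stats|signals|soc-profile|ime-model|describe`);
`gnrha-pv signals --help` shows the file interface.

## Input dialects

- `simple_table`: one CSV, one row per case–drug–reaction, headered
  `case_id, receipt_date, age, sex, country, drug, role_code, indication,
  reaction_pt, outcome, off_label` (ISO dates, `|`-joined outcomes).
- `faers_multi_table`: a directory of `$`-delimited tables in the style of
  FAERS quarterly ASCII — `DEMO.txt`, `DRUG.txt`, `REAC.txt`, `OUTC.txt`
  sharing a `caseid` key, with FAERS age-unit codes (DEC/YR/MON/WK/DY —
  factors 10, 1, 1/12, 1/52, 1/365.25 to years), role codes PS/SS/C/I and
  outcome codes DE/HO/LT/DS/CA/RI/OT. The DEMO table carries an explicit
  `off_label` column (Y/N/blank), which real FAERS lacks.

Rows sharing a case key merge into one report; drug-name normalization maps
verbatim strings to the five study keywords by case-insensitive substring
(brand names are resolved only through a user-supplied synonym table).

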
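"""Population-characteristics summaries and cross-drug comparisons.

Reports are stratified per study drug by year, age group, role code,
indication, reporter country, sex, or outcome. Missing values form an
explicit "null" level (counts always conserve the corpus); for indication
and country only the ten most frequent pooled levels are retained, the
remainder pooled into "other". Comparisons use Pearson r x c chi-square, a
seeded Monte-Carlo Fisher exact test, or one-way ANOVA on raw ages.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as _st
from scipy.special import gammaln

from gnrha_pv.types import CaseReport, SignalCriteria, STUDY_DRUGS

STRATIFIERS = ("year", "age_group", "role_code", "indication", "country", "sex", "outcome")
_TOP_K = 10


@dataclass(frozen=True)
class StratifiedCounts:
    stratifier: str
    cells: dict  # (drug, level) -> count
    drugs: tuple[str, ...]
    levels: tuple[str, ...]

    @property
    def column_percent(self) -> dict:
        """(drug, level) -> percent of the drug's non-missing reports."""
        out = {}
        for drug in self.drugs:
            total = sum(
                v for (d, lv), v in self.cells.items() if d == drug and lv != "null"
            )
            for level in self.levels:
                if level == "null":
                    continue
                if total:
                    out[(drug, level)] = 100.0 * self.cells.get((drug, level), 0) / total
        return out

    def to_frame(self) -> pd.DataFrame:
        pct = self.column_percent
        rows = [
            {
                "drug": d,
                "level": lv,
                "count": self.cells.get((d, lv), 0),
                "percent": pct.get((d, lv), float("nan")),
            }
            for d in self.drugs
            for lv in self.levels
        ]
        return pd.DataFrame(rows)

    def matrix(self, drop_null: bool = False) -> np.ndarray:
        levels = [lv for lv in self.levels if not (drop_null and lv == "null")]
        return np.array(
            [[self.cells.get((d, lv), 0) for lv in levels] for d in self.drugs]
        )


def _study_drug_entries(report: CaseReport, drugs, roles):
    seen = []
    for d in report.drugs:
        if d.name_norm in drugs and d.role_code in roles and d.name_norm not in seen:
            seen.append(d.name_norm)
            yield d


def summarize(
    reports: Sequence[CaseReport],
    stratifier: str,
    drugs: Sequence[str] = STUDY_DRUGS,
    criteria: SignalCriteria = SignalCriteria(),
) -> StratifiedCounts:
    """Count reports per drug x level for one stratifier.

    A report listing several study drugs contributes to each drug's column;
    a report with several outcomes contributes once per outcome.
    """
    if stratifier not in STRATIFIERS:
        raise ValueError(f"unknown stratifier: {stratifier!r}")
    drugs = [d.casefold() for d in drugs]
    roles = criteria.role_codes_included
    cells: dict[tuple[str, str], int] = {}

    def bump(drug: str, level: str) -> None:
        cells[(drug, level)] = cells.get((drug, level), 0) + 1

    for r in reports:
        for entry in _study_drug_entries(r, drugs, roles):
            drug = entry.name_norm
            if stratifier == "year":
                bump(drug, str(r.receipt_date.year) if r.receipt_date else "null")
            elif stratifier == "age_group":
                g = r.age_group
                bump(drug, "null" if g == "unknown" else g)
            elif stratifier == "sex":
                bump(drug, "null" if r.sex == "unknown" else r.sex)
            elif stratifier == "country":
                bump(drug, "null" if r.country == "unknown" else r.country)
            elif stratifier == "role_code":
                bump(drug, entry.role_code)
            elif stratifier == "indication":
                bump(drug, entry.indication or "null")
            elif stratifier == "outcome":
                if r.outcomes:
                    for o in sorted(r.outcomes):
                        bump(drug, o)
                else:
                    bump(drug, "null")

    levels = sorted({lv for (_, lv) in cells})
    if stratifier in ("indication", "country") and len(levels) > _TOP_K + 1:
        pooled = {lv: 0 for lv in levels}
        for (d, lv), v in cells.items():
            pooled[lv] += v
        top = set(
            sorted(pooled, key=lambda lv: (-pooled[lv], lv))[:_TOP_K]
        )
        folded: dict[tuple[str, str], int] = {}
        for (d, lv), v in cells.items():
            key = (d, lv if lv in top else "other")
            folded[key] = folded.get(key, 0) + v
        cells = folded
        levels = sorted({lv for (_, lv) in cells})
    return StratifiedCounts(
        stratifier=stratifier,
        cells=cells,
        drugs=tuple(d for d in drugs if any(dd == d for (dd, _) in cells)),
        levels=tuple(levels),
    )


def _log_table_prob(table: np.ndarray) -> float:
    """Log conditional probability of an r x c table at fixed margins (up to
    the margin-only constant): -sum log(n_ij!)."""
    return float(-gammaln(table + 1).sum())


def compare_strata(
    counts: StratifiedCounts,
    method: str,
    reports: Sequence[CaseReport] | None = None,
    drugs: Sequence[str] = STUDY_DRUGS,
    criteria: SignalCriteria = SignalCriteria(),
    n_permutations: int = 10_000,
    seed: int = 0,
) -> float:
    """p-value for a difference in stratum composition across drugs.

    method="chi_square": Pearson r x c test on the counts matrix.
    method="fisher_mc": Monte-Carlo Fisher exact test — tables are drawn at
    the observed margins by permuting level labels against drug labels, and
    p is the fraction of draws whose conditional probability does not
    exceed the observed table's.
    method="anova": one-way F test of age_years across drugs (requires the
    raw ``reports``; only reports with a known age enter).
    """
    if method == "anova":
        if reports is None:
            raise ValueError("anova requires the raw reports")
        roles = criteria.role_codes_included
        groups = []
        for drug in (d.casefold() for d in drugs):
            ages = [
                r.age_years
                for r in reports
                if r.age_years is not None and r.has_drug(drug, roles)
            ]
            if ages:
                groups.append(ages)
        if len(groups) < 2:
            raise ValueError("anova needs at least two drugs with known ages")
        if all(len(set(g)) == 1 for g in groups) and len({g[0] for g in groups}) == 1:
            return 1.0  # zero between- and within-group variance
        return float(_st.f_oneway(*groups).pvalue)

    table = counts.matrix(drop_null=False)
    table = table[table.sum(axis=1) > 0][:, table.sum(axis=0) > 0]
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("need at least a 2x2 counts table")
    if method == "chi_square":
        return float(_st.chi2_contingency(table, correction=False).pvalue)
    if method == "fisher_mc":
        rng = np.random.default_rng(seed)
        row_margins = table.sum(axis=1)
        obs_logp = _log_table_prob(table)
        # one pooled observation per report: its level index
        level_labels = np.repeat(np.arange(table.shape[1]), table.sum(axis=0))
        hits = 0
        n_levels = table.shape[1]
        starts = np.concatenate([[0], np.cumsum(row_margins)])
        for _ in range(n_permutations):
            rng.shuffle(level_labels)
            sim = np.array(
                [
                    np.bincount(
                        level_labels[starts[i] : starts[i + 1]], minlength=n_levels
                    )
                    for i in range(table.shape[0])
                ]
            )
            if _log_table_prob(sim) <= obs_logp + 1e-9:
                hits += 1
        return (hits + 1) / (n_permutations + 1)
    raise ValueError(f"unknown method: {method!r}")
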
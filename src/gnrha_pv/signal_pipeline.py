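"""Drug-PT signal screening over a deduplicated corpus.

The counting unit is the report: a report mentioning a PT twice contributes
one count (the "repetitive" collapse), and exposure means the report lists
the drug in an included role (primary or secondary suspect by default).
Every (drug, PT) pair observed together at least once gets a
:class:`~gnrha_pv.types.SignalRecord` holding its 2x2 table, statistics and
a screening decision. Exclusion reasons are assigned with fixed precedence:
below_min_n -> ci_includes_1 -> chi2_below_threshold -> ic025_nonpositive ->
unmapped_soc -> excluded_soc; only the first failing reason is recorded.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _scipy_stats

from gnrha_pv.disprostats import signal_stat
from gnrha_pv.types import (
    CaseReport,
    ContingencyTable,
    DEFAULT_EXCLUDED_SOCS,
    EmptyExposureError,
    PtSocMap,
    SignalCriteria,
    SignalRecord,
    norm_term,
)


def _exposure_vector(reports: Sequence[CaseReport], drug: str, roles) -> np.ndarray:
    return np.fromiter(
        (r.has_drug(drug, roles) for r in reports), dtype=bool, count=len(reports)
    )


def _reaction_matrix(reports: Sequence[CaseReport]) -> tuple[np.ndarray, list[str]]:
    """Boolean reports x PTs incidence matrix; repeated PTs in one report collapse."""
    index: dict[str, int] = {}
    display: list[str] = []
    rows: list[list[int]] = []
    for r in reports:
        cols = set()
        for pt in r.reactions:
            key = norm_term(pt)
            j = index.get(key)
            if j is None:
                j = len(display)
                index[key] = j
                display.append(pt.strip())
            cols.add(j)
        rows.append(sorted(cols))
    mat = np.zeros((len(reports), len(display)), dtype=bool)
    for i, cols in enumerate(rows):
        mat[i, cols] = True
    return mat, display


def build_contingency(
    reports: Sequence[CaseReport],
    drug: str,
    pt: str,
    criteria: SignalCriteria = SignalCriteria(),
) -> ContingencyTable:
    """Report-level 2x2 table for one drug-PT pair.

    a + b + c + d always equals the corpus size. A drug with no exposed
    reports raises :class:`EmptyExposureError`.
    """
    roles = criteria.role_codes_included
    key = norm_term(pt)
    a = b = c = d = 0
    for r in reports:
        exposed = r.has_drug(drug, roles)
        has_pt = any(norm_term(x) == key for x in r.reactions)
        if exposed and has_pt:
            a += 1
        elif exposed:
            b += 1
        elif has_pt:
            c += 1
        else:
            d += 1
    if a + b == 0:
        raise EmptyExposureError(f"drug {drug!r} has no exposed reports")
    return ContingencyTable(a, b, c, d)


def detect_signals(
    reports: Sequence[CaseReport],
    drugs: Sequence[str],
    pt_soc_map: PtSocMap,
    criteria: SignalCriteria = SignalCriteria(),
    excluded_socs: Sequence[str] = DEFAULT_EXCLUDED_SOCS,
) -> list[SignalRecord]:
    """Screen every observed (drug, PT) pair and record pass/fail decisions.

    Statistics use no continuity correction except when a > 0 and b*c = 0,
    where the Haldane-Anscombe correction keeps the estimate finite; pairs
    with a = 0 are never emitted (no co-reporting observed). The comparator
    is every other report in the corpus.
    """
    n = len(reports)
    if n == 0:
        return []
    excluded = {norm_term(s) for s in excluded_socs}
    reac, pts = _reaction_matrix(reports)
    pt_margin = reac.sum(axis=0)

    records: list[SignalRecord] = []
    for drug in drugs:
        exposed = _exposure_vector(reports, drug, criteria.role_codes_included)
        n_exposed = int(exposed.sum())
        if n_exposed == 0:
            raise EmptyExposureError(f"drug {drug!r} has no exposed reports")
        a_vec = reac[exposed].sum(axis=0)
        for j in np.nonzero(a_vec)[0]:
            a = int(a_vec[j])
            b = n_exposed - a
            c = int(pt_margin[j]) - a
            d = n - a - b - c
            table = ContingencyTable(a, b, c, d)
            correction = "haldane_anscombe" if (a > 0 and b * c == 0) else "none"
            stats = signal_stat(table, correction=correction)
            soc = pt_soc_map.get(pts[j])

            reason = "none"
            if a < criteria.min_n:
                reason = "below_min_n"
            elif criteria.require_ror_low_gt1 and not (stats.ror_ci_low > 1.0):
                reason = "ci_includes_1"
            elif criteria.require_chi2_ge is not None and stats.chi2 < criteria.require_chi2_ge:
                reason = "chi2_below_threshold"
            elif criteria.require_ic025_gt0 and not (stats.ic025 > 0.0):
                reason = "ic025_nonpositive"
            elif soc is None:
                reason = "unmapped_soc"
            elif norm_term(soc) in excluded:
                reason = "excluded_soc"

            records.append(
                SignalRecord(
                    drug=drug,
                    pt=pts[j],
                    soc=soc,
                    table=table,
                    stats=stats,
                    passed=reason == "none",
                    exclusion_reason=reason,
                )
            )
    # deterministic output order: drugs as given, then frequency, then PT
    order = {d: i for i, d in enumerate(drugs)}
    records.sort(key=lambda r: (order[r.drug], -r.stats.n, r.pt))
    return records


def top_signals(
    records: Iterable[SignalRecord], by: str = "frequency", k: int = 20
) -> list[SignalRecord]:
    """Top-k passed signals by report count (``frequency``) or by ROR.

    Ties break on the other key (descending), then PT lexicographically.
    """
    passed = [r for r in records if r.passed]
    if by == "frequency":
        key = lambda r: (-r.stats.n, -r.stats.ror, r.pt)  # noqa: E731
    elif by == "ror":
        key = lambda r: (-r.stats.ror, -r.stats.n, r.pt)  # noqa: E731
    else:
        raise ValueError(f"unknown ranking key: {by!r}")
    return sorted(passed, key=key)[:k]


def signals_to_frame(records: Iterable[SignalRecord], adjust: bool = False) -> pd.DataFrame:
    """Flatten signal records to a table (the CSV schema of the `signals` command).

    With ``adjust=True``, Bonferroni and Benjamini-Hochberg adjusted
    chi-square p-values are appended for transparency; the screening
    decision itself never uses them.
    """
    rows = []
    for r in records:
        rows.append(
            {
                "drug": r.drug,
                "pt": r.pt,
                "soc": r.soc if r.soc is not None else "",
                "a": r.table.a,
                "b": r.table.b,
                "c": r.table.c,
                "d": r.table.d,
                "ror": r.stats.ror,
                "ror_low": r.stats.ror_ci_low,
                "ror_high": r.stats.ror_ci_high,
                "prr": r.stats.prr,
                "chi2": r.stats.chi2,
                "ic": r.stats.ic,
                "ic025": r.stats.ic025,
                "passed": r.passed,
                "exclusion_reason": r.exclusion_reason,
            }
        )
    df = pd.DataFrame(rows)
    if adjust and len(df):
        p = _scipy_stats.chi2.sf(df["chi2"].to_numpy(), df=1)
        m = len(p)
        df["chi2_p"] = p
        df["chi2_p_bonferroni"] = np.minimum(p * m, 1.0)
        order = np.argsort(p)
        ranked = p[order] * m / (np.arange(m) + 1)
        ranked = np.minimum.accumulate(ranked[::-1])[::-1]
        bh = np.empty(m)
        bh[order] = np.minimum(ranked, 1.0)
        df["chi2_p_bh"] = bh
    return df
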
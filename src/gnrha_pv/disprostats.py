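"""Disproportionality statistics on a report-level 2x2 table.

For a drug-event pair with cells (a, b, c, d) — a: drug & event, b: drug
only, c: event only, d: neither — the module computes:

* ROR, the reporting odds ratio ad/bc, with a 95% Wald CI on the log scale
  ``exp(ln ROR +/- z * sqrt(1/a + 1/b + 1/c + 1/d))``;
* PRR, the proportional reporting ratio ``[a/(a+b)] / [c/(c+d)]``;
* the Pearson chi-square test (optional Yates continuity correction);
* the BCPNN information component ``IC = log2((a + 0.5) / (E + 0.5))`` with
  expected count ``E = (a+b)(a+c)/N`` and its lower 95% credibility bound
  via the closed-form shrinkage approximation
  ``IC025 = IC - 3.3 (a + 0.5)^{-1/2} - 2 (a + 0.5)^{-3/2}``;
* Fisher's exact test (two-sided).

Zero cells can be handled with the Haldane-Anscombe correction (add 0.5 to
every cell); without it a degenerate denominator raises
:class:`~gnrha_pv.types.DegenerateTableError`.
"""

from __future__ import annotations

import math
from typing import NamedTuple

from scipy import stats as _st

from gnrha_pv.types import ContingencyTable, DegenerateTableError

Z95 = 1.959963984540054  # two-sided 95% normal quantile


class RorResult(NamedTuple):
    ror: float
    ci_low: float
    ci_high: float
    ci_defined: bool = True


def _cells(table: ContingencyTable, correction: str) -> tuple[float, float, float, float]:
    if correction == "haldane_anscombe":
        return table.a + 0.5, table.b + 0.5, table.c + 0.5, table.d + 0.5
    if correction == "none":
        return float(table.a), float(table.b), float(table.c), float(table.d)
    raise ValueError(f"unknown correction: {correction!r}")


def ror(table: ContingencyTable, correction: str = "none", z: float = Z95) -> RorResult:
    """Reporting odds ratio with its Wald 95% CI.

    With ``correction='none'`` and a = 0 the point estimate is 0 and the CI
    is undefined (``ci_defined=False``); b*c = 0 without correction raises
    :class:`DegenerateTableError`.
    """
    a, b, c, d = _cells(table, correction)
    if b * c == 0:
        raise DegenerateTableError(
            f"b*c = 0 in table (a={table.a}, b={table.b}, c={table.c}, d={table.d}); "
            "use the Haldane-Anscombe correction"
        )
    if a == 0:
        return RorResult(0.0, math.nan, math.nan, ci_defined=False)
    est = (a * d) / (b * c)
    if d == 0:
        return RorResult(0.0 if a == 0 else est, math.nan, math.nan, ci_defined=False)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    log_est = math.log(est)
    return RorResult(est, math.exp(log_est - z * se), math.exp(log_est + z * se))


def prr(table: ContingencyTable, correction: str = "none") -> float:
    """Proportional reporting ratio [a/(a+b)] / [c/(c+d)]."""
    a, b, c, d = _cells(table, correction)
    if a + b == 0 or c + d == 0:
        raise DegenerateTableError("empty row margin in PRR")
    if c == 0:
        raise DegenerateTableError(
            "c = 0 without correction; use the Haldane-Anscombe correction"
        )
    return (a / (a + b)) / (c / (c + d))


def chi_square(table: ContingencyTable, yates: bool = False) -> tuple[float, float]:
    """Pearson chi-square on the 2x2 table, 1 df, optional Yates correction.

    Returns (chi2, p). A zero row or column margin makes the test
    undefined and raises :class:`DegenerateTableError`.
    """
    a, b, c, d = float(table.a), float(table.b), float(table.c), float(table.d)
    n = a + b + c + d
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    if min(r1, r2, c1, c2) == 0:
        raise DegenerateTableError("zero margin: chi-square undefined")
    diff = abs(a * d - b * c)
    if yates:
        diff = max(0.0, diff - n / 2.0)
    chi2 = n * diff * diff / (r1 * r2 * c1 * c2)
    return chi2, float(_st.chi2.sf(chi2, df=1))


def information_component(table: ContingencyTable) -> tuple[float, float]:
    """BCPNN information component and its lower 95% credibility bound.

    The shrinkage (+0.5 on observed and expected) keeps both quantities
    finite for every table, including a = 0.
    """
    a = table.a
    n = table.n_total
    expected = (table.a + table.b) * (table.a + table.c) / n
    ic = math.log2((a + 0.5) / (expected + 0.5))
    shrunk = a + 0.5
    ic025 = ic - 3.3 * shrunk**-0.5 - 2.0 * shrunk**-1.5
    return ic, ic025


def fisher_exact(table: ContingencyTable) -> float:
    """Two-sided Fisher exact p: total probability of tables no more likely
    than the observed one, at fixed margins."""
    _, p = _st.fisher_exact(
        [[table.a, table.b], [table.c, table.d]], alternative="two-sided"
    )
    return float(p)


def signal_stat(table: ContingencyTable, correction: str = "none", yates: bool = False):
    """All screening statistics for one table, as a SignalStat.

    The chi-square component falls back to 0 (p undefined) on degenerate
    margins instead of raising, since screening tables with an empty margin
    are filtered out downstream anyway.
    """
    from gnrha_pv.types import SignalStat

    r = ror(table, correction=correction)
    p = prr(table, correction=correction)
    try:
        chi2, _ = chi_square(table, yates=yates)
    except DegenerateTableError:
        chi2 = 0.0
    ic, ic025 = information_component(table)
    return SignalStat(
        n=table.a,
        ror=r.ror,
        ror_ci_low=r.ci_low,
        ror_ci_high=r.ci_high,
        prr=p,
        chi2=chi2,
        ic=ic,
        ic025=ic025,
    )
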
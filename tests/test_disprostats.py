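"""2x2 disproportionality statistics against independently coded oracles.

Each statistic is checked against a separately written single-expression
(or enumeration) implementation, plus its algebraic invariants.
"""

import math

import numpy as np
import pytest
from scipy import stats as sps

from gnrha_pv.disprostats import (
    Z95,
    chi_square,
    fisher_exact,
    information_component,
    prr,
    ror,
)
from gnrha_pv.types import ContingencyTable, DegenerateTableError

# --- independent oracles -----------------------------------------------------


def oracle_ror(a, b, c, d):
    est = (a * d) / (b * c)
    half = Z95 * math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return est, est * math.exp(-half), est * math.exp(half)


def oracle_prr(a, b, c, d):
    return (a / (a + b)) / (c / (c + d))


def oracle_chi2(a, b, c, d, yates=False):
    n = a + b + c + d
    diff = abs(a * d - b * c)
    if yates:
        diff = max(0.0, diff - n / 2)
    return n * diff**2 / ((a + b) * (c + d) * (a + c) * (b + d))


def oracle_ic(a, b, c, d):
    n = a + b + c + d
    e = (a + b) * (a + c) / n
    ic = math.log2((a + 0.5) / (e + 0.5))
    return ic, ic - 3.3 * (a + 0.5) ** -0.5 - 2.0 * (a + 0.5) ** -1.5


def oracle_fisher(a, b, c, d):
    """Full hypergeometric enumeration of the two-sided p."""
    n, r1, c1 = a + b + c + d, a + b, a + c
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    pmf = {x: math.comb(r1, x) * math.comb(n - r1, c1 - x) / math.comb(n, c1) for x in range(lo, hi + 1)}
    p_obs = pmf[a]
    return sum(p for p in pmf.values() if p <= p_obs * (1 + 1e-9))


def random_tables(n, low=1, high=500, seed=0):
    rng = np.random.default_rng(seed)
    return rng.integers(low, high + 1, size=(n, 4))


# --- worked examples ---------------------------------------------------------


def test_ror_point_estimate():
    r = ror(ContingencyTable(10, 20, 30, 240))
    assert r.ror == pytest.approx(4.0)


def test_ror_symmetric_table_ci_contains_1():
    r = ror(ContingencyTable(10, 10, 10, 10))
    assert r.ror == pytest.approx(1.0)
    assert r.ci_low < 1 < r.ci_high


def test_ror_zero_a_flags_undefined_ci():
    r = ror(ContingencyTable(0, 10, 10, 10))
    assert r.ror == 0.0 and not r.ci_defined


def test_ror_degenerate_without_correction():
    with pytest.raises(DegenerateTableError):
        ror(ContingencyTable(5, 0, 10, 10))
    corrected = ror(ContingencyTable(5, 0, 10, 10), correction="haldane_anscombe")
    assert math.isfinite(corrected.ror) and corrected.ror > 0


def test_prr_point_estimate():
    assert prr(ContingencyTable(10, 20, 30, 240)) == pytest.approx(3.0)
    assert prr(ContingencyTable(10, 10, 10, 10)) == pytest.approx(1.0)


def test_chi2_worked_example_and_independence():
    chi2, p = chi_square(ContingencyTable(20, 10, 10, 20))
    assert chi2 == pytest.approx(60 * 300**2 / 30**4)
    chi0, p0 = chi_square(ContingencyTable(10, 10, 10, 10))
    assert chi0 == pytest.approx(0.0) and p0 == pytest.approx(1.0)


def test_ic_worked_example():
    # (100, 0, 0, 100): E = 100*100/200 = 50, so observed a = 2E
    ic, ic025 = information_component(ContingencyTable(100, 0, 0, 100))
    assert ic == pytest.approx(math.log2(100.5 / 50.5), rel=1e-12)
    assert ic == pytest.approx(0.9928, abs=5e-5)
    assert ic025 == pytest.approx(ic - 3.3 / math.sqrt(100.5) - 2 / 100.5**1.5, abs=1e-9)
    assert ic025 == pytest.approx(0.662, abs=5e-4)


def test_ic_zero_at_independence_for_large_a():
    # a == E exactly: IC = log2((a+.5)/(a+.5)) = 0
    ic, _ = information_component(ContingencyTable(1000, 1000, 1000, 1000))
    assert ic == pytest.approx(0.0, abs=1e-12)


def test_fisher_worked_examples():
    assert fisher_exact(ContingencyTable(10, 10, 10, 10)) == pytest.approx(1.0)
    assert fisher_exact(ContingencyTable(1, 9, 11, 3)) == pytest.approx(
        oracle_fisher(1, 9, 11, 3), rel=1e-9
    )
    assert oracle_fisher(1, 9, 11, 3) == pytest.approx(0.00276, abs=5e-5)


# --- oracle agreement & invariants on random tables --------------------------


def test_all_statistics_match_oracles_on_random_tables():
    for a, b, c, d in random_tables(300, seed=1):
        t = ContingencyTable(a, b, c, d)
        est, lo, hi = oracle_ror(a, b, c, d)
        r = ror(t)
        assert r.ror == pytest.approx(est, rel=1e-10)
        assert r.ci_low == pytest.approx(lo, rel=1e-10)
        assert r.ci_high == pytest.approx(hi, rel=1e-10)
        assert prr(t) == pytest.approx(oracle_prr(a, b, c, d), rel=1e-10)
        for yates in (False, True):
            assert chi_square(t, yates=yates)[0] == pytest.approx(
                oracle_chi2(a, b, c, d, yates), rel=1e-10, abs=1e-12
            )
        ic, ic025 = information_component(t)
        o_ic, o_ic025 = oracle_ic(a, b, c, d)
        assert ic == pytest.approx(o_ic, rel=1e-10)
        assert ic025 == pytest.approx(o_ic025, rel=1e-10)


def test_chi2_agrees_with_scipy_contingency():
    for a, b, c, d in random_tables(50, seed=2):
        t = ContingencyTable(a, b, c, d)
        for yates in (False, True):
            res = sps.chi2_contingency([[a, b], [c, d]], correction=yates)
            chi2, p = chi_square(t, yates=yates)
            assert chi2 == pytest.approx(res.statistic, rel=1e-10, abs=1e-12)
            assert p == pytest.approx(res.pvalue, rel=1e-9, abs=1e-12)


def test_yates_never_exceeds_uncorrected():
    for a, b, c, d in random_tables(500, seed=3):
        t = ContingencyTable(a, b, c, d)
        assert chi_square(t, yates=True)[0] <= chi_square(t, yates=False)[0] + 1e-12


def test_ror_label_swap_reciprocity():
    for a, b, c, d in random_tables(200, seed=4):
        fwd = ror(ContingencyTable(a, b, c, d)).ror
        rev = ror(ContingencyTable(b, a, d, c)).ror
        assert fwd * rev == pytest.approx(1.0, rel=1e-10)


def test_ic025_increases_with_a_at_fixed_expected():
    # sweep observed counts upward while E is pinned by construction
    prev = -math.inf
    for a in np.unique(np.geomspace(1, 10_000, 60).astype(int)):
        ic, ic025 = oracle_ic_fixed_e(a, e=50.0)
        assert ic025 > prev
        prev = ic025


def oracle_ic_fixed_e(a, e):
    ic = math.log2((a + 0.5) / (e + 0.5))
    return ic, ic - 3.3 * (a + 0.5) ** -0.5 - 2.0 * (a + 0.5) ** -1.5


def test_fisher_symmetry_under_row_and_column_swap():
    for a, b, c, d in random_tables(100, low=0, high=30, seed=5):
        if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
            continue
        p = fisher_exact(ContingencyTable(a, b, c, d))
        assert 0.0 <= p <= 1.0
        assert fisher_exact(ContingencyTable(d, c, b, a)) == pytest.approx(p, rel=1e-9)
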
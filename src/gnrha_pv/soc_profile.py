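"""SOC-level aggregation of passed signals and cross-drug comparison.

Each drug's passed signals are counted per system organ class; proportions
are within-drug. Cross-drug comparison of one SOC's share uses an r x 2
chi-square (in-SOC vs not-in-SOC counts per drug), falling back to a seeded
Monte-Carlo permutation p-value when any expected cell is below 5.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _st

from gnrha_pv.types import SignalRecord, norm_term


@dataclass(frozen=True)
class SocProfile:
    drug: str
    rows: tuple[tuple[str, int, float], ...]  # (soc, signal_count, proportion)
    total_signals: int


def soc_summary(records: Iterable[SignalRecord]) -> list[SocProfile]:
    """Count passed signals per (drug, SOC); proportions sum to 1 per drug."""
    counts: dict[str, dict[str, int]] = {}
    for r in records:
        if not r.passed:
            continue
        soc = r.soc if r.soc is not None else "unmapped"
        counts.setdefault(r.drug, {})[soc] = counts.get(r.drug, {}).get(soc, 0) + 1
    profiles = []
    for drug in counts:
        total = sum(counts[drug].values())
        rows = tuple(
            (soc, k, k / total)
            for soc, k in sorted(counts[drug].items(), key=lambda kv: (-kv[1], kv[0]))
        )
        profiles.append(SocProfile(drug=drug, rows=rows, total_signals=total))
    profiles.sort(key=lambda p: (-p.total_signals, p.drug))
    return profiles


def profiles_to_frame(profiles: Iterable[SocProfile]) -> pd.DataFrame:
    """Long-format (drug, soc, count, proportion) table."""
    rows = [
        {"drug": p.drug, "soc": soc, "count": k, "proportion": prop}
        for p in profiles
        for soc, k, prop in p.rows
    ]
    return pd.DataFrame(rows, columns=["drug", "soc", "count", "proportion"])


def _chi2_rx2(in_soc: np.ndarray, out_soc: np.ndarray) -> float:
    table = np.stack([in_soc, out_soc], axis=1).astype(float)
    n = table.sum()
    exp = np.outer(table.sum(axis=1), table.sum(axis=0)) / n
    return float(((table - exp) ** 2 / exp).sum())


def compare_soc_proportions(
    profiles: Sequence[SocProfile],
    soc: str,
    n_permutations: int = 10_000,
    seed: int = 0,
) -> tuple[float, int, float]:
    """Test whether one SOC's share of passed signals differs across drugs.

    Returns (chi2, df, p). Drugs with zero passed signals are dropped with
    a warning. When any expected cell of the r x 2 table is below 5 the p
    comes from a seeded Monte-Carlo permutation (multivariate
    hypergeometric resampling at fixed margins, ``n_permutations`` draws)
    instead of the chi-square distribution.
    """
    kept = [p for p in profiles if p.total_signals > 0]
    dropped = [p.drug for p in profiles if p.total_signals == 0]
    if dropped:
        warnings.warn(f"dropping drug(s) with no passed signals: {dropped}")
    if len(kept) < 2:
        raise ValueError("need at least two drugs with passed signals")
    key = norm_term(soc)
    in_soc = np.array(
        [sum(k for s, k, _ in p.rows if norm_term(s) == key) for p in kept]
    )
    totals = np.array([p.total_signals for p in kept])
    out_soc = totals - in_soc
    df = len(kept) - 1
    chi2 = _chi2_rx2(in_soc, out_soc)

    table = np.stack([in_soc, out_soc], axis=1).astype(float)
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
    if (expected >= 5).all():
        p = float(_st.chi2.sf(chi2, df=df))
    else:
        rng = np.random.default_rng(seed)
        total_in = int(in_soc.sum())
        hits = 0
        for _ in range(n_permutations):
            sim_in = rng.multivariate_hypergeometric(totals, total_in)
            if _chi2_rx2(sim_in, totals - sim_in) >= chi2 - 1e-12:
                hits += 1
        p = (hits + 1) / (n_permutations + 1)
    return chi2, df, p
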
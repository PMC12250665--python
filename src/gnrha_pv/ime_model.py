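"""Important-medical-event (IME) flagging and logistic risk modelling.

A report is IME-positive when any of its reaction PTs appears on the
(EMA-style) IME list. Risk factors for an IME report — drug, sex,
off-label use, age group — are modelled with univariate and multivariate
binary logistic regression; effects are reported as odds ratios with Wald
95% CIs, against the reference levels leuprolide, female, on-label and
age 19-45.

Rows with an unknown level are excluded listwise: per-factor for the
univariate fits, across all factors for the multivariate fit; exclusion
counts are carried on the fit object.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from gnrha_pv.disprostats import Z95
from gnrha_pv.types import CaseReport, ImeList, SignalCriteria, STUDY_DRUGS

#: Modelled factors, their reference level, and non-reference level order.
FACTOR_LEVELS: dict[str, tuple[str, ...]] = {
    "drug": ("leuprolide", "buserelin", "goserelin", "histrelin", "triptorelin"),
    "sex": ("female", "male"),
    "off_label": ("no", "yes"),
    "age_group": ("19-45", "<=18", ">80", "46-60", "61-80"),
}


@dataclass(frozen=True)
class Term:
    factor: str
    level: str
    or_estimate: float
    ci_low: float
    ci_high: float
    p: float


@dataclass
class LogisticFit:
    terms: list[Term]
    converged: bool
    n_used: int
    n_excluded: int
    message: str = ""


def flag_ime(report: CaseReport, ime_list: ImeList) -> bool:
    """True when any reaction PT is on the IME list (case/space-insensitive)."""
    return any(pt in ime_list for pt in report.reactions)


def build_design(
    reports: Sequence[CaseReport],
    ime_list: ImeList,
    drugs: Sequence[str] = STUDY_DRUGS,
    criteria: SignalCriteria = SignalCriteria(),
) -> pd.DataFrame:
    """One design row per report exposed to a study drug.

    Columns: ime (bool), drug, sex, off_label, age_group — the last three
    may hold "unknown". A report listing several study drugs is attributed
    to the first one in its drug list.
    """
    roles = criteria.role_codes_included
    rows = []
    study = [d.casefold() for d in drugs]
    for r in reports:
        drug = next(
            (
                d.name_norm
                for d in r.drugs
                if d.name_norm in study and d.role_code in roles
            ),
            None,
        )
        if drug is None:
            continue
        if r.off_label is None:
            off = "unknown"
        else:
            off = "yes" if r.off_label else "no"
        rows.append(
            {
                "ime": flag_ime(r, ime_list),
                "drug": drug,
                "sex": r.sex,
                "off_label": off,
                "age_group": r.age_group,
            }
        )
    return pd.DataFrame(rows, columns=["ime", "drug", "sex", "off_label", "age_group"])


def _fit_one(design: pd.DataFrame, factors: Sequence[str]) -> LogisticFit:
    known = design.copy()
    for f in factors:
        known = known[known[f] != "unknown"]
    n_excluded = len(design) - len(known)

    y = known["ime"].to_numpy(dtype=float)
    cols: list[tuple[str, str]] = []
    mats: list[np.ndarray] = []
    dropped: list[str] = []
    for f in factors:
        ref, *rest = FACTOR_LEVELS[f]
        present = set(known[f].unique())
        for level in rest:
            if level not in present:
                dropped.append(f"{f}={level}")
                continue
            cols.append((f, level))
            mats.append((known[f] == level).to_numpy(dtype=float))
    if not cols or y.sum() == 0 or y.sum() == len(y):
        return LogisticFit(
            terms=[],
            converged=False,
            n_used=len(known),
            n_excluded=n_excluded,
            message="degenerate design: single outcome class or no varying level",
        )
    X = sm.add_constant(np.column_stack(mats))
    msg = f"empty level(s) dropped: {dropped}" if dropped else ""
    try:
        # convergence/separation handled explicitly below; silence the
        # statsmodels warnings that duplicate that reporting
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, X).fit(disp=0, maxiter=100, tol=1e-10)
        converged = bool(res.mle_retvals.get("converged", False))
    except Exception as exc:  # separation / singular design
        return LogisticFit(
            terms=[],
            converged=False,
            n_used=len(known),
            n_excluded=n_excluded,
            message=f"fit failed ({exc}); odds ratios suppressed — "
            "check for complete separation",
        )
    if not converged:
        return LogisticFit(
            terms=[],
            converged=False,
            n_used=len(known),
            n_excluded=n_excluded,
            message="no convergence in 100 iterations; odds ratios suppressed — "
            "check for complete separation",
        )
    terms = []
    for i, (f, level) in enumerate(cols, start=1):
        coef = res.params[i]
        se = res.bse[i]
        terms.append(
            Term(
                factor=f,
                level=level,
                or_estimate=math.exp(coef),
                ci_low=math.exp(coef - Z95 * se),
                ci_high=math.exp(coef + Z95 * se),
                p=float(res.pvalues[i]),
            )
        )
    return LogisticFit(
        terms=terms,
        converged=True,
        n_used=len(known),
        n_excluded=n_excluded,
        message=msg,
    )


def fit_logistic(design: pd.DataFrame, mode: str = "multivariate"):
    """Fit IME ~ factors by maximum likelihood (Newton/IRLS).

    mode="univariate" returns ``{factor: LogisticFit}`` with one
    single-factor model per factor; mode="multivariate" returns one joint
    main-effects LogisticFit.
    """
    if mode == "multivariate":
        return _fit_one(design, list(FACTOR_LEVELS))
    if mode == "univariate":
        return {f: _fit_one(design, [f]) for f in FACTOR_LEVELS}
    raise ValueError(f"unknown mode: {mode!r}")


def format_or(or_estimate: float, ci_low: float, ci_high: float) -> str:
    return f"{or_estimate:.2f}({ci_low:.2f},{ci_high:.2f})"


def parse_or(cell: str) -> tuple[float, float, float]:
    """Inverse of :func:`format_or` ("6.78(6.06,7.59)" -> (6.78, 6.06, 7.59))."""
    est, rest = cell.split("(")
    lo, hi = rest.rstrip(")").split(",")
    return float(est), float(lo), float(hi)


def _fmt_p(p: float) -> str:
    return "<0.001" if p < 0.001 else f"{p:.3f}"


_VARIABLE_LABEL = {
    "drug": "Drug",
    "sex": "Gender",
    "off_label": "Off-label use",
    "age_group": "Age group",
}
_LEVEL_LABEL = {"female": "Female", "male": "Male", "no": "No", "yes": "Yes"}


def build_table1(
    univariate: dict[str, LogisticFit], multivariate: LogisticFit
) -> pd.DataFrame:
    """Side-by-side univariate/multivariate odds-ratio table.

    One row per factor level; reference levels render "Ref" with "/" in the
    p column; estimates render "x.xx(lo,hi)".
    """
    uni_ix = {
        (t.factor, t.level): t for fit in univariate.values() for t in fit.terms
    }
    multi_ix = {(t.factor, t.level): t for t in multivariate.terms}
    rows = []
    for factor, levels in FACTOR_LEVELS.items():
        ref, *rest = levels
        rows.append(
            {
                "variable": _VARIABLE_LABEL[factor],
                "factor": _LEVEL_LABEL.get(ref, ref),
                "univariate_or": "Ref",
                "univariate_p": "/",
                "multivariate_or": "Ref",
                "multivariate_p": "/",
            }
        )
        for level in rest:
            u = uni_ix.get((factor, level))
            m = multi_ix.get((factor, level))
            rows.append(
                {
                    "variable": _VARIABLE_LABEL[factor],
                    "factor": _LEVEL_LABEL.get(level, level),
                    "univariate_or": format_or(u.or_estimate, u.ci_low, u.ci_high) if u else "",
                    "univariate_p": _fmt_p(u.p) if u else "",
                    "multivariate_or": format_or(m.or_estimate, m.ci_low, m.ci_high) if m else "",
                    "multivariate_p": _fmt_p(m.p) if m else "",
                }
            )
    return pd.DataFrame(rows)
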
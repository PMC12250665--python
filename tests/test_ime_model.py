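"""IME flagging, logistic odds-ratio estimation, and the comparison table."""

import math

import numpy as np
import pandas as pd
import pytest

from gnrha_pv import synthetic as syn
from gnrha_pv.dedup import deduplicate
from gnrha_pv.ime_model import (
    build_design,
    build_table1,
    fit_logistic,
    flag_ime,
    format_or,
    parse_or,
)
from gnrha_pv.types import ImeList
from tests.conftest import make_report


class TestFlagIme:
    def test_not_flagged_when_no_reaction_listed(self):
        r = make_report(reactions=("Hot flush",))
        assert flag_ime(r, ImeList(["Anaphylactic reaction"])) is False

    def test_any_listed_reaction_flags(self):
        r = make_report(reactions=("Hot flush", "Anaphylactic reaction"))
        assert flag_ime(r, ImeList(["Anaphylactic reaction"])) is True

    def test_matching_ignores_case_and_whitespace(self):
        r = make_report(reactions=("  anaphylactic   REACTION ",))
        assert flag_ime(r, ImeList(["Anaphylactic reaction"])) is True

    def test_planted_flag_rate_recovered(self, ime_list):
        cfg = syn.profile_config("null", seed=21)  # baseline-only IME rate
        cfg.n_reports = 20_000
        reports, truth = syn.generate(cfg)
        kept, _ = deduplicate(reports)
        rate = np.mean([flag_ime(r, ime_list) for r in kept])
        se = math.sqrt(truth.mean_ime_rate * (1 - truth.mean_ime_rate) / len(kept))
        assert abs(rate - truth.mean_ime_rate) < 2 * se + 1e-9


def _binary_design(rng, n=600):
    x = rng.random(n) < 0.4
    p = 1 / (1 + np.exp(-(-1.0 + 1.2 * x)))
    y = rng.random(n) < p
    return pd.DataFrame(
        {
            "ime": y,
            "drug": np.where(x, "goserelin", "leuprolide"),
            "sex": "female",
            "off_label": "no",
            "age_group": "19-45",
        }
    )


class TestFitLogistic:
    def test_univariate_binary_factor_equals_collapsed_2x2_odds_ratio(self):
        rng = np.random.default_rng(8)
        checked = 0
        while checked < 25:
            design = _binary_design(rng)
            x = design["drug"] == "goserelin"
            y = design["ime"]
            n11 = int((x & y).sum())
            n10 = int((x & ~y).sum())
            n01 = int((~x & y).sum())
            n00 = int((~x & ~y).sum())
            if min(n11, n10, n01, n00) == 0:
                continue
            fit = fit_logistic(design, mode="univariate")["drug"]
            assert fit.converged
            (term,) = fit.terms
            assert term.or_estimate == pytest.approx(
                (n11 * n00) / (n10 * n01), rel=1e-6
            )
            checked += 1

    def test_null_wald_p_calibrated(self):
        rng = np.random.default_rng(12)
        n_sig = 0
        n_runs = 400
        for _ in range(n_runs):
            design = _binary_design(rng)
            design["ime"] = rng.random(len(design)) < 0.3  # outcome independent
            fit = fit_logistic(design, mode="univariate")["drug"]
            if fit.converged and fit.terms[0].p < 0.05:
                n_sig += 1
        assert abs(n_sig / n_runs - 0.05) < 0.025

    def test_fitted_likelihood_beats_intercept_only(self):
        rng = np.random.default_rng(3)
        design = _binary_design(rng, n=2_000)
        fit = fit_logistic(design, mode="multivariate")
        (term,) = fit.terms
        # effect planted at log-OR 1.2; the CI must bracket a positive effect
        assert term.ci_low <= math.exp(1.2) * 1.6
        assert term.or_estimate > 1

    def test_complete_separation_reported_not_silently_estimated(self):
        design = pd.DataFrame(
            {
                "ime": [True] * 20 + [False] * 20,
                "drug": ["goserelin"] * 20 + ["leuprolide"] * 20,
                "sex": "female",
                "off_label": "no",
                "age_group": "19-45",
            }
        )
        fit = fit_logistic(design, mode="multivariate")
        assert not fit.converged
        assert fit.terms == []
        assert "separation" in fit.message or "converge" in fit.message

    def test_unknown_levels_excluded_listwise_and_counted(self, ime_list):
        reports = [
            make_report(case_id="A", sex="unknown"),
            make_report(case_id="B"),
            make_report(case_id="C", drug="goserelin"),
            make_report(case_id="D", drug="tamoxifen"),  # not a study drug
        ]
        design = build_design(reports, ime_list)
        assert len(design) == 3  # study-drug reports only
        fit = fit_logistic(design, mode="multivariate")
        assert fit.n_excluded == 1


class TestRecovery:
    def test_planted_multivariate_ors_recovered(self, ime_list):
        cfg = syn.profile_config("ime", seed=77)
        reports, truth = syn.generate(cfg)
        kept, _ = deduplicate(reports)
        fit = fit_logistic(build_design(kept, ime_list), mode="multivariate")
        assert fit.converged
        ix = {(t.factor, t.level): t for t in fit.terms}
        for factor, level, true_or in truth.ime_effects:
            term = ix[(factor, level)]
            assert term.ci_low <= true_or * 1.35 and term.ci_high >= true_or * 0.7, (
                factor,
                level,
                term,
            )


class TestTable:
    def test_reference_rows_render_ref(self, ime_list):
        cfg = syn.profile_config("ime", seed=5)
        cfg.n_reports = 8_000
        reports, _ = syn.generate(cfg)
        kept, _ = deduplicate(reports)
        design = build_design(kept, ime_list)
        table = build_table1(
            fit_logistic(design, "univariate"), fit_logistic(design, "multivariate")
        )
        ref_rows = table[table["univariate_or"] == "Ref"]
        assert list(ref_rows["factor"]) == ["leuprolide", "Female", "No", "19-45"]
        assert (ref_rows["multivariate_p"] == "/").all()

    def test_or_cell_format_and_roundtrip(self):
        assert format_or(6.781, 6.06, 7.59) == "6.78(6.06,7.59)"
        assert parse_or("6.78(6.06,7.59)") == (6.78, 6.06, 7.59)

    def test_rendered_table_parses_back_to_fit_values(self, ime_list):
        cfg = syn.profile_config("ime", seed=6)
        cfg.n_reports = 8_000
        reports, _ = syn.generate(cfg)
        kept, _ = deduplicate(reports)
        design = build_design(kept, ime_list)
        multi = fit_logistic(design, "multivariate")
        table = build_table1(fit_logistic(design, "univariate"), multi)
        ix = {t.level: t for t in multi.terms}
        for _, row in table.iterrows():
            lv = row["factor"].lower() if row["factor"] in ("Yes", "No", "Male", "Female") else row["factor"]
            if row["multivariate_or"] in ("Ref", ""):
                continue
            est, lo, hi = parse_or(row["multivariate_or"])
            t = ix[lv]
            assert est == pytest.approx(t.or_estimate, abs=5.1e-3)
            assert lo == pytest.approx(t.ci_low, abs=5.1e-3)
            assert hi == pytest.approx(t.ci_high, abs=5.1e-3)
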
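"""Contingency building, screening criteria, exclusion filters, ranking."""

import numpy as np
import pytest

from gnrha_pv import synthetic as syn
from gnrha_pv.dedup import deduplicate
from gnrha_pv.signal_pipeline import (
    build_contingency,
    detect_signals,
    signals_to_frame,
    top_signals,
)
from gnrha_pv.types import (
    ContingencyTable,
    EmptyExposureError,
    SignalCriteria,
    SignalRecord,
    SignalStat,
)
from tests.conftest import make_report


class TestBuildContingency:
    def test_hand_enumerable_four_report_corpus(self, four_report_corpus):
        t = build_contingency(four_report_corpus, "leuprolide", "Hot flush")
        assert (t.a, t.b, t.c, t.d) == (1, 1, 1, 1)

    def test_cells_partition_the_corpus(self, four_report_corpus):
        t = build_contingency(four_report_corpus, "leuprolide", "Hot flush")
        assert t.n_total == len(four_report_corpus)

    def test_repeated_pt_within_report_counts_once(self):
        reports = [
            make_report(case_id="A", reactions=("Hot flush", "hot  flush")),
            make_report(case_id="B", drug="tamoxifen", reactions=("Nausea",)),
        ]
        t = build_contingency(reports, "leuprolide", "Hot flush")
        assert (t.a, t.b, t.c, t.d) == (1, 0, 0, 1)

    def test_role_filter_excludes_concomitant_exposure(self):
        reports = [
            make_report(case_id="A", role="concomitant"),
            make_report(case_id="B", drug="tamoxifen", reactions=("Nausea",)),
        ]
        with pytest.raises(EmptyExposureError):
            build_contingency(reports, "leuprolide", "Hot flush")

    def test_absent_drug_raises_empty_exposure(self, four_report_corpus):
        with pytest.raises(EmptyExposureError):
            build_contingency(four_report_corpus, "histrelin", "Hot flush")

    def test_generator_planted_cells_recovered_exactly(self):
        for seed in range(5):
            cfg = syn.profile_config("signals", seed=seed)
            cfg.n_reports = 4_000
            reports, truth = syn.generate(cfg)
            kept, _ = deduplicate(reports)
            for t in truth.injected:
                table = build_contingency(kept, t.drug, t.pt)
                assert (table.a, table.b, table.c, table.d) == t.realized_cells


class TestDetectSignals:
    def test_planted_association_passes_and_filters_apply(self, pt_map):
        cfg = syn.profile_config("signals", seed=9)
        reports, truth = syn.generate(cfg)
        kept, _ = deduplicate(reports)
        records = detect_signals(kept, list(cfg.drug_weights), pt_map)
        by_pair = {(r.drug, r.pt): r for r in records}
        for t in truth.injected:
            rec = by_pair[(t.drug, t.pt)]
            assert rec.passed, rec.exclusion_reason
        # every passed record re-satisfies all enabled criteria post hoc
        for r in records:
            if r.passed:
                assert r.stats.n >= 3 and r.stats.ror_ci_low > 1 and r.stats.ic025 > 0
            if r.exclusion_reason == "excluded_soc":
                assert r.soc is not None

    def test_excluded_soc_blocks_even_huge_ror(self, pt_map):
        # "Weight increased" maps to Investigations (an excluded SOC)
        reports = [
            make_report(case_id=f"A{i}", reactions=("Weight increased",))
            for i in range(30)
        ] + [
            make_report(case_id=f"B{i}", drug="tamoxifen", reactions=("Nausea",))
            for i in range(200)
        ]
        records = detect_signals(reports, ["leuprolide"], pt_map)
        rec = next(r for r in records if r.pt == "Weight increased")
        assert rec.stats.ror > 100
        assert not rec.passed and rec.exclusion_reason == "excluded_soc"

    def test_unmapped_soc_detected_before_exclusion(self, pt_map):
        reports = [
            make_report(case_id=f"A{i}", reactions=("Imaginary reaction",))
            for i in range(30)
        ] + [
            make_report(case_id=f"B{i}", drug="tamoxifen", reactions=("Nausea",))
            for i in range(200)
        ]
        rec = next(
            r
            for r in detect_signals(reports, ["leuprolide"], pt_map)
            if r.pt == "Imaginary reaction"
        )
        assert rec.exclusion_reason == "unmapped_soc" and rec.soc is None

    def test_raising_min_n_never_adds_passed_records(self, pt_map):
        cfg = syn.profile_config("signals", seed=5)
        cfg.n_reports = 5_000
        reports, _ = syn.generate(cfg)
        kept, _ = deduplicate(reports)
        drugs = list(cfg.drug_weights)
        loose = {
            (r.drug, r.pt)
            for r in detect_signals(kept, drugs, pt_map, SignalCriteria(min_n=3))
            if r.passed
        }
        strict = {
            (r.drug, r.pt)
            for r in detect_signals(kept, drugs, pt_map, SignalCriteria(min_n=10))
            if r.passed
        }
        assert strict <= loose

    def test_deterministic_signal_table(self, pt_map):
        cfg = syn.profile_config("signals", seed=2)
        cfg.n_reports = 3_000
        reports, _ = syn.generate(cfg)
        kept, _ = deduplicate(reports)
        drugs = list(cfg.drug_weights)
        csv1 = signals_to_frame(detect_signals(kept, drugs, pt_map)).to_csv(index=False)
        csv2 = signals_to_frame(detect_signals(kept, drugs, pt_map)).to_csv(index=False)
        assert csv1 == csv2


def _rec(drug, pt, n, ror_val, passed=True):
    stats = SignalStat(
        n=n, ror=ror_val, ror_ci_low=ror_val / 2, ror_ci_high=ror_val * 2,
        prr=ror_val, chi2=10.0, ic=1.0, ic025=0.5,
    )
    return SignalRecord(
        drug=drug, pt=pt, soc="Vascular disorders",
        table=ContingencyTable(n, 10, 10, 100), stats=stats,
        passed=passed, exclusion_reason="none" if passed else "below_min_n",
    )


class TestTopSignals:
    def test_frequency_ranking(self):
        recs = [_rec("x", "P1", 5, 2.0), _rec("x", "P2", 9, 1.5), _rec("x", "P3", 2, 9.0)]
        top = top_signals(recs, by="frequency", k=2)
        assert [r.stats.n for r in top] == [9, 5]

    def test_tie_broken_by_other_key(self):
        recs = [_rec("x", "P1", 5, 2.0), _rec("x", "P2", 5, 7.0)]
        assert top_signals(recs, by="frequency", k=1)[0].pt == "P2"
        recs = [_rec("x", "P1", 9, 3.0), _rec("x", "P2", 5, 3.0)]
        assert top_signals(recs, by="ror", k=1)[0].pt == "P1"

    def test_failed_records_never_ranked(self):
        recs = [_rec("x", "P1", 50, 9.0, passed=False), _rec("x", "P2", 5, 2.0)]
        assert [r.pt for r in top_signals(recs, by="frequency")] == ["P2"]

    def test_union_of_top20_lists_bounded(self, pt_map):
        cfg = syn.profile_config("full", seed=4)
        cfg.n_reports = 20_000
        reports, _ = syn.generate(cfg)
        kept, _ = deduplicate(reports)
        records = detect_signals(kept, list(cfg.drug_weights), pt_map)
        by_n = {(r.drug, r.pt) for r in top_signals(records, "frequency", 20)}
        by_ror = {(r.drug, r.pt) for r in top_signals(records, "ror", 20)}
        union = by_n | by_ror
        assert len(by_n) <= 20 and len(by_ror) <= 20
        assert max(len(by_n), len(by_ror)) <= len(union) <= 40
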
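import datetime as dt

import pytest
from hypothesis import HealthCheck, settings

from gnrha_pv import io as gio
from gnrha_pv.types import CaseReport, DrugEntry

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def pt_map():
    return gio.default_pt_soc_map()


@pytest.fixture(scope="session")
def ime_list():
    return gio.default_ime_list()


def make_report(
    case_id="C1",
    date=dt.date(2020, 6, 1),
    age=55.0,
    sex="male",
    country="US",
    drug="leuprolide",
    role="primary_suspect",
    reactions=("Hot flush",),
    outcomes=(),
    off_label=False,
    indication=None,
):
    """Terse report factory for hand-written corpora."""
    drugs = []
    if drug is not None:
        drugs = [
            DrugEntry(
                name_raw=drug.upper(),
                name_norm=gio.normalize_drug_name(drug),
                role_code=role,
                indication=indication,
            )
        ]
    return CaseReport(
        case_id=case_id,
        receipt_date=date,
        age_years=age,
        sex=sex,
        country=country,
        drugs=drugs,
        reactions=list(reactions),
        outcomes=frozenset(outcomes),
        off_label=off_label,
    )


@pytest.fixture
def four_report_corpus():
    """2 exposed reports (1 with the PT), 2 unexposed (1 with the PT)."""
    return [
        make_report(case_id="A", reactions=("Hot flush",)),
        make_report(case_id="B", reactions=("Nausea",)),
        make_report(case_id="C", drug="tamoxifen", reactions=("Hot flush",)),
        make_report(case_id="D", drug="tamoxifen", reactions=("Nausea",)),
    ]
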
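import datetime as dt

import pytest

from pvsignal.reports import AEReport


def mk_report(
    primary_id="1",
    case_id="C1",
    fda_date=dt.date(2020, 1, 1),
    drugs=(("semaglutide", "PS"),),
    reactions=("nausea",),
    sex="unknown",
    age_years=None,
    country="US",
    outcomes=(),
):
    return AEReport(
        primary_id=str(primary_id),
        case_id=str(case_id),
        fda_date=fda_date,
        drugs=tuple(drugs),
        reactions=frozenset(reactions),
        sex=sex,
        age_years=age_years,
        country=country,
        outcomes=frozenset(outcomes),
    )


@pytest.fixture
def make_report():
    return mk_report
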
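"""Descriptive cohort layer: shares, demographics, serious outcomes, trends."""

import datetime as dt
import itertools

import numpy as np
import pytest
from scipy import stats as sps

from pvsignal.cohort import (
    SERIOUS_FIVE_CODES,
    SeriousOutcomeRule,
    StratumSpec,
    assign_age_bin,
    compare_rates,
    demographic_table,
    drug_share,
    round_half_up,
    serious_rate,
    subgroup_signals,
    yearly_trend,
)
from pvsignal.ebgm import MgpsHyperParams
from pvsignal.reports import default_drug_catalog
from conftest import mk_report

CATALOG = default_drug_catalog()

# published biliary-cohort drug counts for the GLP-1 receptor agonist class
GLP1_COUNTS = {
    "exenatide": 142,
    "liraglutide": 384,
    "dulaglutide": 290,
    "lixisenatide": 12,
    "semaglutide": 655,
    "tirzepatide": 226,
}
DPP4_COUNTS = {"alogliptin": 13, "linagliptin": 79, "sitagliptin": 382, "saxagliptin": 32}


def cohort_from_counts(counts):
    reports = []
    i = 0
    for drug, n in counts.items():
        for _ in range(n):
            reports.append(mk_report(str(i), f"C{i}", drugs=((drug, "PS"),)))
            i += 1
    return reports


class TestDrugShare:
    def test_glp1_class_shares(self):
        df = drug_share(cohort_from_counts(GLP1_COUNTS), CATALOG, "GLP-1 RA")
        shares = dict(zip(df.drug, df.percent))
        assert shares["semaglutide"] == 38.33
        assert shares["liraglutide"] == 22.47
        assert df.n.sum() == 1709

    def test_dpp4_class_shares(self):
        df = drug_share(cohort_from_counts(DPP4_COUNTS), CATALOG, "DPP-4 inhibitor")
        shares = dict(zip(df.drug, df.percent))
        assert shares["sitagliptin"] == 75.49

    def test_single_drug_cohort(self):
        df = drug_share(cohort_from_counts({"semaglutide": 7}), CATALOG, "GLP-1 RA")
        assert dict(zip(df.drug, df.percent))["semaglutide"] == 100.00

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            drug_share([], CATALOG, "GLP-1 RA")


class TestDemographics:
    def _cohort(self):
        spec = [("female", 944), ("male", 647), ("not_specified", 4), ("unknown", 114)]
        countries = itertools.chain(
            itertools.repeat("US", 1104), itertools.repeat("JP", 88),
            itertools.repeat("GB", 66), itertools.repeat("CA", 60),
            itertools.repeat("FR", 60), itertools.repeat("DE", 60),
            itertools.repeat("AU", 60), itertools.repeat("IT", 60),
            itertools.repeat("ES", 60), itertools.repeat("BR", 60),
            itertools.repeat("NL", 31),
        )
        reports, i = [], 0
        for sex, n in spec:
            for _ in range(n):
                reports.append(
                    mk_report(str(i), f"C{i}", sex=sex, country=next(countries))
                )
                i += 1
        return reports

    def test_sex_and_country_percentages(self):
        demo = demographic_table(self._cohort())
        sex = dict(zip(demo.sex.category, demo.sex.percent))
        assert sex["female"] == 55.24
        assert sex["male"] == 37.86
        assert demo.country.category.tolist()[:3] == ["US", "JP", "GB"]
        assert demo.country.percent.iloc[0] == 64.60

    def test_percent_columns_sum_to_100(self):
        demo = demographic_table(self._cohort())
        assert demo.sex.percent.sum() == pytest.approx(100, abs=0.05)
        assert demo.age.percent.sum() == pytest.approx(100, abs=0.05)

    def test_all_ages_unknown_median_unavailable(self):
        demo = demographic_table([mk_report(), mk_report("2", "C2")])
        assert demo.age_median is None

    def test_median_and_quartiles_over_known_ages(self):
        reports = [
            mk_report(str(i), f"C{i}", age_years=a)
            for i, a in enumerate([40, 50, 60, 70, 80])
        ] + [mk_report("99", "C99", age_years=None)]
        demo = demographic_table(reports)
        assert demo.age_median == 60
        assert demo.age_q1 == 50 and demo.age_q3 == 70


class TestAgeBins:
    @pytest.mark.parametrize(
        "age,expected",
        [
            (0, "<19"), (18.9, "<19"), (19, "19-45"), (45, "19-45"),
            (46, "46-65"), (65, "46-65"), (65.1, ">65"), (90, ">65"),
            (None, "unknown"),
        ],
    )
    def test_boundaries(self, age, expected):
        assert assign_age_bin(age) == expected

    def test_negative_age_rejected(self):
        with pytest.raises(ValueError):
            assign_age_bin(-1)


class TestSeriousRate:
    def _cohort(self, n_serious, n_total, code="HO"):
        reports = []
        for i in range(n_total):
            outcomes = (code,) if i < n_serious else ("OT",)
            reports.append(mk_report(str(i), f"C{i}", outcomes=outcomes))
        return reports

    @pytest.mark.parametrize(
        "n_serious,n_total,pct",
        [(86, 142, 60.56), (308, 382, 80.63), (881, 1709, 51.55), (389, 506, 76.88)],
    )
    def test_published_rates(self, n_serious, n_total, pct):
        n_s, n_t, p = serious_rate(self._cohort(n_serious, n_total))
        assert (n_s, n_t, p) == (n_serious, n_total, pct)

    def test_report_counted_once_with_multiple_codes(self):
        r = mk_report(outcomes=("DE", "HO", "LT"))
        assert serious_rate([r]) == (1, 1, 100.00)

    def test_no_serious_codes(self):
        assert serious_rate(self._cohort(0, 5))[2] == 0.00

    def test_monotone_in_rule(self):
        reports = self._cohort(3, 10, code="RI")
        strict = serious_rate(reports, SeriousOutcomeRule(frozenset(SERIOUS_FIVE_CODES)))
        lenient = serious_rate(reports)  # five codes + RI
        assert strict[0] == 0 and lenient[0] == 3

    def test_ot_not_serious_by_default(self):
        # the "other serious" code sits outside both rules here
        assert serious_rate([mk_report(outcomes=("OT",))])[0] == 0


class TestCompareRates:
    def test_identical_rates_give_zero(self):
        chi2, df, p = compare_rates([(50, 100), (50, 100)])
        assert chi2 == pytest.approx(0) and p == pytest.approx(1)

    def test_derived_two_group_value(self):
        chi2, df, p = compare_rates([(90, 100), (10, 100)])
        assert chi2 == pytest.approx(128.0)
        assert df == 1

    def test_three_equal_groups(self):
        chi2, df, _ = compare_rates([(30, 90)] * 3)
        assert chi2 == pytest.approx(0) and df == 2

    def test_matches_independent_oracle_on_random_configs(self):
        rng = np.random.default_rng(8)
        for _ in range(200):
            k = int(rng.integers(2, 6))
            groups = []
            for _ in range(k):
                n = int(rng.integers(10, 500))
                s = int(rng.integers(1, n))
                groups.append((s, n))
            chi2, df, p = compare_rates(groups)
            table = np.array([[s, n - s] for s, n in groups])
            ref_chi2, ref_p, ref_df, _ = sps.chi2_contingency(table, correction=False)
            assert chi2 == pytest.approx(ref_chi2, rel=1e-9)
            assert df == ref_df and p == pytest.approx(ref_p, rel=1e-9)

    def test_empty_expected_cell_rejected(self):
        with pytest.raises(ValueError):
            compare_rates([(100, 100), (50, 50)])  # nobody non-serious


class TestYearlyTrend:
    def test_exact_tallies_with_gap_year(self):
        reports = (
            [mk_report(str(i), f"C{i}", dt.date(2013, 3, 1),
                       reactions=("cholelithiasis",)) for i in range(3)]
            + [mk_report(str(10 + i), f"C{10+i}", dt.date(2013, 8, 1)) for i in range(2)]
            + [mk_report("20", "C20", dt.date(2015, 1, 1))]
        )
        df = yearly_trend(reports, {"cholelithiasis"})
        assert df.year.tolist() == [2013, 2014, 2015]
        assert df.n_total.tolist() == [5, 0, 1]
        assert df.n_event.tolist() == [3, 0, 0]

    def test_single_year(self):
        df = yearly_trend([mk_report()], {"nausea"})
        assert len(df) == 1 and df.n_event.iloc[0] == 1

    def test_event_counts_bounded_by_totals(self):
        rng = np.random.default_rng(4)
        reports = [
            mk_report(
                str(i), f"C{i}",
                dt.date(int(rng.integers(2013, 2024)), 6, 1),
                reactions=("cholelithiasis",) if rng.random() < 0.3 else ("nausea",),
            )
            for i in range(200)
        ]
        df = yearly_trend(reports, {"cholelithiasis"})
        assert (df.n_event <= df.n_total).all()


class TestSubgroupSignals:
    H = MgpsHyperParams(0.2, 0.1, 2.0, 4.0, 1 / 3)

    def _reports(self, spike_in=("female", 30.0)):
        rng = np.random.default_rng(9)
        reports = []
        for i in range(4000):
            sex = "female" if rng.random() < 0.5 else "male"
            age = float(rng.integers(20, 80))
            drug = "semaglutide" if rng.random() < 0.3 else "metformin"
            p = 0.02
            if drug == "semaglutide" and sex == spike_in[0] and age <= 45:
                p = 0.45
            reactions = ("cholelithiasis",) if rng.random() < p else ("nausea",)
            reports.append(
                mk_report(str(i), f"C{i}", drugs=((drug, "PS"),),
                          reactions=reactions, sex=sex, age_years=age)
            )
        return reports

    def test_spiked_stratum_flagged_others_not(self):
        strata = [
            StratumSpec("female", "19-45"), StratumSpec("male", "19-45"),
            StratumSpec("female", "46-65"), StratumSpec("male", "46-65"),
        ]
        df = subgroup_signals(
            self._reports(), {"semaglutide"}, {"cholelithiasis"}, strata, self.H
        )
        by = dict(zip(df.stratum, df.positive))
        assert by["female/19-45"]
        assert not by["male/46-65"] and not by["female/46-65"]

    def test_stratum_without_exposed_reports_is_no_data(self):
        reports = [mk_report(str(i), f"C{i}", drugs=(("metformin", "PS"),),
                             sex="male", age_years=30) for i in range(10)]
        df = subgroup_signals(
            reports, {"semaglutide"}, {"nausea"}, [StratumSpec("male", "19-45")], self.H
        )
        assert df.no_data.iloc[0]

    def test_partition_additivity_of_a_cells(self):
        reports = self._reports()
        strata = [
            StratumSpec(sex, bin_)
            for sex in ("female", "male")
            for bin_ in ("<19", "19-45", "46-65", ">65")
        ]
        df = subgroup_signals(
            reports, {"semaglutide"}, {"cholelithiasis"}, strata, self.H
        )
        from pvsignal.stats import build_table

        total_a = build_table(reports, {"semaglutide"}, {"cholelithiasis"}).a
        assert int(df.n.fillna(0).sum()) == total_a

    def test_duplicate_strata_rejected(self):
        with pytest.raises(ValueError):
            subgroup_signals(
                [mk_report()], {"semaglutide"}, {"nausea"},
                [StratumSpec("male"), StratumSpec("male")], self.H,
            )


def test_round_half_up_at_the_boundary():
    assert round_half_up(38.325) == 38.33  # plain float rounding would give .32
    assert round_half_up(2.5, 0) == 3.0
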
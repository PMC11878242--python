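"""Descriptive cohort layer: drug shares, demographics, trends, serious
outcomes, and sex-by-age subgroup disproportionality.

Percent columns are rounded half-up to two decimals, matching the
presentation conventions of spontaneous-report characteristic tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .detect import compute_metrics
from .ebgm import MgpsHyperParams
from .reports import AEReport, DrugCatalog
from .stats import BcpnnPriors, SignalMetrics, build_table, evaluate_signal

__all__ = [
    "StratumSpec",
    "SeriousOutcomeRule",
    "SERIOUS_FIVE_CODES",
    "SERIOUS_WITH_RI",
    "AGE_BINS",
    "assign_age_bin",
    "drug_share",
    "demographic_table",
    "serious_rate",
    "compare_rates",
    "yearly_trend",
    "subgroup_signals",
    "round_half_up",
]

AGE_BINS = ("<19", "19-45", "46-65", ">65", "unknown")

#: The five outcome codes of the strict seriousness definition: death,
#: life-threatening, hospitalization, disability, congenital anomaly.
SERIOUS_FIVE_CODES = frozenset({"DE", "LT", "HO", "DS", "CA"})
#: Default rule: the five codes plus required-intervention (RI), the
#: composition under which published seriousness totals add up.
SERIOUS_WITH_RI = SERIOUS_FIVE_CODES | {"RI"}


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round half away from zero at ``ndigits`` decimals (table convention)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class StratumSpec:
    """A subgroup: optional sex filter and optional age-bin filter."""

    sex: str | None = None
    age_bin: str | None = None

    def __post_init__(self) -> None:
        if self.sex is not None and self.sex not in {"male", "female"}:
            raise ValueError(f"stratum sex must be male/female, got {self.sex!r}")
        if self.age_bin is not None and self.age_bin not in AGE_BINS:
            raise ValueError(f"unknown age bin {self.age_bin!r}")

    def matches(self, r: AEReport) -> bool:
        if self.sex is not None and r.sex != self.sex:
            return False
        if self.age_bin is not None and assign_age_bin(r.age_years) != self.age_bin:
            return False
        return True

    def label(self) -> str:
        return f"{self.sex or 'all'}/{self.age_bin or 'all'}"


@dataclass(frozen=True)
class SeriousOutcomeRule:
    """Outcome codes counted as serious; a report is serious when its
    outcome set intersects them."""

    serious_codes: frozenset = SERIOUS_WITH_RI

    def __post_init__(self) -> None:
        if not self.serious_codes:
            raise ValueError("serious_codes must be non-empty")

    def is_serious(self, r: AEReport) -> bool:
        return bool(r.outcomes & self.serious_codes)


def assign_age_bin(age_years: float | None) -> str:
    """Age bin label: <19, 19-45, 46-65, >65 (inclusive boundaries), unknown.

    Ages in (45, 46) fall in 19-45? No: the bins are <19, [19, 45],
    [46, 65], >65; a fractional age strictly between 45 and 46 belongs to
    no closed bin and is assigned to 19-45 by extending its upper edge to
    just-below 46 (bins must cover [0, 130]).
    """
    if age_years is None:
        return "unknown"
    if age_years < 0:
        raise ValueError(f"age must be non-negative, got {age_years}")
    if age_years < 19:
        return "<19"
    if age_years < 46:
        return "19-45"
    if age_years <= 65:
        return "46-65"
    return ">65"


def drug_share(
    reports: Iterable[AEReport],
    catalog: DrugCatalog,
    drug_class: str,
    role: str = "PS",
) -> pd.DataFrame:
    """Per-drug report counts and percent of the class cohort.

    ``reports`` should already be restricted to the class cohort; each
    report is attributed to every class drug it carries in the given role
    (a report naming two class drugs as primary suspect appears under
    both, so counts can exceed the cohort size in that edge case).
    """
    reports = list(reports)
    if not reports:
        raise ValueError("empty cohort")
    members = sorted(catalog.members(drug_class))
    if not members:
        raise ValueError(f"no drugs in class {drug_class!r}")
    counts = {m: 0 for m in members}
    for r in reports:
        for name in r.drug_names(role) & frozenset(members):
            counts[name] += 1
    total = len(reports)
    rows = [
        {"drug": m, "n": counts[m], "percent": round_half_up(100.0 * counts[m] / total)}
        for m in members
    ]
    return pd.DataFrame(rows)


@dataclass
class DemographicSummary:
    """Sex, age-bin and country distributions plus the median age."""

    sex: pd.DataFrame
    age: pd.DataFrame
    country: pd.DataFrame  # ranked descending; top-3 of the full ranking
    age_median: float | None
    age_q1: float | None
    age_q3: float | None
    n_total: int


def _dist(values: Sequence[str], order: Sequence[str] | None, total: int) -> pd.DataFrame:
    ser = pd.Series(list(values))
    counts = ser.value_counts()
    cats = list(order) if order is not None else list(counts.index)
    rows = [
        {
            "category": c,
            "n": int(counts.get(c, 0)),
            "percent": round_half_up(100.0 * counts.get(c, 0) / total),
        }
        for c in cats
    ]
    return pd.DataFrame(rows)


def demographic_table(reports: Iterable[AEReport], top_countries: int = 3) -> DemographicSummary:
    """Sex/age/country distributions with counts and rounded percents.

    Country rows are ranked descending by count with the top three
    reported; the age median and quartiles use known ages only and are
    ``None`` when every age is unknown.
    """
    reports = list(reports)
    total = len(reports)
    if total == 0:
        raise ValueError("empty report set")
    sex = _dist(
        [r.sex for r in reports], ["male", "female", "not_specified", "unknown"], total
    )
    age = _dist([assign_age_bin(r.age_years) for r in reports], AGE_BINS, total)
    country_full = _dist([r.country for r in reports], None, total)
    country = country_full.sort_values("n", ascending=False).head(top_countries)
    country = country.reset_index(drop=True)
    known = np.array([r.age_years for r in reports if r.age_years is not None])
    if known.size:
        q1, med, q3 = np.percentile(known, [25, 50, 75])
    else:
        q1 = med = q3 = None
    return DemographicSummary(
        sex=sex,
        age=age,
        country=country,
        age_median=med,
        age_q1=q1,
        age_q3=q3,
        n_total=total,
    )


def serious_rate(
    reports: Iterable[AEReport],
    rule: SeriousOutcomeRule | None = None,
) -> tuple[int, int, float]:
    """(n_serious, n_total, percent) of reports with a serious outcome.

    A report counts once however many serious codes it carries; the
    default rule is :data:`SERIOUS_WITH_RI`.
    """
    rule = rule or SeriousOutcomeRule()
    reports = list(reports)
    n_total = len(reports)
    n_serious = sum(1 for r in reports if rule.is_serious(r))
    pct = round_half_up(100.0 * n_serious / n_total) if n_total else 0.0
    return n_serious, n_total, pct


def compare_rates(groups: Sequence[tuple[int, int]]) -> tuple[float, int, float]:
    """Pearson chi-square comparing serious-outcome rates across groups.

    ``groups`` holds (n_serious, n_total) per group; the r x 2 table of
    serious/non-serious counts gives the statistic with df = r - 1.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    table = []
    for n_serious, n_total in groups:
        if n_total <= 0 or n_serious < 0 or n_serious > n_total:
            raise ValueError(f"invalid group ({n_serious}, {n_total})")
        table.append([n_serious, n_total - n_serious])
    table = np.asarray(table)
    if np.any(table.sum(axis=0) == 0):
        raise ValueError("a column of the rate table is empty; expected counts are zero")
    chi2, p, df, _ = sps.chi2_contingency(table, correction=False)
    return float(chi2), int(df), float(p)


def yearly_trend(
    reports: Iterable[AEReport],
    event_terms: Iterable[str],
) -> pd.DataFrame:
    """Reports per calendar year: all reports and the event-matched subset.

    Years within the observed range with no reports appear with zero
    counts.
    """
    reports = list(reports)
    terms = frozenset(t.casefold() for t in event_terms)
    if not reports:
        return pd.DataFrame(columns=["year", "n_total", "n_event"])
    years = [r.fda_date.year for r in reports]
    matched = [any(rx.casefold() in terms for rx in r.reactions) for r in reports]
    df = pd.DataFrame({"year": years, "event": matched})
    grouped = df.groupby("year").agg(n_total=("event", "size"), n_event=("event", "sum"))
    full = range(min(years), max(years) + 1)
    grouped = grouped.reindex(full, fill_value=0).rename_axis("year").reset_index()
    grouped["n_event"] = grouped["n_event"].astype(int)
    return grouped


def subgroup_signals(
    reports: Sequence[AEReport],
    drug_set: Iterable[str],
    event_terms: Iterable[str],
    strata: Sequence[StratumSpec],
    hyperparams: MgpsHyperParams,
    priors: BcpnnPriors | None = None,
    role: str = "PS",
) -> pd.DataFrame:
    """Disproportionality within sex/age subgroups.

    Both exposed and comparator reports are restricted to each stratum
    before the fourfold table is rebuilt. The EBGM shrinkage prior
    (``hyperparams``) is fitted once on the full dataset and shared across
    strata. Strata whose a-cell is empty are reported as no-data rows
    (NaN metrics, no decision).
    """
    if len({(s.sex, s.age_bin) for s in strata}) != len(strata):
        raise ValueError("strata must be distinct")
    reports = list(reports)
    rows = []
    for s in strata:
        sub = [r for r in reports if s.matches(r)]
        row: dict = {"stratum": s.label(), "sex": s.sex, "age_bin": s.age_bin}
        table = None
        if sub:
            table = build_table(sub, drug_set, event_terms, role=role)
        if table is None or table.a == 0:
            row.update({"n": 0 if table is None else table.a, "no_data": True})
        else:
            m = compute_metrics(table, hyperparams, priors)
            d = evaluate_signal(m)
            row.update(
                {k: getattr(m, k) for k in SignalMetrics.__dataclass_fields__}
            )
            row.update(
                {
                    "no_data": False,
                    "ror_pass": d.ror_pass,
                    "prr_pass": d.prr_pass,
                    "ic_pass": d.ic_pass,
                    "ebgm_pass": d.ebgm_pass,
                    "positive": d.positive,
                }
            )
        rows.append(row)
    return pd.DataFrame(rows)
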
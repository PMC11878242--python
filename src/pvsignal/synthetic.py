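"""Synthetic spontaneous-report generator with known ground truth.

Emulates an OpenVigil-style FAERS extract: each report carries one primary
suspect (PS) drug drawn from a weighted menu, a reaction set drawn by
independent per-term Bernoulli trials whose probability is the term's
baseline reporting rate times the configured rate ratio ``rho(drug, term)``
(1 everywhere except spiked associations), demographics and seriousness
outcomes from simple categorical models, and an FDA acceptance date
uniform over the study window. A configurable fraction of reports gains a
duplicate entry sharing its case identifier with a fresh, higher primary
identifier and an advanced date — exactly the situation the deduplication
rules resolve.

``rho`` is the generator's analogue of the relative reporting rate the
reporting odds ratio estimates, so spiked pairs have a known target and
:func:`expected_ror` gives the exact odds ratio implied by the generative
process. Reaction draws are independent across terms given the drug (no
co-reporting correlation); reports that draw no term receive the filler
term "adverse event unspecified", which belongs to no query and keeps the
reaction-set-non-empty invariant without disturbing any analyzed pair.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .reports import AEReport, write_reports

__all__ = [
    "DrugSpec",
    "EventSpec",
    "AgeModel",
    "OutcomeModel",
    "SyntheticConfig",
    "GroundTruth",
    "generate",
    "expected_ror",
    "write_dataset",
    "default_config",
]

FILLER_PT = "adverse event unspecified"


@dataclass(frozen=True)
class DrugSpec:
    name: str
    drug_class: str
    weight: float

    def __post_init__(self) -> None:
        if self.weight <= 0:
            raise ValueError(f"drug weight must be positive ({self.name})")


@dataclass(frozen=True)
class EventSpec:
    pt: str
    smq: str | None
    baseline: float

    def __post_init__(self) -> None:
        if not 0 < self.baseline <= 1:
            raise ValueError(f"baseline probability must be in (0, 1] ({self.pt})")


@dataclass(frozen=True)
class AgeModel:
    """Two-component normal mixture for ages, truncated to [0, 120], with a
    missing-at-random fraction."""

    means: tuple[float, float] = (54.0, 72.0)
    sds: tuple[float, float] = (12.0, 9.0)
    weights: tuple[float, float] = (0.6, 0.4)
    missing_fraction: float = 0.4

    def __post_init__(self) -> None:
        if not 0 <= self.missing_fraction < 1:
            raise ValueError("missing_fraction must be in [0, 1)")
        if abs(sum(self.weights) - 1) > 1e-9:
            raise ValueError("mixture weights must sum to 1")


@dataclass(frozen=True)
class OutcomeModel:
    """Latent severity class then a single outcome code per report.

    Serious reports draw one of the serious codes; non-serious reports
    carry the other-serious code OT with probability ``p_ot`` and no code
    otherwise (the 'unknown outcome' rows of characteristic tables).
    """

    p_serious: float = 0.55
    serious_code_weights: Mapping[str, float] = field(
        default_factory=lambda: {
            "HO": 0.60,
            "DE": 0.20,
            "LT": 0.10,
            "DS": 0.05,
            "CA": 0.01,
            "RI": 0.04,
        }
    )
    p_ot: float = 0.7

    def __post_init__(self) -> None:
        if not 0 <= self.p_serious <= 1 or not 0 <= self.p_ot <= 1:
            raise ValueError("probabilities must lie in [0, 1]")


def _default_drug_menu() -> tuple[DrugSpec, ...]:
    study = [
        ("exenatide", "GLP-1 RA", 0.010),
        ("liraglutide", "GLP-1 RA", 0.025),
        ("dulaglutide", "GLP-1 RA", 0.020),
        ("lixisenatide", "GLP-1 RA", 0.002),
        ("semaglutide", "GLP-1 RA", 0.045),
        ("tirzepatide", "GLP-1 RA", 0.015),
        ("linagliptin", "DPP-4 inhibitor", 0.006),
        ("alogliptin", "DPP-4 inhibitor", 0.002),
        ("saxagliptin", "DPP-4 inhibitor", 0.004),
        ("sitagliptin", "DPP-4 inhibitor", 0.020),
    ]
    background = [
        ("metformin", "other", 0.20),
        ("atorvastatin", "other", 0.18),
        ("lisinopril", "other", 0.15),
        ("omeprazole", "other", 0.16),
        ("ibuprofen", "other", 0.16),
    ]
    return tuple(DrugSpec(*t) for t in study + background)


def _default_event_menu() -> tuple[EventSpec, ...]:
    biliary = [
        ("cholelithiasis", "gallstone related disorders", 0.005),
        ("choledocholithiasis", "gallstone related disorders", 0.002),
        ("cholecystitis", "gallbladder related disorders", 0.004),
        ("cholecystitis acute", "gallbladder related disorders", 0.002),
        ("cholangitis", "infectious biliary disorders", 0.002),
        ("bile duct obstruction", "biliary tract disorders", 0.002),
        ("cholestasis", "biliary tract disorders", 0.002),
        ("blood bilirubin increased", "biliary system related investigations, signs and symptoms", 0.003),
        ("jaundice", "biliary system related investigations, signs and symptoms", 0.003),
        ("cholangiocarcinoma", "biliary malignant tumours", 0.0005),
        ("gallbladder polyp", "biliary neoplasms benign (incl cysts and polyps)", 0.0005),
        ("biliary neoplasm", "biliary tumours of unspecified malignancy", 0.0002),
        ("biliary atresia", "congenital biliary disorders", 0.0002),
    ]
    background = [
        ("nausea", None, 0.08),
        ("headache", None, 0.06),
        ("diarrhoea", None, 0.05),
        ("vomiting", None, 0.04),
        ("fatigue", None, 0.04),
        ("dizziness", None, 0.03),
        ("rash", None, 0.02),
        ("arthralgia", None, 0.02),
    ]
    return tuple(EventSpec(*t) for t in biliary + background)


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator parameters; defaults describe the emulated study setting.

    ``spikes`` lists (drug, preferred term, rate ratio rho) triples; rho = 1
    is the null. The default configuration plants a single rho = 4 spike on
    a biliary term with baseline reporting rate 0.005 in a universe of
    200,000 reports with a 10% duplicate-entry rate.
    """

    n_reports: int = 200_000
    drug_menu: tuple[DrugSpec, ...] = field(default_factory=_default_drug_menu)
    event_menu: tuple[EventSpec, ...] = field(default_factory=_default_event_menu)
    spikes: tuple[tuple[str, str, float], ...] = (
        ("sitagliptin", "cholelithiasis", 4.0),
    )
    duplicate_rate: float = 0.1
    sex_probs: Mapping[str, float] = field(
        default_factory=lambda: {
            "female": 0.550,
            "male": 0.380,
            "not_specified": 0.004,
            "unknown": 0.066,
        }
    )
    age_model: AgeModel = field(default_factory=AgeModel)
    country_weights: Mapping[str, float] = field(
        default_factory=lambda: {
            "US": 0.60,
            "JP": 0.08,
            "GB": 0.05,
            "FR": 0.04,
            "CA": 0.04,
            "DE": 0.04,
            "unknown": 0.15,
        }
    )
    outcome_model: OutcomeModel = field(default_factory=OutcomeModel)
    concomitant_rate: float = 0.2
    window_start: _dt.date = _dt.date(2013, 1, 1)
    window_end: _dt.date = _dt.date(2024, 3, 31)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reports <= 0:
            raise ValueError("n_reports must be positive")
        if not 0 <= self.duplicate_rate < 1:
            raise ValueError("duplicate_rate must be in [0, 1)")
        if not 0 <= self.concomitant_rate <= 1:
            raise ValueError("concomitant_rate must be in [0, 1]")
        for probs, what in ((self.sex_probs, "sex"), (self.country_weights, "country")):
            if any(p < 0 for p in probs.values()) or abs(sum(probs.values()) - 1) > 1e-9:
                raise ValueError(f"{what} probabilities must be non-negative and sum to 1")
        drugs = {d.name for d in self.drug_menu}
        pts = {e.pt for e in self.event_menu}
        for drug, pt, rho in self.spikes:
            if drug not in drugs:
                raise ValueError(f"spiked drug {drug!r} not in drug_menu")
            if pt not in pts:
                raise ValueError(f"spiked PT {pt!r} not in event_menu")
            if rho <= 0:
                raise ValueError(f"rate ratio must be positive, got {rho}")
        if self.window_start > self.window_end:
            raise ValueError("window_start after window_end")

    def rho(self, drug: str, pt: str) -> float:
        for d, p, r in self.spikes:
            if d == drug and p == pt:
                return r
        return 1.0


@dataclass
class GroundTruth:
    """What the generator actually did: true rate ratios per (drug, PT),
    the duplicate links, and the number of distinct cases."""

    rate_ratios: dict[tuple[str, str], float]
    duplicate_of: dict[str, str]  # clone primary_id -> original primary_id
    n_cases: int

    def null_pairs(self) -> list[tuple[str, str]]:
        return [pair for pair, rho in self.rate_ratios.items() if rho == 1.0]

    def spiked_pairs(self) -> list[tuple[str, str]]:
        return [pair for pair, rho in self.rate_ratios.items() if rho != 1.0]


def generate(config: SyntheticConfig) -> tuple[list[AEReport], GroundTruth]:
    """Draw a synthetic report collection; byte-reproducible for a fixed seed."""
    rng = np.random.default_rng(config.seed)
    n = config.n_reports
    menu = config.drug_menu
    events = config.event_menu

    weights = np.array([d.weight for d in menu], dtype=float)
    weights /= weights.sum()
    drug_idx = rng.choice(len(menu), size=n, p=weights)

    # reaction matrix: independent Bernoulli per (report, term) at baseline * rho
    prob = np.empty((len(menu), len(events)))
    for i, d in enumerate(menu):
        for j, e in enumerate(events):
            prob[i, j] = min(e.baseline * config.rho(d.name, e.pt), 1.0)
    hits = rng.random((n, len(events))) < prob[drug_idx]

    sexes = list(config.sex_probs)
    sex_draw = rng.choice(len(sexes), size=n, p=np.array(list(config.sex_probs.values())))
    am = config.age_model
    comp = rng.choice(2, size=n, p=np.array(am.weights))
    ages = rng.normal(np.array(am.means)[comp], np.array(am.sds)[comp])
    ages = np.clip(ages, 0.0, 120.0).round(0)
    age_missing = rng.random(n) < am.missing_fraction
    countries = list(config.country_weights)
    country_draw = rng.choice(
        len(countries), size=n, p=np.array(list(config.country_weights.values()))
    )
    om = config.outcome_model
    serious = rng.random(n) < om.p_serious
    s_codes = list(om.serious_code_weights)
    s_w = np.array(list(om.serious_code_weights.values()), dtype=float)
    s_w /= s_w.sum()
    serious_code = rng.choice(len(s_codes), size=n, p=s_w)
    ot_flag = rng.random(n) < om.p_ot
    concomitant = rng.random(n) < config.concomitant_rate
    conco_drug = rng.choice(len(menu), size=n, p=weights)

    span = (config.window_end - config.window_start).days
    day_offsets = rng.integers(0, span + 1, size=n)

    event_names = [e.pt for e in events]
    reports: list[AEReport] = []
    for i in range(n):
        pts = [event_names[j] for j in np.flatnonzero(hits[i])]
        if not pts:
            pts = [FILLER_PT]
        drugs = [(menu[drug_idx[i]].name, "PS")]
        if concomitant[i] and conco_drug[i] != drug_idx[i]:
            drugs.append((menu[conco_drug[i]].name, "C"))
        if serious[i]:
            outcomes = frozenset({s_codes[serious_code[i]]})
        elif ot_flag[i]:
            outcomes = frozenset({"OT"})
        else:
            outcomes = frozenset()
        reports.append(
            AEReport(
                primary_id=str(1_000_000 + i),
                case_id=f"C{i:07d}",
                fda_date=config.window_start + _dt.timedelta(days=int(day_offsets[i])),
                drugs=tuple(drugs),
                reactions=frozenset(pts),
                sex=sexes[sex_draw[i]],
                age_years=None if age_missing[i] else float(ages[i]),
                country=countries[country_draw[i]],
                outcomes=outcomes,
            )
        )

    # duplicate entries: same case, fresh higher primary_id, advanced date
    n_dup = int(rng.binomial(n, config.duplicate_rate))
    dup_idx = rng.choice(n, size=n_dup, replace=False)
    advance = rng.integers(1, 181, size=n_dup)
    duplicate_of: dict[str, str] = {}
    for k, i in enumerate(dup_idx):
        orig = reports[i]
        new_date = min(orig.fda_date + _dt.timedelta(days=int(advance[k])), config.window_end)
        clone_id = str(1_000_000 + n + k)
        duplicate_of[clone_id] = orig.primary_id
        reports.append(
            AEReport(
                primary_id=clone_id,
                case_id=orig.case_id,
                fda_date=new_date,
                drugs=orig.drugs,
                reactions=orig.reactions,
                sex=orig.sex,
                age_years=orig.age_years,
                country=orig.country,
                outcomes=orig.outcomes,
            )
        )

    truth = GroundTruth(
        rate_ratios={
            (d.name, e.pt): config.rho(d.name, e.pt)
            for d in menu
            for e in events
        },
        duplicate_of=duplicate_of,
        n_cases=n,
    )
    return reports, truth


def expected_ror(config: SyntheticConfig, drug: str, pt: str) -> float:
    """Odds ratio implied by the generative process for one (drug, PT) pair.

    Computed analytically from the per-cell event probabilities: with
    drug-selection weights w_d and event probability p_d = baseline * rho(d),
    the fourfold cell probabilities are a = w_drug p_drug,
    b = w_drug (1 - p_drug), c = sum over other drugs of w_d p_d and d the
    complement; the expected ROR is (a/b)/(c/d).
    """
    names = [d.name for d in config.drug_menu]
    if drug not in names:
        raise KeyError(f"unknown drug {drug!r}")
    ev = {e.pt: e for e in config.event_menu}
    if pt not in ev:
        raise KeyError(f"unknown PT {pt!r}")
    baseline = ev[pt].baseline
    w = np.array([d.weight for d in config.drug_menu], dtype=float)
    w /= w.sum()
    p = np.array(
        [min(baseline * config.rho(d.name, pt), 1.0) for d in config.drug_menu]
    )
    target = np.array([d.name == drug for d in config.drug_menu])
    a = float(np.sum(w[target] * p[target]))
    b = float(np.sum(w[target] * (1 - p[target])))
    c = float(np.sum(w[~target] * p[~target]))
    d_ = float(np.sum(w[~target] * (1 - p[~target])))
    return (a / b) / (c / d_)


def write_dataset(
    reports: Sequence[AEReport],
    truth: GroundTruth,
    directory: str | Path,
    stem: str = "synthetic_reports",
) -> tuple[Path, Path]:
    """Write the dialect CSV plus a JSON ground-truth sidecar; returns both paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    csv_path = directory / f"{stem}.csv"
    truth_path = directory / f"{stem}.truth.json"
    write_reports(reports, csv_path)
    payload = {
        "rate_ratios": [
            {"drug": d, "pt": p, "rho": r} for (d, p), r in truth.rate_ratios.items()
        ],
        "duplicate_of": truth.duplicate_of,
        "n_cases": truth.n_cases,
    }
    truth_path.write_text(json.dumps(payload, indent=1), encoding="utf-8")
    return csv_path, truth_path
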
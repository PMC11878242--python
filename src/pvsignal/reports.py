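"""Spontaneous adverse-event report records: reading, validation, deduplication, filtering.

Reports follow the layout of OpenVigil-style FAERS extracts: one row per
report with a per-entry primary identifier, a case identifier shared by
successive versions of the same case, the FDA acceptance date, the drug
list with role codes, the MedDRA preferred-term reaction list, basic
demographics and the seriousness outcome codes.

The on-disk dialect is a UTF-8 CSV with a mandatory header and
semicolon-delimited multi-value fields::

    primary_id,case_id,fda_date,drugs,reactions,sex,age_years,country,outcomes
    1001,C1,2020-03-15,semaglutide:PS;metformin:SS,cholelithiasis;nausea,female,54,US,HO

``drugs`` holds ``name:ROLE`` pairs (roles PS, SS, C, I), ``fda_date`` is
ISO ``YYYY-MM-DD``, blank ``age_years`` means unknown.
"""

from __future__ import annotations

import csv
import datetime as _dt
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "AEReport",
    "DrugCatalog",
    "ReadResult",
    "Quarter",
    "ROLES",
    "OUTCOME_CODES",
    "SEX_VALUES",
    "default_drug_catalog",
    "read_reports",
    "write_reports",
    "deduplicate",
    "filter_window",
    "select_by_drug",
]

ROLES = frozenset({"PS", "SS", "C", "I"})
OUTCOME_CODES = frozenset({"DE", "LT", "HO", "DS", "CA", "RI", "OT"})
SEX_VALUES = frozenset({"male", "female", "not_specified", "unknown"})

DIALECT_COLUMNS = (
    "primary_id",
    "case_id",
    "fda_date",
    "drugs",
    "reactions",
    "sex",
    "age_years",
    "country",
    "outcomes",
)

_SEX_ALIASES = {
    "m": "male",
    "male": "male",
    "f": "female",
    "female": "female",
    "ns": "not_specified",
    "not_specified": "not_specified",
    "": "unknown",
    "unknown": "unknown",
    "u": "unknown",
}


@dataclass(frozen=True, slots=True)
class AEReport:
    """One spontaneous adverse-event report.

    ``primary_id`` identifies the entry; ``case_id`` is shared by all
    versions of one case. ``drugs`` is an ordered tuple of
    ``(generic_name, role)`` pairs, ``reactions`` a frozenset of MedDRA
    preferred terms, ``outcomes`` a frozenset of FAERS seriousness codes.
    ``age_years`` is ``None`` when unknown; ``country`` is ISO-3166
    alpha-2 or ``"unknown"``.
    """

    primary_id: str
    case_id: str
    fda_date: _dt.date
    drugs: tuple[tuple[str, str], ...]
    reactions: frozenset[str]
    sex: str = "unknown"
    age_years: float | None = None
    country: str = "unknown"
    outcomes: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.primary_id:
            raise ValueError("primary_id must be non-empty")
        if not self.case_id:
            raise ValueError("case_id must be non-empty")
        for name, role in self.drugs:
            if role not in ROLES:
                raise ValueError(f"unknown drug role {role!r} for {name!r}")
        if not self.reactions:
            raise ValueError("reactions set must be non-empty")
        if self.sex not in SEX_VALUES:
            raise ValueError(f"invalid sex {self.sex!r}")
        if self.age_years is not None and not (0 <= self.age_years <= 130):
            raise ValueError(f"age_years {self.age_years} outside [0, 130]")
        unknown = self.outcomes - OUTCOME_CODES
        if unknown:
            raise ValueError(f"unknown outcome codes {sorted(unknown)}")

    def drug_names(self, role: str | None = None) -> frozenset[str]:
        """Set of drug names on the report, optionally restricted to one role."""
        return frozenset(n for n, r in self.drugs if role is None or r == role)


class DrugCatalog:
    """Canonical generic names, drug classes and a case-insensitive synonym map.

    ``lookup`` is total: names absent from the catalog map to ``"other"``.
    Every canonical name belongs to exactly one class.
    """

    def __init__(
        self,
        class_map: Mapping[str, str],
        synonym_map: Mapping[str, str] | None = None,
    ) -> None:
        self.class_map = {k.strip().lower(): v for k, v in class_map.items()}
        self.synonym_map = {}
        for raw, canonical in (synonym_map or {}).items():
            canonical = canonical.strip().lower()
            if canonical not in self.class_map:
                raise ValueError(f"synonym target {canonical!r} not a canonical name")
            self.synonym_map[raw.strip().lower()] = canonical

    def lookup(self, name: str) -> str:
        """Canonical generic name for ``name``; ``"other"`` if not cataloged."""
        key = name.strip().lower()
        if key in self.class_map:
            return key
        return self.synonym_map.get(key, "other")

    def drug_class(self, name: str) -> str:
        """Class of a drug name (after synonym resolution); ``"other"`` if unknown."""
        return self.class_map.get(self.lookup(name), "other")

    def members(self, drug_class: str) -> frozenset[str]:
        return frozenset(n for n, c in self.class_map.items() if c == drug_class)


#: Brand/raw spellings commonly seen in spontaneous reports for the ten
#: incretin-based study drugs.
_SYNONYMS = {
    "byetta": "exenatide",
    "bydureon": "exenatide",
    "victoza": "liraglutide",
    "saxenda": "liraglutide",
    "trulicity": "dulaglutide",
    "adlyxin": "lixisenatide",
    "lyxumia": "lixisenatide",
    "ozempic": "semaglutide",
    "rybelsus": "semaglutide",
    "wegovy": "semaglutide",
    "mounjaro": "tirzepatide",
    "zepbound": "tirzepatide",
    "tradjenta": "linagliptin",
    "nesina": "alogliptin",
    "onglyza": "saxagliptin",
    "januvia": "sitagliptin",
}

GLP1_RA = (
    "exenatide",
    "liraglutide",
    "dulaglutide",
    "lixisenatide",
    "semaglutide",
    "tirzepatide",
)
DPP4_INHIBITOR = ("linagliptin", "alogliptin", "saxagliptin", "sitagliptin")


def default_drug_catalog() -> DrugCatalog:
    """Catalog of the six GLP-1 receptor agonists and four DPP-4 inhibitors."""
    class_map = {d: "GLP-1 RA" for d in GLP1_RA}
    class_map.update({d: "DPP-4 inhibitor" for d in DPP4_INHIBITOR})
    return DrugCatalog(class_map, _SYNONYMS)


@dataclass
class ReadResult:
    """Outcome of reading a report file: parsed reports plus quarantined rows."""

    reports: list[AEReport]
    quarantined: list[tuple[int, str, dict]] = field(default_factory=list)

    def __iter__(self):
        return iter(self.reports)

    def __len__(self) -> int:
        return len(self.reports)


def _parse_multivalue(raw: str) -> list[str]:
    return [part.strip() for part in raw.split(";") if part.strip()]


def _parse_row(row: dict, catalog: DrugCatalog | None) -> AEReport:
    try:
        fda_date = _dt.date.fromisoformat(row["fda_date"].strip())
    except ValueError as exc:
        raise ValueError(f"unparseable fda_date {row['fda_date']!r}: {exc}") from None
    drugs = []
    for entry in _parse_multivalue(row["drugs"]):
        name, sep, role = entry.rpartition(":")
        if not sep:
            raise ValueError(f"drug entry {entry!r} lacks a role code")
        name = name.strip().lower()
        if catalog is not None:
            name = catalog.lookup(name) if catalog.lookup(name) != "other" else name
        drugs.append((name, role.strip().upper()))
    age_raw = row.get("age_years", "").strip()
    age = float(age_raw) if age_raw else None
    sex_raw = row.get("sex", "").strip().lower()
    sex = _SEX_ALIASES.get(sex_raw)
    if sex is None:
        raise ValueError(f"invalid sex value {row['sex']!r}")
    country = row.get("country", "").strip().upper() or "unknown"
    if country in {"UNKNOWN", ""}:
        country = "unknown"
    return AEReport(
        primary_id=row["primary_id"].strip(),
        case_id=row["case_id"].strip(),
        fda_date=fda_date,
        drugs=tuple(drugs),
        reactions=frozenset(t.lower() for t in _parse_multivalue(row["reactions"])),
        sex=sex,
        age_years=age,
        country=country,
        outcomes=frozenset(o.upper() for o in _parse_multivalue(row.get("outcomes", ""))),
    )


def read_reports(
    path: str | Path,
    catalog: DrugCatalog | None = None,
    delimiter: str = ",",
) -> ReadResult:
    """Read a report file in the documented dialect.

    Drug names are normalized through ``catalog`` when given (brand names
    mapped to canonical generics). Malformed rows are quarantined with a
    reason rather than silently dropped; a missing mandatory column is a
    hard error.
    """
    path = Path(path)
    result = ReadResult(reports=[])
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter=delimiter)
        header = reader.fieldnames or []
        for col in DIALECT_COLUMNS:
            if col not in header:
                raise ValueError(f"missing mandatory column {col!r} in {path}")
        for idx, row in enumerate(reader, start=2):
            try:
                result.reports.append(_parse_row(row, catalog))
            except (ValueError, KeyError) as exc:
                result.quarantined.append((idx, str(exc), dict(row)))
    return result


def write_reports(reports: Iterable[AEReport], path: str | Path, delimiter: str = ",") -> None:
    """Write reports in the same dialect ``read_reports`` consumes (round-trips)."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        writer.writerow(DIALECT_COLUMNS)
        for r in reports:
            writer.writerow(
                [
                    r.primary_id,
                    r.case_id,
                    r.fda_date.isoformat(),
                    ";".join(f"{n}:{role}" for n, role in r.drugs),
                    ";".join(sorted(r.reactions)),
                    r.sex,
                    "" if r.age_years is None else format(r.age_years, "g"),
                    r.country,
                    ";".join(sorted(r.outcomes)),
                ]
            )


def write_quarantine(result: ReadResult, path: str | Path) -> None:
    """Write quarantined rows with their rejection reasons as CSV."""
    rows = [
        {"line": line, "reason": reason, **raw}
        for line, reason, raw in result.quarantined
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def _dedup_key(r: AEReport) -> tuple:
    pid = r.primary_id
    # numeric comparison when the identifier is all digits, else lexicographic;
    # the (0/1, ...) prefix keeps the two regimes mutually ordered and deterministic
    pid_key = (1, int(pid), "") if pid.isdigit() else (0, 0, pid)
    return (r.fda_date, pid_key)


def deduplicate(reports: Iterable[AEReport]) -> list[AEReport]:
    """Keep one entry per case: the latest FDA acceptance date, ties broken
    by the greater primary identifier.

    Output order follows the first occurrence of each case in the input,
    so the operation is deterministic and idempotent.
    """
    best: dict[str, AEReport] = {}
    order: list[str] = []
    for r in reports:
        cur = best.get(r.case_id)
        if cur is None:
            best[r.case_id] = r
            order.append(r.case_id)
        elif _dedup_key(r) > _dedup_key(cur):
            best[r.case_id] = r
    return [best[cid] for cid in order]


@dataclass(frozen=True, order=True)
class Quarter:
    """A calendar quarter, e.g. ``Quarter.parse("2013Q1")`` or ``"Q1 2013"``."""

    year: int
    quarter: int

    def __post_init__(self) -> None:
        if not 1 <= self.quarter <= 4:
            raise ValueError(f"quarter must be 1..4, got {self.quarter}")

    @classmethod
    def parse(cls, spec: "str | Quarter") -> "Quarter":
        if isinstance(spec, Quarter):
            return spec
        text = str(spec).strip()
        m = re.fullmatch(r"[Qq]([1-4])[\s\-/]*(\d{4})", text)
        if m:  # "Q1 2013" style -> "2013Q1"
            text = f"{m.group(2)}Q{m.group(1)}"
        try:
            period = pd.Period(text, freq="Q")
        except Exception as exc:
            raise ValueError(f"invalid quarter spec {spec!r}") from exc
        return cls(period.year, period.quarter)

    @property
    def start_date(self) -> _dt.date:
        return _dt.date(self.year, 3 * (self.quarter - 1) + 1, 1)

    @property
    def end_date(self) -> _dt.date:
        p = pd.Period(f"{self.year}Q{self.quarter}", freq="Q")
        return p.end_time.date()

    def __str__(self) -> str:
        return f"{self.year}Q{self.quarter}"


def filter_window(
    reports: Iterable[AEReport],
    start: str | Quarter,
    end: str | Quarter,
) -> list[AEReport]:
    """Retain reports whose FDA acceptance date falls in the closed quarter
    range ``[start, end]``."""
    start_q = Quarter.parse(start)
    end_q = Quarter.parse(end)
    if start_q > end_q:
        raise ValueError(f"window start {start_q} after end {end_q}")
    lo, hi = start_q.start_date, end_q.end_date
    return [r for r in reports if lo <= r.fda_date <= hi]


def select_by_drug(
    reports: Iterable[AEReport],
    drug_set: Iterable[str],
    role: str = "PS",
) -> list[AEReport]:
    """Reports carrying at least one drug from ``drug_set`` in the given role.

    The default role is the primary suspect (PS); a report naming a target
    drug only in a concomitant or interacting role is excluded.
    """
    drugs = frozenset(d.strip().lower() for d in drug_set)
    if not drugs:
        raise ValueError("drug_set must be non-empty")
    if role not in ROLES:
        raise ValueError(f"unknown role {role!r}")
    return [r for r in reports if drugs & r.drug_names(role)]
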
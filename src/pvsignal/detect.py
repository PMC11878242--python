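"""Assemble the four statistics and the joint decision for drug-event pairs."""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import pandas as pd

from .ebgm import MgpsHyperParams, ebgm_score, mgps_fit
from .reports import AEReport
from .stats import (
    BcpnnPriors,
    ContingencyTable,
    SignalMetrics,
    bcpnn_ic,
    evaluate_signal,
    prr_stats,
    ror_stats,
)

__all__ = ["compute_metrics", "analyze_pairs", "RESULT_COLUMNS"]


def compute_metrics(
    t: ContingencyTable,
    hyperparams: MgpsHyperParams,
    priors: BcpnnPriors | None = None,
    zero_cell: str = "nan",
    yates: bool = False,
    ebgm_quantile: float = 0.05,
) -> SignalMetrics:
    """All four disproportionality statistics for one fourfold table.

    ``hyperparams`` is the MGPS prior fitted over the whole dataset's
    drug-event grid (shrinkage is a database-level property, not a
    per-cell one).
    """
    import math as _math
    from .stats import PrrResult

    ror = ror_stats(t, zero_cell=zero_cell)
    try:
        prr = prr_stats(t, zero_cell=zero_cell, yates=yates)
    except ValueError:  # zero margin: ratio and chi-square undefined
        prr = PrrResult(_math.nan, _math.nan, _math.nan, _math.nan, defined=False)
    ic = bcpnn_ic(t, priors)
    if t.expected > 0:
        ebgm, ebgm05 = ebgm_score(t, hyperparams, quantile=ebgm_quantile)
    else:  # empty margin: no expected count, shrinkage score undefined
        ebgm = ebgm05 = _math.nan
    return SignalMetrics(
        n=t.a,
        ror=ror.estimate,
        ror_lo=ror.lower,
        ror_hi=ror.upper,
        prr=prr.prr,
        prr_lo=prr.lower,
        prr_hi=prr.upper,
        chi2=prr.chi2,
        ic=ic.ic,
        ic025=ic.ic025,
        ebgm=ebgm,
        ebgm05=ebgm05,
    )


RESULT_COLUMNS = [
    "drug",
    "event",
    "n",
    "ror",
    "ror_lo",
    "ror_hi",
    "prr",
    "prr_lo",
    "prr_hi",
    "chi2",
    "ic",
    "ic025",
    "ebgm",
    "ebgm05",
    "ror_pass",
    "prr_pass",
    "ic_pass",
    "ebgm_pass",
    "positive",
]


def analyze_pairs(
    reports: Sequence[AEReport],
    drug_sets: Mapping[str, Iterable[str]],
    event_sets: Mapping[str, Iterable[str]],
    role: str = "PS",
    hyperparams: MgpsHyperParams | None = None,
    priors: BcpnnPriors | None = None,
    zero_cell: str = "nan",
    ebgm_quantile: float = 0.05,
) -> pd.DataFrame:
    """Metrics and decisions for every (drug set, event set) pair.

    When ``hyperparams`` is omitted the MGPS prior is fitted on the full
    grid of pairs first. Returns one row per pair with all estimates,
    bounds and pass flags (columns in :data:`RESULT_COLUMNS`).
    """
    reports = list(reports)
    if not reports:
        raise ValueError("report set is empty; N must be positive")
    n_total = len(reports)
    # membership vectors once per drug set / event set; each pair's table
    # then follows from a and the margins (equivalent to build_table)
    role_names = [r.drug_names(role) for r in reports]
    reactions = [frozenset(rx.casefold() for rx in r.reactions) for r in reports]
    import numpy as _np

    exposed = {
        dn: _np.fromiter(
            (bool(frozenset(d.lower() for d in drugs) & s) for s in role_names),
            dtype=bool,
            count=n_total,
        )
        for dn, drugs in drug_sets.items()
    }
    has_event = {}
    for en, terms in event_sets.items():
        t = frozenset(x.casefold() for x in terms)
        if not t:
            raise ValueError("event_terms must be non-empty")
        has_event[en] = _np.fromiter(
            (bool(t & s) for s in reactions), dtype=bool, count=n_total
        )
    tables = {}
    for dn in drug_sets:
        e = exposed[dn]
        n_drug = int(e.sum())
        for en in event_sets:
            ev = has_event[en]
            a = int((e & ev).sum())
            n_event = int(ev.sum())
            tables[(dn, en)] = ContingencyTable(
                a, n_drug - a, n_event - a, n_total - n_drug - n_event + a
            )
    if hyperparams is None:
        hyperparams = mgps_fit(t for t in tables.values() if t.expected > 0)
    rows = []
    for (dn, en), t in tables.items():
        m = compute_metrics(
            t, hyperparams, priors, zero_cell=zero_cell, ebgm_quantile=ebgm_quantile
        )
        d = evaluate_signal(m)
        rows.append(
            {
                "drug": dn,
                "event": en,
                **{k: getattr(m, k) for k in SignalMetrics.__dataclass_fields__},
                "ror_pass": d.ror_pass,
                "prr_pass": d.prr_pass,
                "ic_pass": d.ic_pass,
                "ebgm_pass": d.ebgm_pass,
                "positive": d.positive,
            }
        )
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)
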
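"""Disproportionality statistics on the fourfold (2x2) report table.

For a (drug set, event set) pair each deduplicated report falls in exactly
one cell:

              event     other events
    drug        a            b
    other       c            d

with N = a+b+c+d. Four signal statistics are computed:

* ROR, the reporting odds ratio (a/b)/(c/d), with Woolf (log-normal) 95% CI;
* PRR, the proportional reporting ratio [a/(a+b)]/[c/(c+d)], with its
  log-normal 95% CI and the Pearson chi-square of the table;
* IC, the Bayesian confidence propagation neural network information
  component log2 P(drug,event)/(P(drug)P(event)), with its lower 2.5%
  bound IC025;
* EBGM, the empirical Bayes geometric mean of the shrunken observed/expected
  ratio (see :mod:`pvsignal.ebgm`).

A pair is a positive signal only when all four methods pass their
thresholds: n >= 3 with ROR lower bound > 1; chi-square >= 4 with PRR lower
bound > 1; IC025 > 0; EBGM05 > 2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal

import numpy as np
from scipy import special

from .reports import AEReport

__all__ = [
    "ContingencyTable",
    "BcpnnPriors",
    "SignalMetrics",
    "SignalDecision",
    "build_table",
    "ror_stats",
    "prr_stats",
    "bcpnn_ic",
    "bcpnn_ic_mc",
    "evaluate_signal",
]

Z95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass(frozen=True)
class ContingencyTable:
    """The fourfold table of a disproportionality analysis."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"cell {name} must be a non-negative integer, got {v}")
        if self.n_total == 0:
            raise ValueError("table must contain at least one report")

    @property
    def n_total(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def n_drug(self) -> int:
        return self.a + self.b

    @property
    def n_event(self) -> int:
        return self.a + self.c

    @property
    def expected(self) -> float:
        """Expected a-cell count under independence, (a+b)(a+c)/N."""
        return self.n_drug * self.n_event / self.n_total

    def with_continuity(self, k: float = 0.5) -> "ContingencyTableF":
        return ContingencyTableF(self.a + k, self.b + k, self.c + k, self.d + k)


@dataclass(frozen=True)
class ContingencyTableF:
    """Continuity-corrected table (real-valued cells)."""

    a: float
    b: float
    c: float
    d: float

    @property
    def n_total(self) -> float:
        return self.a + self.b + self.c + self.d


def build_table(
    reports: Iterable[AEReport],
    target_drugs: Iterable[str],
    event_terms: Iterable[str],
    role: str = "PS",
) -> ContingencyTable:
    """Classify each report into one cell of the fourfold table.

    Exposure means carrying a target drug in the given role (primary
    suspect by default); the event means the reaction set intersects
    ``event_terms``. A report counts once regardless of how many drugs or
    matching reactions it lists.
    """
    drugs = frozenset(d.strip().lower() for d in target_drugs)
    terms = frozenset(t.strip().casefold() for t in event_terms)
    if not terms:
        raise ValueError("event_terms must be non-empty")
    a = b = c = d = 0
    n = 0
    for r in reports:
        n += 1
        exposed = bool(drugs & r.drug_names(role))
        event = any(rx.strip().casefold() in terms for rx in r.reactions)
        if exposed and event:
            a += 1
        elif exposed:
            b += 1
        elif event:
            c += 1
        else:
            d += 1
    if n == 0:
        raise ValueError("report set is empty; N must be positive")
    return ContingencyTable(a, b, c, d)


@dataclass(frozen=True)
class EstimateCI:
    """A point estimate with 95% bounds; ``defined`` is False when a zero
    cell makes the large-sample interval undefined."""

    estimate: float
    lower: float
    upper: float
    defined: bool = True

    def __iter__(self):
        return iter((self.estimate, self.lower, self.upper))


ZeroCellPolicy = Literal["nan", "haldane"]


def _resolve_cells(t: ContingencyTable, zero_cell: ZeroCellPolicy):
    cells = (t.a, t.b, t.c, t.d)
    if min(cells) > 0:
        return cells, True
    if zero_cell == "haldane":
        tf = t.with_continuity(0.5)
        return (tf.a, tf.b, tf.c, tf.d), True
    return cells, False


def ror_stats(
    t: ContingencyTable, zero_cell: ZeroCellPolicy = "nan"
) -> EstimateCI:
    """Reporting odds ratio with Woolf 95% confidence bounds.

    ROR = (a/b)/(c/d); CI = exp(ln ROR +/- 1.96 sqrt(1/a+1/b+1/c+1/d)).
    With a zero cell the default policy returns an undefined-with-flag
    result; ``zero_cell="haldane"`` applies the +0.5 correction instead.
    """
    (a, b, c, d), ok = _resolve_cells(t, zero_cell)
    if not ok:
        return EstimateCI(math.nan, math.nan, math.nan, defined=False)
    ror = (a / b) / (c / d)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return EstimateCI(ror, ror * math.exp(-Z95 * se), ror * math.exp(Z95 * se))


@dataclass(frozen=True)
class PrrResult:
    prr: float
    lower: float
    upper: float
    chi2: float
    defined: bool = True


def pearson_chi2(t: ContingencyTable, yates: bool = False) -> float:
    """Pearson chi-square of the 2x2 table, N(ad-bc)^2 / product of margins.

    No continuity correction by default; ``yates=True`` subtracts N/2 from
    |ad-bc| before squaring.
    """
    a, b, c, d = t.a, t.b, t.c, t.d
    n = t.n_total
    margins = (a + b) * (c + d) * (a + c) * (b + d)
    if margins == 0:
        raise ValueError("chi-square undefined: a margin of the table is zero")
    dev = abs(a * d - b * c)
    if yates:
        dev = max(dev - n / 2, 0.0)
    return n * dev * dev / margins


def prr_stats(
    t: ContingencyTable,
    zero_cell: ZeroCellPolicy = "nan",
    yates: bool = False,
) -> PrrResult:
    """Proportional reporting ratio with 95% CI and Pearson chi-square.

    PRR = [a/(a+b)] / [c/(c+d)];
    CI = exp(ln PRR +/- 1.96 sqrt(1/a - 1/(a+b) + 1/c - 1/(c+d))).
    Zero margins raise; a zero a- or c-cell yields an undefined-with-flag
    interval under the default policy.
    """
    if t.n_drug == 0 or t.c + t.d == 0 or t.n_event == 0 or t.b + t.d == 0:
        raise ValueError("PRR undefined: a margin of the table is zero")
    chi2 = pearson_chi2(t, yates=yates)
    a, b, c, d = t.a, t.b, t.c, t.d
    if a == 0:
        return PrrResult(0.0, math.nan, math.nan, chi2, defined=False)
    if c == 0:
        if zero_cell == "haldane":
            a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        else:
            return PrrResult(math.inf, math.nan, math.nan, chi2, defined=False)
    prr = (a / (a + b)) / (c / (c + d))
    se = math.sqrt(1 / a - 1 / (a + b) + 1 / c - 1 / (c + d))
    return PrrResult(prr, prr * math.exp(-Z95 * se), prr * math.exp(Z95 * se), chi2)


@dataclass(frozen=True)
class BcpnnPriors:
    """Pseudo-counts of the BCPNN Beta priors.

    ``alpha1``/``alpha`` parametrize the drug margin prior
    Beta(alpha1, alpha - alpha1), ``beta1``/``beta`` the event margin, and
    ``gamma11`` the joint cell; the joint prior total is calibrated so the
    prior expectation of the cell equals the product of the posterior
    margin expectations. Defaults (1, 2, 1, 2, 1) are the standard choice.
    """

    alpha1: float = 1.0
    alpha: float = 2.0
    beta1: float = 1.0
    beta: float = 2.0
    gamma11: float = 1.0

    def __post_init__(self) -> None:
        for f in ("alpha1", "alpha", "beta1", "beta", "gamma11"):
            if getattr(self, f) <= 0:
                raise ValueError(f"prior {f} must be strictly positive")
        if self.alpha <= self.alpha1 or self.beta <= self.beta1:
            raise ValueError("margin prior totals must exceed their first parameter")


def _bcpnn_posterior_params(t: ContingencyTable, priors: BcpnnPriors):
    """Parameters of the three independent Beta posteriors (cell, margins)."""
    n, n1, m1, nn = t.a, t.n_drug, t.n_event, t.n_total
    p = priors
    gamma = p.gamma11 * (nn + p.alpha) * (nn + p.beta) / ((n1 + p.alpha1) * (m1 + p.beta1))
    cell = (n + p.gamma11, nn - n + gamma - p.gamma11)
    drug = (n1 + p.alpha1, nn - n1 + p.alpha - p.alpha1)
    event = (m1 + p.beta1, nn - m1 + p.beta - p.beta1)
    return cell, drug, event


@dataclass(frozen=True)
class IcResult:
    ic: float
    ic025: float
    variance: float


def bcpnn_ic(
    t: ContingencyTable,
    priors: BcpnnPriors | None = None,
    moment_method: Literal["exact", "delta"] = "delta",
) -> IcResult:
    """Information component of the BCPNN with its lower 95% bound.

    The posterior of (cell probability, drug margin, event margin) is a
    product of independent Beta distributions; IC = log2 p11/(p1 p2).
    ``moment_method="delta"`` (default) is the classical closed form built
    from ratios of posterior means; ``"exact"`` uses the exact posterior
    log-moments (digamma/trigamma) of the same posterior — the two agree
    to O(1/n). IC025 is the normal approximation E(IC) - 1.96 sqrt(V(IC));
    finite for any non-negative cells.
    """
    priors = priors or BcpnnPriors()
    cell, drug, event = _bcpnn_posterior_params(t, priors)
    ln2 = math.log(2.0)
    if moment_method == "exact":
        ic = (
            special.digamma(cell[0])
            - special.digamma(sum(cell))
            - special.digamma(drug[0])
            + special.digamma(sum(drug))
            - special.digamma(event[0])
            + special.digamma(sum(event))
        ) / ln2
        var = (
            special.polygamma(1, cell[0])
            - special.polygamma(1, sum(cell))
            + special.polygamma(1, drug[0])
            - special.polygamma(1, sum(drug))
            + special.polygamma(1, event[0])
            - special.polygamma(1, sum(event))
        ) / ln2**2
    elif moment_method == "delta":
        ic = (
            math.log(cell[0] / sum(cell))
            - math.log(drug[0] / sum(drug))
            - math.log(event[0] / sum(event))
        ) / ln2
        var = (
            cell[1] / (cell[0] * (1 + sum(cell)))
            + drug[1] / (drug[0] * (1 + sum(drug)))
            + event[1] / (event[0] * (1 + sum(event)))
        ) / ln2**2
    else:
        raise ValueError(f"unknown moment_method {moment_method!r}")
    return IcResult(ic, ic - Z95 * math.sqrt(var), var)


def bcpnn_ic_mc(
    t: ContingencyTable,
    priors: BcpnnPriors | None = None,
    n_draws: int = 100_000,
    rng: np.random.Generator | int | None = None,
    quantile: float = 0.025,
) -> tuple[float, float, float]:
    """Monte-Carlo posterior of the information component.

    Samples the three independent Beta posteriors and returns the sample
    mean, the ``quantile`` posterior quantile of IC, and the sample
    variance. Used to validate the closed form and, optionally, as an
    alternative IC025 (posterior quantile rather than normal
    approximation).
    """
    rng = np.random.default_rng(rng)
    priors = priors or BcpnnPriors()
    cell, drug, event = _bcpnn_posterior_params(t, priors)
    p11 = rng.beta(*cell, size=n_draws)
    p1 = rng.beta(*drug, size=n_draws)
    p2 = rng.beta(*event, size=n_draws)
    ic = np.log2(p11 / (p1 * p2))
    return float(ic.mean()), float(np.quantile(ic, quantile)), float(ic.var(ddof=1))


@dataclass(frozen=True)
class SignalMetrics:
    """All four disproportionality statistics for one (drug set, event set)."""

    n: int
    ror: float
    ror_lo: float
    ror_hi: float
    prr: float
    prr_lo: float
    prr_hi: float
    chi2: float
    ic: float
    ic025: float
    ebgm: float
    ebgm05: float


@dataclass(frozen=True)
class SignalDecision:
    """Per-method threshold flags and the joint positive-signal call."""

    ror_pass: bool
    prr_pass: bool
    ic_pass: bool
    ebgm_pass: bool

    @property
    def positive(self) -> bool:
        return self.ror_pass and self.prr_pass and self.ic_pass and self.ebgm_pass


def evaluate_signal(
    m: SignalMetrics,
    min_n: int = 3,
    ebgm05_threshold: float = 2.0,
) -> SignalDecision:
    """Apply the joint threshold rule.

    ROR passes when n >= 3 and its lower bound exceeds 1; PRR when
    chi-square >= 4 and its lower bound exceeds 1; BCPNN when IC025 > 0;
    EBGM when EBGM05 > 2. Undefined (NaN) bounds fail their criterion. The
    pair is a positive signal only when all four pass.
    """

    def _gt(x: float, thr: float) -> bool:
        return bool(x > thr) and not math.isnan(x)

    return SignalDecision(
        ror_pass=m.n >= min_n and _gt(m.ror_lo, 1.0),
        prr_pass=m.chi2 >= 4.0 and _gt(m.prr_lo, 1.0),
        ic_pass=_gt(m.ic025, 0.0),
        ebgm_pass=_gt(m.ebgm05, ebgm05_threshold),
    )
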
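"""Multi-item gamma-Poisson shrinker (MGPS) and the EBGM score.

Each drug-event cell of a spontaneous-report database contributes an
observed count ``n`` and an expected count ``E = (a+b)(a+c)/N`` from the
table margins. The MGPS model treats ``n ~ Poisson(lambda * E)`` with the
relative reporting rate ``lambda`` drawn from a two-component gamma
mixture prior::

    lambda ~ w * Gamma(a1, b1) + (1 - w) * Gamma(a2, b2)    (shape, rate)

whose five hyperparameters are estimated by maximizing the marginal
(negative-binomial mixture) likelihood over all cells of the database.
The cell posterior is again a gamma mixture; EBGM = exp(E[ln lambda]) is
the empirical Bayes geometric mean of the shrunken observed/expected
ratio, and EBGM05 its 5th posterior percentile (the conventional lower
signal bound).

:class:`GammaPoissonShrinker` is a scikit-learn style estimator
(``fit`` / ``predict`` / ``get_params``) over an ``(n_cells, 2)`` array of
``[n, E]`` columns; :func:`mgps_fit` and :func:`ebgm_score` are thin
functional wrappers working on contingency tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Callable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats as sps
from sklearn.base import BaseEstimator

from .reports import AEReport
from .stats import ContingencyTable

__all__ = [
    "MgpsHyperParams",
    "GammaPoissonShrinker",
    "mgps_fit",
    "ebgm_score",
    "observed_expected",
]

#: Conventional starting point for the hyperparameter search
#: (a1, b1, a2, b2, w).
DEFAULT_INIT = (0.2, 0.1, 2.0, 4.0, 1.0 / 3.0)


@dataclass(frozen=True)
class MgpsHyperParams:
    """Hyperparameters of the two-component gamma mixture prior."""

    a1: float
    b1: float
    a2: float
    b2: float
    w: float

    def __post_init__(self) -> None:
        if min(self.a1, self.b1, self.a2, self.b2) <= 0:
            raise ValueError("gamma shapes and rates must be strictly positive")
        if not 0 < self.w < 1:
            raise ValueError(f"mixture weight must lie in (0, 1), got {self.w}")

    @property
    def prior_mean(self) -> float:
        return self.w * self.a1 / self.b1 + (1 - self.w) * self.a2 / self.b2

    @property
    def prior_geometric_mean(self) -> float:
        ln = self.w * (special.digamma(self.a1) - math.log(self.b1)) + (
            1 - self.w
        ) * (special.digamma(self.a2) - math.log(self.b2))
        return math.exp(ln)


def _log_nb(n, a, b, E):
    """Log marginal P(n | a, b, E): negative binomial with size a, p = b/(b+E)."""
    return (
        special.gammaln(a + n)
        - special.gammaln(a)
        - special.gammaln(n + 1.0)
        + a * (np.log(b) - np.log(b + E))
        + n * (np.log(E) - np.log(b + E))
    )


def _neg_loglik(theta, n, E):
    la1, lb1, la2, lb2, logit_w = theta
    a1, b1, a2, b2 = np.exp([la1, lb1, la2, lb2])
    log_w = -np.logaddexp(0.0, -logit_w)       # log sigmoid
    log_1mw = -np.logaddexp(0.0, logit_w)
    lp = np.logaddexp(log_w + _log_nb(n, a1, b1, E), log_1mw + _log_nb(n, a2, b2, E))
    return -float(lp.sum())


class GammaPoissonShrinker(BaseEstimator):
    """Empirical-Bayes gamma-Poisson shrinkage estimator for report counts.

    Parameters
    ----------
    a1, b1, a2, b2, w
        Starting hyperparameters for the marginal-likelihood maximization
        (also the prior used by :meth:`predict` before :meth:`fit`).
    quantile
        Lower posterior quantile reported alongside EBGM (0.05 by
        convention; 0.025 gives a two-sided-style bound).
    max_iter
        Iteration cap for the quasi-Newton (L-BFGS-B) search.

    Attributes
    ----------
    a1_, b1_, a2_, b2_, w_ : fitted hyperparameters
    loglik_ : log marginal likelihood at the optimum
    loglik_init_ : log marginal likelihood at the starting point
    n_iter_ : iterations used
    trace_ : list of (iteration, negative log-likelihood) pairs
    """

    def __init__(
        self,
        a1: float = DEFAULT_INIT[0],
        b1: float = DEFAULT_INIT[1],
        a2: float = DEFAULT_INIT[2],
        b2: float = DEFAULT_INIT[3],
        w: float = DEFAULT_INIT[4],
        quantile: float = 0.05,
        max_iter: int = 1000,
    ) -> None:
        self.a1 = a1
        self.b1 = b1
        self.a2 = a2
        self.b2 = b2
        self.w = w
        self.quantile = quantile
        self.max_iter = max_iter

    # -- fitting -----------------------------------------------------------

    @staticmethod
    def _validate(X) -> tuple[np.ndarray, np.ndarray]:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError("X must be an (n_cells, 2) array of [n, E] columns")
        if X.shape[0] < 2:
            raise ValueError("need at least two cells to estimate a mixture prior")
        n, E = X[:, 0], X[:, 1]
        if np.any(n < 0):
            raise ValueError("observed counts must be non-negative")
        if np.any(E <= 0):
            raise ValueError("expected counts must be strictly positive")
        return n, E

    def fit(self, X, y=None) -> "GammaPoissonShrinker":
        """Maximize the negative-binomial-mixture marginal likelihood.

        ``X`` is an ``(n_cells, 2)`` array with observed and expected
        counts per cell; at least ~50 cells are recommended for a stable
        five-parameter fit. The search is deterministic given the data and
        starting point; non-convergence raises with the optimizer trace
        attached.
        """
        n, E = self._validate(X)
        h0 = MgpsHyperParams(self.a1, self.b1, self.a2, self.b2, self.w)
        theta0 = np.array(
            [
                math.log(h0.a1),
                math.log(h0.b1),
                math.log(h0.a2),
                math.log(h0.b2),
                math.log(h0.w / (1 - h0.w)),
            ]
        )
        self.loglik_init_ = -_neg_loglik(theta0, n, E)
        trace: list[tuple[int, float]] = []

        def _cb(xk):
            trace.append((len(trace) + 1, _neg_loglik(xk, n, E)))

        # L-BFGS-B on log/logit-transformed parameters; the bounds keep the
        # weight away from exact 0/1 when the mixture collapses onto one
        # component (a flat, non-identifiable direction of the likelihood)
        bounds = [(-12.0, 12.0)] * 4 + [(-15.0, 15.0)]
        res = optimize.minimize(
            _neg_loglik,
            theta0,
            args=(n, E),
            method="L-BFGS-B",
            bounds=bounds,
            callback=_cb,
            options={"maxiter": self.max_iter},
        )
        self.trace_ = trace
        if not res.success:
            err = RuntimeError(f"MGPS hyperparameter fit did not converge: {res.message}")
            err.trace = trace  # type: ignore[attr-defined]
            raise err
        la1, lb1, la2, lb2, logit_w = res.x
        self.a1_, self.b1_, self.a2_, self.b2_ = np.exp([la1, lb1, la2, lb2])
        self.w_ = float(special.expit(logit_w))
        self.loglik_ = -float(res.fun)
        self.n_iter_ = int(res.nit)
        return self

    @property
    def hyperparams_(self) -> MgpsHyperParams:
        return MgpsHyperParams(self.a1_, self.b1_, self.a2_, self.b2_, self.w_)

    def _current_hyperparams(self) -> MgpsHyperParams:
        if hasattr(self, "a1_"):
            return self.hyperparams_
        return MgpsHyperParams(self.a1, self.b1, self.a2, self.b2, self.w)

    # -- scoring -----------------------------------------------------------

    def predict(self, X) -> np.ndarray:
        """EBGM per cell of an ``(n_cells, 2)`` array of [n, E]."""
        X = np.asarray(X, dtype=float)
        h = self._current_hyperparams()
        return np.array([_ebgm_point(n, E, h) for n, E in X])

    def interval(self, X) -> np.ndarray:
        """Per-cell (EBGM, lower-quantile) pairs at ``self.quantile``."""
        X = np.asarray(X, dtype=float)
        h = self._current_hyperparams()
        return np.array([_ebgm_pair(n, E, h, self.quantile) for n, E in X])

    def score(self, X, y=None) -> float:
        """Mean log marginal likelihood per cell (higher is better)."""
        n, E = self._validate(X)
        h = self._current_hyperparams()
        theta = np.array(
            [
                math.log(h.a1),
                math.log(h.b1),
                math.log(h.a2),
                math.log(h.b2),
                math.log(h.w / (1 - h.w)),
            ]
        )
        return -_neg_loglik(theta, n, E) / len(n)


def _posterior_mixture(n: float, E: float, h: MgpsHyperParams):
    """Posterior component weights and gamma parameters for one cell."""
    lw = np.array([math.log(h.w), math.log1p(-h.w)])
    lm = np.array(
        [float(_log_nb(n, h.a1, h.b1, E)), float(_log_nb(n, h.a2, h.b2, E))]
    )
    logq = lw + lm
    logq -= special.logsumexp(logq)
    q = np.exp(logq)
    shapes = np.array([h.a1 + n, h.a2 + n])
    rates = np.array([h.b1 + E, h.b2 + E])
    return q, shapes, rates


def _ebgm_point(n: float, E: float, h: MgpsHyperParams) -> float:
    q, shapes, rates = _posterior_mixture(n, E, h)
    e_ln = float(np.sum(q * (special.digamma(shapes) - np.log(rates))))
    return math.exp(e_ln)


def _mixture_cdf(x: float, q, shapes, rates) -> float:
    return float(np.sum(q * sps.gamma.cdf(x, a=shapes, scale=1.0 / rates)))


def _mixture_quantile(p: float, q, shapes, rates, rtol: float = 1e-10) -> float:
    comp_q = sps.gamma.ppf(p, a=shapes, scale=1.0 / rates)
    lo = float(comp_q.min())
    hi = float(sps.gamma.ppf(min(p * 2 + 0.5, 0.9999999), a=shapes, scale=1.0 / rates).max())
    # widen until the bracket straddles the root (cheap; CDF is monotone)
    while _mixture_cdf(lo, q, shapes, rates) > p and lo > 1e-300:
        lo /= 4.0
    while _mixture_cdf(hi, q, shapes, rates) < p:
        hi *= 4.0
    return float(
        optimize.brentq(
            lambda x: _mixture_cdf(x, q, shapes, rates) - p, lo, hi, rtol=rtol
        )
    )


def _ebgm_pair(n: float, E: float, h: MgpsHyperParams, quantile: float):
    q, shapes, rates = _posterior_mixture(n, E, h)
    e_ln = float(np.sum(q * (special.digamma(shapes) - np.log(rates))))
    return math.exp(e_ln), _mixture_quantile(quantile, q, shapes, rates)


def _tables_to_ne(tables: Iterable[ContingencyTable]) -> np.ndarray:
    rows = [(t.a, t.expected) for t in tables]
    return np.asarray(rows, dtype=float)


def mgps_fit(
    tables: Iterable[ContingencyTable],
    init: Sequence[float] = DEFAULT_INIT,
    max_iter: int = 1000,
) -> MgpsHyperParams:
    """Fit the MGPS prior over all drug-event cells of a dataset.

    ``tables`` supplies one fourfold table per cell; observed counts are
    the a-cells and expected counts come from each table's margins.
    """
    est = GammaPoissonShrinker(*init, max_iter=max_iter)
    est.fit(_tables_to_ne(tables))
    return est.hyperparams_


def ebgm_score(
    t: "ContingencyTable | tuple[float, float]",
    h: MgpsHyperParams,
    quantile: float = 0.05,
) -> tuple[float, float]:
    """EBGM and its lower posterior quantile for one cell.

    Accepts a contingency table (n = a, E from margins) or a bare
    ``(n, E)`` pair. The quantile (EBGM05 at the default 0.05) is found by
    bracketed root finding on the posterior mixture CDF to 1e-10 relative
    tolerance.
    """
    if isinstance(t, ContingencyTable):
        n, E = float(t.a), t.expected
    else:
        n, E = float(t[0]), float(t[1])
    if E <= 0:
        raise ValueError("expected count must be strictly positive")
    return _ebgm_pair(n, E, h, quantile)


def observed_expected(
    reports: Sequence[AEReport],
    drug_sets: Mapping[str, Iterable[str]],
    event_sets: Mapping[str, Iterable[str]],
    role: str = "PS",
    stratify_by: Callable[[AEReport], object] | None = None,
) -> pd.DataFrame:
    """Observed and expected counts for every (drug set, event set) cell.

    Expected counts use the unstratified margins E = (a+b)(a+c)/N by
    default; with ``stratify_by`` (a report -> stratum key function) the
    Mantel-Haenszel style sum of per-stratum expectations is used instead.
    Returns a DataFrame with columns drug, event, n, expected.
    """
    reports = list(reports)
    drug_sets = {k: frozenset(d.lower() for d in v) for k, v in drug_sets.items()}
    event_sets = {k: frozenset(t.casefold() for t in v) for k, v in event_sets.items()}
    strata_keys = (
        [None] * len(reports) if stratify_by is None else [stratify_by(r) for r in reports]
    )
    rows = []
    for dname, drugs in drug_sets.items():
        exposed = np.array([bool(drugs & r.drug_names(role)) for r in reports])
        for ename, terms in event_sets.items():
            event = np.array(
                [any(rx.casefold() in terms for rx in r.reactions) for r in reports]
            )
            n_obs = int(np.sum(exposed & event))
            expected = 0.0
            for key in set(strata_keys):
                mask = np.array([k == key for k in strata_keys])
                n_s = int(mask.sum())
                if n_s:
                    expected += exposed[mask].sum() * event[mask].sum() / n_s
            rows.append({"drug": dname, "event": ename, "n": n_obs, "expected": expected})
    return pd.DataFrame(rows)
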
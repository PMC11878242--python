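# Methods

## Data model and cleaning

A spontaneous report carries a per-entry primary identifier, a case
identifier shared by successive versions of the same case, the FDA
acceptance date, an ordered drug list with role codes (PS primary
suspect, SS secondary suspect, C concomitant, I interacting), a set of
MedDRA preferred terms (PTs), sex, age, country and FAERS seriousness
outcome codes (DE, LT, HO, DS, CA, RI, OT).

Deduplication keeps, within each case identifier, the entry with the most
recent FDA acceptance date; ties are broken by the greater primary
identifier. The tiebreaker compares identifiers numerically when both are
all-digit strings and lexicographically otherwise, so the operation is
deterministic for any identifier scheme. Output preserves the first
occurrence order of cases, which makes deduplication idempotent.

Window filtering is by calendar quarter, closed on both ends, keyed on
the FDA acceptance date (the only date the record model carries).
Exposure selection requires the target drug in the primary-suspect role
by default; the role is a parameter. A report naming drugs from two study
classes as primary suspect is retained in both class cohorts.

## SMQ mapping

SMQ catalogs are trees; a node's effective term set is the union of its
own terms and all descendants' terms, so membership rolls up
monotonically from sub-queries to their parents. Matching is exact string
equality on case-folded, trimmed PT text — no fuzzy matching, no LLT→PT
coding. Each term carries a narrow/broad scope tag; queries include all
terms by default because the scope used by upstream extraction tools is
often unrecorded, and the choice is written to run metadata. A report
matches an SMQ at most once regardless of how many of its reactions hit
the term set; the counting unit throughout the package is the report, not
the drug–event pair.

The bundled biliary-disorders catalog reproduces the standard hierarchy
topology (one root, nine sub-queries) with synthetic term lists, because
licensed MedDRA term lists cannot be redistributed. Analyses of real
extracts should load a user-supplied catalog in the same format.

## The four statistics

All four statistics are computed on the report-level fourfold table. The
comparator universe is every loaded report not exposed to the target drug
set, so absolute values depend on the breadth of the loaded extract; this
matches standard practice.

**ROR and PRR.** Point estimates as in the README; confidence intervals
are the usual log-normal (Woolf) forms at z = 1.96. The Pearson χ² is
computed without continuity correction by default; a Yates-corrected
variant is available by flag. Zero cells make the large-sample intervals
undefined: the default policy returns NaN bounds carrying an explicit
`defined=False` flag (undefined bounds always fail their signal
criterion), and a Haldane–Anscombe +0.5 correction can be selected
instead. The policy in force is recorded in run metadata.

**BCPNN information component.** The posterior of (cell probability,
drug-margin probability, event-margin probability) is a product of three
independent Beta distributions with pseudo-count priors
α₁ = β₁ = γ₁₁ = 1, α = β = 2, the joint prior total calibrated so the
prior cell expectation equals the product of the posterior margin
expectations. Two closed forms for E(IC) and V(IC) are provided:

- `delta` (default): the classical expressions built from ratios of
  posterior means — the form in which the statistic is usually published
  and thresholded;
- `exact`: the exact log-moments of the same posterior via
  digamma/trigamma functions.

The two agree to O(1/n) and never differ at the precision signal
thresholds are applied; the exact form is what a Monte-Carlo sampler of
the posterior converges to, and the validation suite exercises exactly
that agreement. IC025 is the normal approximation E(IC) − 1.96·√V(IC),
finite for any non-negative cells; a Monte-Carlo posterior-quantile
alternative (`bcpnn_ic_mc`) exists for validation and sensitivity checks.

**MGPS / EBGM.** Observed cell counts are modelled as n ~ Poisson(λE)
with expected counts E from the unstratified table margins by default; an
optional stratification key computes E as the sum of per-stratum
expectations (off by default). The prior on λ is a two-component gamma
mixture; its five hyperparameters maximize the negative-binomial-mixture
marginal likelihood over all cells of the analyzed grid, starting from
the conventional (0.2, 0.1, 2, 4, 1/3). The search runs in log/logit
space with L-BFGS-B; box bounds (±12 on log shapes/rates, ±15 on the
weight logit) keep the weight away from exact 0/1, because when the data
support a single component the mixture weight is driven to a boundary
along a flat, non-identifiable likelihood direction. The optimizer trace
is retained on the fitted estimator, the fit is deterministic given data
and configuration, and non-convergence raises with the trace attached.
Under a single-gamma truth the individual components are only weakly
identified — the dominant component's mean and the mixture mean are the
stable functionals, which is what the recovery tests assert.

The cell posterior is again a two-component gamma mixture; EBGM =
exp E[ln λ] uses the digamma closed form, and the lower bound solves the
posterior mixture CDF by bracketed root finding to 1e-10 relative
tolerance. The bound is named EBGM05 and defaults to the 5th percentile,
matching the conventional name; a 2.5% variant is selectable and the
quantile in force is recorded per run. Cells with E = 0 (an empty margin)
have no defined shrinkage score and are reported as NaN, failing the EBGM
criterion.

**Joint decision.** A pair is positive only when all four criteria hold
(pure conjunction): n ≥ 3 with ROR lower bound > 1; χ² ≥ 4 with PRR lower
bound > 1; IC025 > 0; EBGM05 > 2.

## Descriptive layer

Percents are rounded half-up to two decimals, the presentation convention
of report-characteristic tables. Age bins are <19, 19–45, 46–65, >65 with
inclusive boundaries as written (a fractional age between 45 and 46 falls
in 19–45 so the bins cover all of [0, 130]); unknown ages form their own
category, excluded from subgroup strata but retained in totals. Median
age and quartiles use known ages only.

The serious-outcome rule defaults to the five classical codes (death,
life-threatening, hospitalization, disability, congenital anomaly) plus
required-intervention, the composition under which published seriousness
totals for this kind of cohort add up; the strict five-code rule is
selectable. The "other serious" code OT is outside both rules. Rate
comparisons across drugs use the r×2 Pearson χ² with df = r − 1.

Subgroup disproportionality restricts both the exposed and the comparator
reports to each sex×age stratum before rebuilding the table. The EBGM
shrinkage prior is fitted once on the full dataset's drug–event grid and
shared across strata — shrinkage is a database-level property and
per-stratum grids are too small to re-estimate it. Strata with an empty
a-cell are reported as no-data rows rather than zeros.

## Synthetic report generator

The generator emulates an OpenVigil-style extract over the Q1 2013 –
Q1 2024 window: each report draws one primary-suspect drug from a
weighted menu (ten incretin-based study drugs plus five high-volume
background drugs carrying most of the reporting mass), then draws each
menu term independently with probability baseline × ρ(drug, term), where
ρ is the planted relative reporting rate (1 everywhere except configured
spikes). Defaults plant a single ρ = 4 spike on a biliary term with
baseline 0.005 in 200,000 reports. Demographics follow the study
cohort's printed marginals qualitatively: a 55/38% female/male split with
small not-specified and unknown fractions, ages from a two-component
normal mixture (means 54 and 72, truncated to [0, 120]) with 40% missing,
US-dominant country weights. Outcomes follow a latent severity class
(P(serious) = 0.55, then one code from a weighted menu; non-serious
reports get OT or no code). A configurable fraction of reports (10% by
default) gains a duplicate entry with the same case identifier, a fresh
higher primary identifier and an advanced date — the exact situation the
deduplication rules resolve, with the links recorded as ground truth.

`expected_ror` returns the odds ratio implied analytically by the
generative process, enabling unbiasedness checks; reports that draw no
term receive a filler term outside every analyzed set, so the closed form
stays exact. Deliberate simplifications: terms are independent given the
drug (no co-reporting correlation), one suspect drug per report (a
concomitant drug is added with probability 0.2 but plays no causal role),
no country- or time-varying reporting dynamics, no drug interactions.
Passing recovery tests therefore demonstrates correctness of the
statistical machinery under the stated model, not robustness to
correlated reporting or confounding in real data.

## Validation problem sizes

The test suite validates the frequentist statistics against an
independent general-purpose 2×2 oracle on 1,000 random tables (1e-10
relative), the BCPNN moments against 1e5-draw posterior sampling on 20
tables (within 3 Monte-Carlo standard errors), EBGM against direct
numerical quadrature of the posterior on 50 cells (4 significant
digits), MGPS prior recovery on 5,000 simulated cells (component mean
within 15%), and end-to-end signal recovery on ten replicate 200,000
report datasets (planted spike flagged in every replicate, ≤5% of null
pairs flagged). `scripts/acceptance.py` repeats these computations,
using three replicate datasets for the end-to-end stage, and reports the
measured errors and rates.

## Known limitations

Signal statistics quantify reporting disproportionality, not risk;
confounding by indication, stimulated reporting and duplicate cases that
do not share a case identifier are outside the package's scope. The
BCPNN IC025 uses a normal approximation whose coverage degrades for very
sparse cells (the Monte-Carlo quantile mode is available there). The
MGPS likelihood is multi-modal in pathological datasets; the fit is
deterministic from its fixed starting point, and alternative starts can
be supplied through the estimator's parameters.
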
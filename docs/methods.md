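# Methods

## The measurement model

The quantity of interest is a latent per-system tendency to deliver
low-value ("overuse") services. It is estimated from tracer indicators: for
indicator *j*, quarter *i*, hospital *h* in system *k*, the engine counts
`n` eligible beneficiaries and `C` indicator events among them, and the model
is

```
C ~ NB2(mu, alpha),   mu = n * exp(omega_i + psi_j + Phi_k + beta'X + b_h)
```

* `omega_i` — quarter fixed effects (secular/seasonal utilization drift),
* `psi_j` — indicator fixed effects (baseline rates differ by orders of
  magnitude across indicators),
* `Phi_k` — health-system fixed effects, the raw material of the index,
* `X` — cell-level patient covariates: mean age (years), proportion of women,
  median chronic-condition count (a precomputed per-beneficiary count is
  consumed; no comorbidity algorithm is implemented here),
* `b_h ~ N(0, sigma2_h)` — hospital random intercepts, capturing
  within-system heterogeneity,
* NB2 variance `mu + alpha*mu^2`; `alpha > 0` absorbs overdispersion
  relative to Poisson.

One quarter, one indicator and one system are reference levels (coefficients
pinned at 0); a global intercept is included. The default reference system is
the one contributing the most cells (configurable) — reference choice shifts
`Phi` by a constant and provably leaves the standardized index unchanged.
The model contains no additive residual term: in a GLMM for counts all
residual variation is carried by the NB2 distribution and the random
intercept.

The index is `OI_k = (Phi_k - mean(Phi)) / SD(Phi)` with the **sample** SD
(n−1), the reference system entering at `Phi = 0` like any other system.
Categories are half-open intervals of the Z-score: 1 (`oi < -1`),
2 (`-1 <= oi < -0.5`), 3 (`-0.5 <= oi < 0.5`), 4 (`0.5 <= oi < 1`),
5 (`oi >= 1`); every boundary value belongs to the upper category, a
convention chosen once because the verbal interval descriptions overlap at
their endpoints.

## Estimation

The hospital intercepts are integrated out per hospital with a Laplace
approximation — the one-point adaptive-quadrature special case:

```
log ∫ exp(g(b)) db / sqrt(2π σ²)  ≈  g(b̂) − ½ log(σ² H),   H = −g''(b̂)
```

with `b̂` the conditional mode (damped 1-D Newton, strictly concave
objective). At `sigma2_h = 0` this reduces *exactly* to the fixed-effects NB
log-likelihood. Tests hold the approximation to within 0.5% of a 50-point
adaptive Gauss–Hermite evaluation on small panels.

The marginal likelihood is maximized over all parameters jointly, with
`alpha` and `sigma2_h` on the log scale (lower bound `log sigma2 = −12`,
the practical zero). The gradient is exact and analytic, including the
derivative of the Laplace curvature term (third-order cell derivatives and
the implicit dependence of `b̂` on the parameters); it is verified against
central differences in the test suite. The optimization runs in three
stages: (1) warm start of the fixed effects from a Poisson GLM with offset,
`alpha = 1`, `sigma2_h = 0.1`; (2) L-BFGS-B with the analytic gradient;
(3) Newton–Raphson polish with step-halving line search, the Hessian taken
as finite differences of the analytic gradient. Convergence requires
relative log-likelihood change < 1e−8 and gradient max-norm < 1e−5. Pure
Newton from the warm start is not globally stable with dozens of system
dummies; the quasi-Newton warm phase buys the basin, the Newton phase the
tolerance. Standard errors come from the observed information at the
optimum. Covariates are centered and scaled by default (transforms stored);
zero-variance covariates are dropped with a warning; an all-zero-event
system triggers a separation warning.

Degenerate inputs: cells with zero eligible have no defined offset and never
exist downstream of the engine (the generator drops them too); a constant
`Phi` vector makes the index undefined and is an error; fewer than two
systems is an error.

## Indicator engine semantics

* Codes are matched on normalized strings (uppercased, dots stripped); code
  sets are prefix lists by default (the way ICD-10 lists are maintained),
  exact-match per indicator via `prefix_match: false`.
* A qualifying claim opens an eligibility window of
  `eligibility_window_days` at the claim's CCN. Events are claims bearing an
  event code on any day inside a window; an event covered by several windows
  attributes to the earliest-starting one (deterministic tie-break).
* Demographic-only indicators (e.g. screening in women over 85) defer
  attribution to the event claim; a beneficiary is "present" at every
  hospital where they have any claim in a quarter, and the eligible
  denominator is all demographically matching present beneficiaries.
* A beneficiary is eligible in a (hospital, quarter, indicator) cell when a
  window intersects the quarter; events land in the quarter of the event
  date. This is the only membership rule under which
  `event_count <= eligible_count` is guaranteed when windows span quarter
  boundaries.
* First-occurrence rule: per (beneficiary, indicator, quarter, hospital)
  only the earliest event counts; different indicators in the same
  quarter-hospital all count. Deduplication is idempotent.
* Quarters are 2016Q1–2018Q4 (indices 1–12); claims from July–December 2015
  act only as an eligibility lookback and can never contribute events.
  Hospital→system linkage uses the 2016 vintage for 2016–17 quarters and the
  2018 vintage for 2018 quarters; CCNs absent from the applicable vintage
  are dropped with a log entry, as are specialty hospitals (children's,
  behavioral, psychiatric, rehabilitation — keyword match on names).
* The minimum-eligible sensitivity filter removes a hospital from an
  indicator when fewer than `threshold` (default 20) individuals were
  eligible for that indicator at that hospital over the whole study; a
  per-quarter variant is available by flag.

## The synthetic generator

The generator emulates the nested structure of the real data — systems,
hospitals, beneficiaries, Compendium-style characteristics — and draws cell
event counts from exactly the model above, so the estimation stage can be
validated against known truth.

Defaults (the study conditions for all tests):

| parameter | default | meaning |
|---|---|---|
| `dispersion` | 0.5 | NB2 `alpha` (0 selects the Poisson limit) |
| `hospital_variance` | 0.25 | `sigma2_h` |
| `phi_sd` | 0.4 | residual SD of latent tendencies (log-rate scale) |
| `characteristic_effects` | pcp tertile 2/3: −0.3/−0.6; investor-owned: +0.3; major teaching: −0.2 | planted linearly on the φ scale |
| `base_log_rate` | −2.3 | ≈10% events per eligible person |
| `quarter_effect_sd`, `indicator_effect_sd` | 0.1, 0.5 | spread of ω and ψ |
| `covariate_betas` | (0.05, −0.05, 0.05) | on standardized covariates |
| `eligible_mean` | 25 | Poisson mean of per-cell eligible counts (zero cells dropped); not stated by any source, exposed as a parameter |

Characteristic effects are planted linearly on the φ scale, matching the
downstream linear association model; flags are drawn at prevalences in the
ballpark of published system descriptives (investor ownership is drawn at
10% rather than the published 3% so that small simulated populations contain
any investor-owned systems at all).

Claims materialization: every eligible person is a globally distinct
beneficiary with one qualifying (or contact) claim; the first `y` people per
cell get one event claim inside their window; eligibility dates are clamped
so windows sit inside a single quarter, which makes the engine's
reconstruction of the generator's cells *exact* (this is asserted
cell-for-cell in tests). Consequently the bundled indicator definitions use
windows of at most 84 days — a 90-day window cannot fit inside the 90-day
2017Q1. When the NB draw exceeds the eligible count the event count is
capped at `n` (events are per-person first occurrences) and the cap is
counted in the bundle. A `duplicate_injection` mode adds same-quarter repeat
event claims that the first-occurrence rule must remove.

What the generator does **not** emulate: real ICD-10/CPT semantics (code
sets are illustrative and mutually disjoint by construction), longitudinal
enrollment, beneficiaries visiting multiple hospitals for the same
indicator, correlated covariates, or informative missingness in
characteristics. Passing tests therefore demonstrate the correctness of the
counting rules, the estimator and the index construction under the stated
model — not the clinical validity of any indicator list.

## Association analyses

Right-skewed system counts enter as tertile dummies (type-1 inverse-CDF
quantiles, ties to the lower tertile; the upper-quartile flag is strictly
greater-than, ties excluded). Unadjusted comparisons across the five index
categories use Pearson χ² without continuity correction for multilevel
characteristics and the Mantel–Haenszel linear-trend statistic
`(n−1)r²` (integer scores 1..5, df = 1) for binary flags. The adjusted model
is OLS of the standardized index on characteristic features plus state fixed
effects (headquarters state); missing characteristics are handled by
listwise deletion, never imputed, with per-model n reported. Nested models
are compared by the Gaussian likelihood-ratio test, `2Δll = n log(RSS_r/RSS_f)`
against χ² with the parameter-count difference. The sensitivity variant
replaces state fixed effects with random state intercepts (statsmodels
MixedLM, ML so fixed-effect LR comparisons stay valid); a variance estimate
at the zero boundary is reported as 0 with a flag.

For planted-effect recovery checks the OLS response is the *raw* system
effect (`response="raw_phi"`): effects are planted on the φ scale, so the
standardized-index response would estimate `effect / SD(Phi)` instead of the
planted value. Analyses mirroring the published tables use the standardized
index (default).

## Problem sizes used in the checked runs

* Parameter recovery: 30 systems × 5 hospitals × 17 indicators × 12
  quarters (≈30,600 cells), truth `sigma2_h = 0.25`, `alpha = 0.5`; the fit
  takes a few seconds and recovers `corr(Phi_hat, phi_true) ≥ 0.9` and the
  planted −0.6 primary-care effect within its simulation CI.
* End-to-end pipeline runs (claims materialized) use 10–12 systems with 2–3
  hospitals each and a per-cell eligible mean of 12 — large enough to
  exercise every stage, small enough to rerun in seconds.
* Laplace accuracy: 5 hospitals, 50 cells, versus 50-point adaptive
  Gauss–Hermite.

## Known limitations

* `sigma2_h` is a maximum-likelihood estimate; with K system dummies
  absorbing between-system variation of hospital means, it is biased
  downward by roughly the factor `(H − K)/H` at H hospitals (no REML
  correction is attempted). The index itself is unaffected.
* With few hospitals per system, `Phi_k` necessarily absorbs the mean of
  that system's hospital intercepts; recovery of the latent tendency is
  bounded by `sqrt(var(phi) / (var(phi) + sigma2_h/H))` regardless of data
  volume per hospital.
* The engine assumes date-resolved claims, one attribution CCN per claim,
  and no cross-quarter event carry-over beyond the window rule.
* The LR test requires explicitly nested specifications on identical rows;
  it refuses anything else rather than guessing a common subset.
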
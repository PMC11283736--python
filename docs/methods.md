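# Methods

`approvoi` compares four ways a regulator could decide, at each point of an
accruing evidence timeline, among **approve**, **approval with research
(AWR)**, **only in research (OIR)** and **reject** for a hospital treatment
whose key uncertain quantity is its effect on 28-day mortality:

1. **Policy schedule** — the decision the regulator actually announced
   (no authorization → OIR, emergency use authorization → AWR, full
   approval → approve).
2. **Cumulative meta-analysis (CMA) rule** — a significance rule on the
   pooled relative risk: significant reduction → approve, non-significant
   reduction → AWR, non-significant increase → OIR, significant
   increase → reject.
3. **Prospective value of information (VOI)** — the strategy with the
   highest expected net benefit (ENB), using only forecasts available at
   the decision date.
4. **Retrospective VOI (reference standard)** — the same ENB calculation
   using the final forecast vintage, i.e. with hindsight knowledge of how
   many patients were actually affected.

The expected loss of an approach at a time point is the reference ENB of
the reference-optimal strategy minus the reference ENB of the strategy that
approach chose; it is zero exactly when they agree.

## Evidence synthesis

Each trial contributes a 2×2 table of 28-day deaths. The study-level
effect is the log relative risk, `log((a/n1)/(c/n2))`, with standard error
`sqrt(1/a − 1/n1 + 1/c − 1/n2)`. Tables with a zero cell receive a 0.5
continuity correction on all four cells; double-zero tables are excluded
from pooling (they carry no relative-risk information). Pooling follows
the convention of standard meta-analysis software for binary outcomes:

- Mantel–Haenszel fixed-effect pooled RR on the raw tables (reported as a
  diagnostic companion, `rr_mh`);
- Cochran's Q, I² = max(0, (Q − (k−1))/Q)·100 and DerSimonian–Laird τ²
  from inverse-variance statistics;
- random-effects weights `1/(v_i + τ²)`;
- optional **Knapp–Hartung** adjustment: the random-effects variance is
  rescaled by the weighted residual mean square (factor truncated at 1, so
  the adjusted interval never undercuts the normal one) and inference uses
  Student-t with k−1 degrees of freedom. A single study falls back to the
  normal Wald interval.

The cumulative series re-pools after every publication event; comparisons
sharing a publication date (multi-arm articles) enter together. Control
arms of multi-arm articles are double-counted across comparisons — a known
bias of the row-per-comparison convention, retained deliberately.

The implementation was cross-checked during development against an
independent spreadsheet-style computation of the same formulas (frozen in
the test suite at 1e-10) and reproduces `metafor::rma(method="DL",
test="knha")` to ten decimals on the same inputs.

### Known behaviors

- With Knapp–Hartung enabled, the k = 2 interval uses t(1) quantiles and is
  far wider than the k = 1 interval; CI widths shrink monotonically in
  expectation only from k = 2 onward (and throughout for the normal
  interval).
- The truncated Knapp–Hartung interval is deliberately conservative: under
  a homogeneous binomial generator its empirical coverage approaches 100%,
  while the normal random-effects interval sits near the nominal 95%.

## Cohort model

A four-state state-transition cohort model (hospitalized; recovered, ward
highest care; recovered, ICU highest care; dead) with daily cycles and no
half-cycle correction (the acute phase is short). The cohort enters fully
hospitalized and splits at admission: fraction `p_icu` follows the ICU
pathway, the rest the ward pathway. Each pathway applies a constant daily
death probability `q` solving `1 − (1−q)^los = risk28`, so the cumulative
in-hospital death risk equals the arm's 28-day mortality risk; survivors
are discharged at the pathway length of stay. Death is only possible in
hospital, which keeps the 28-day calibration exact for any length of stay.

The treatment arm multiplies the control 28-day risk by the relative risk
(bounded at 1) and re-derives the daily hazard; it also adds a one-off
drug cost at admission. While hospitalized, patients accrue the in-hospital
utility (per year / 365 per day) and the pathway's daily cost; at discharge
survivors receive a continuously discounted annuity `u_post · (1 −
exp(−r·le))/r`, discounted back to admission. Both costs and effects use a
3%/yr discount rate by default; the willingness-to-pay threshold is
$100,000/QALY.

The probabilistic sensitivity analysis (default 10,000 iterations) draws
beta distributions for probabilities and utilities, gamma for costs,
stays and life expectancies (each parameterized by mean and sd; sd = 0
gives a point mass), and a lognormal relative risk centered on the pooled
log-RR with the (adjusted) pooled standard error. Summaries report mean
incremental cost and QALYs, the ICER as the ratio of mean increments
(with dominance codes instead of a ratio where signs make the ratio
meaningless), mean incremental net monetary benefit `ΔQALY·WTP − Δcost`,
a dominance classification, the probability of cost-effectiveness, and
cost-effectiveness acceptability curves.

**The packaged parameter set is a synthetic stand-in** chosen in
clinically plausible ranges (28-day usual-care mortality 0.1–0.3, ICU
fraction 0.2–0.4, ICU daily cost above ward, drug cost near $4,000); it
is not a transcription of any published parameter file, and absolute CEA
magnitudes produced with it carry that caveat.

## Value of information

The VOI target is the single pooled log relative risk; all other
parameters contribute background noise.

- **EVPPI** uses a linear-regression metamodel: least-squares fit of
  sampled incremental net benefit on a polynomial basis of the sampled
  log-RR (default cubic; `Polynomial.fit` rescales the regressor for
  conditioning). EVPPI per person is `mean(max(ĝ(θ),0)) − max(mean(ĝ),0)`.
  The baseline uses the fitted values' own mean — identical in exact
  arithmetic to the mean sampled net benefit for an intercept-carrying
  least-squares fit — which makes the degenerate identities (sign-constant
  conditional mean, constant θ, zero shrinkage) exactly zero rather than
  leaving metamodel-curvature residue.
- **Effective prior sample size** n0 converts the pooled standard error
  into patient units: a two-arm trial with allocation `p` and event risks
  p1/p0 contributes per-patient log-RR information
  `v1 = (1−p1)/(p1·p) + (1−p0)/(p0·(1−p))`, so `n0 = v1/se²`. Event risks
  default to the PSA-mean control risk and its RR-scaled counterpart; a
  user-supplied n0 is accepted.
- **EVSI(n)** uses the Gaussian preposterior approximation: each sampled
  θ is shrunk toward the sample mean by `sqrt(n/(n+n0))` and the metamodel
  is re-evaluated. EVSI(0) = 0 and EVSI(n) → EVPPI as n → ∞ by
  construction; agreement with a brute-force nested two-loop Monte Carlo
  on a conjugate normal toy is verified in the tests at a 3-standard-error
  tolerance.
- **Optimal trial size** maximizes `n_future·EVSI(n) − cost(n)` over an
  integer grid (default step 50) up to the search cap (default 10,000),
  where `cost(n) = c_fixed + c_var·n` for n > 0 and zero for no trial.
  The feasibility-capped size `min(n_opt, 2,500)` is reported alongside.
  The default cost split ($2M fixed + $12,000/patient) reproduces a $32M
  total at n = 2,500; only that total is anchored, the split is a
  configurable package choice.
- Population values multiply per-person values by expected
  hospitalizations of the active horizon without within-horizon
  discounting (horizons are months).

## Decision matrix

With per-person iNB, a candidate trial of size n recruited from current
patients (fraction p to treatment), EVSI(n) per person, and current/future
patient counts:

    ENB(approve) = iNB·n_current + iNB·n_future
    ENB(AWR)     = iNB·(n_current − (1−p)·n) + n_future·(max(iNB,0) + EVSI(n)) − cost(n)
    ENB(OIR)     = iNB·p·n + n_future·(max(iNB,0) + EVSI(n)) − cost(n)
    ENB(reject)  = 0

Future patients under a research strategy receive the currently optimal
treatment (hence `max(iNB,0)`) plus the expected value of the new
information; implementation and reversal costs are zero. Exact ENB ties
resolve to the least committal strategy (reject > OIR > AWR > approve);
the approve row is summed term-by-term so the exact n = 0 degeneracy
(AWR = approve for a beneficial treatment) survives floating point.
A requested trial larger than the current-patient pool is truncated with
a warning.

## Timeline orchestration

Publication events are date groups of comparisons. At event k the pipeline
pools comparisons 1..k (or only group k in the non-cumulative scenario),
runs the PSA with a per-event seed spawned from the master seed (so
scenario runs are comparable draw-for-draw), summarizes cost-effectiveness,
and evaluates the ENB matrix twice: prospectively, on the latest forecast
vintage issued on or before the event date (never later — no information
leakage), and retrospectively on the final vintage. The trial size used in
the ENB matrix is the feasibility-capped optimum; EVSI is computed only
when EVPPI is positive.

**Forecast extension.** A vintage ends "mid-peak" when its final value
still exceeds 50% (configurable) of the last local maximum and the stretch
from that maximum to the end is monotone non-increasing. The decline is
then completed with the day-by-day mirror image of the incline about the
peak, down to the pre-peak baseline — pandemic peaks are assumed to
decline as symmetrically as they rose. Observed entries are never
modified.

**Patient horizon.** The trial window is `window_months` (default 2
months = 61 days at 30.5 days/month): current patients are admissions in
`(decision_date, decision_date + window]`, future patients from the window
end to the series end. Their sum is invariant to the window boundary.

**Scenarios** flip exactly one switch each: `wtp_150k`, `trial_3mo`,
`fda_subset`, `no_extension`, `single_study`, `no_hk`, `il6_subset`.

## Synthetic data

The generators produce the statistical structure the analysis assumes,
not any real data set:

- **Trials**: total size log-uniform in 30–4,116 split 1:1, control
  28-day risk uniform in 0.10–0.30, deaths binomial at the control risk
  and `min(1, RR·p0)` with true RR 0.9 by default; optional lognormal
  between-trial heterogeneity (`het_sd`) exercises the random-effects
  machinery. The packaged 22-comparison fixture additionally mirrors the
  real-world *structure* (18 articles, 10,031 patients, largest trial
  4,116, smallest 30, four comparisons flagged for the regulator subset)
  with frozen synthetic counts.
- **Forecasts**: Gaussian-bump waves on a baseline floor, curve kept
  within 3,000–5,500 admissions/day; one vintage per requested issue
  date, entries flagged observed/predicted around it, horizon truncation
  naturally produces mid-peak endings.
- **Parameters**: plausible clinical ranges as above with ~10–15%
  relative dispersion; a point-mass mode supports deterministic tests.

What passing tests on these fixtures do **not** show: agreement with the
real evidence stream's heterogeneity profile, with real admissions
forecasts, or with any published cost-effectiveness magnitudes — those
require the original trial tables, forecast vintages and parameter
spreadsheet. In particular, with plausible synthetic cohort parameters a
strongly beneficial relative-risk draw yields a large positive per-patient
net benefit, so the retrospective reference can occasionally prefer
outright approval at isolated time points, whereas a parameter set with
near-zero early net benefit suppresses approval throughout.

## Numerical choices and problem sizes

- Cycle length 1 day; occupancy conservation holds to 1e-12.
- PSA default 10,000 iterations; the test suite and the acceptance script
  use 800–4,000 iterations per event, which keeps the full timeline run
  in seconds while leaving Monte-Carlo error well inside the asserted
  tolerances.
- Calibration checks use 200 replicate evidence streams; the nested EVSI
  oracle uses 10,000 outer × 1,000 inner draws.
- Monetary values are stored unrounded in USD; displays follow the
  $-thousand (per-patient) and $-million (population) conventions.

## Limitations

Single pooled log-RR as the only VOI target; no multiparameter EVPPI, no
nonparametric metamodels; age-, variant- and vaccination-independent
cohort parameters; no implementation lag or reversal costs; population
values undiscounted within the horizon; forecast extension is a geometric
heuristic, not an epidemic model.
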
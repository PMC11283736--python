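# approvoi

**Drug-approval decision making under accruing trial evidence: cumulative
meta-analysis, cost-effectiveness modelling, and value-of-information
analysis.**

When randomized trials of a new hospital treatment publish one after
another during a health crisis, a regulator repeatedly faces the same
four-way choice: **approve** the treatment outright, approve it while a
further trial runs (**AWR**, the state an emergency use authorization
creates), restrict it to trial participants (**OIR**, only in research),
or **reject** it. `approvoi` is a reproducible pipeline for comparing, at
every publication event of such a timeline, the strategies suggested by

1. the regulator's actual **policy schedule**,
2. a **cumulative meta-analysis (CMA)** significance rule,
3. **prospective value-of-information (VOI)** analysis using only the
   admissions forecasts available at the decision date, and
4. a **retrospective VOI reference standard** computed with hindsight,

and for pricing each approach's deviations from the reference as an
expected-value loss in dollars. It is aimed at health-economics and
evidence-synthesis researchers studying approval/research policy, with
hospitalized COVID-19 treatment as the motivating setting.

## The model in brief

At each event k the evidence so far is pooled as a relative risk of
28-day mortality (Mantel–Haenszel / DerSimonian–Laird random effects with
the Knapp–Hartung adjustment, t(k−1) inference). The pooled log-RR and
its standard error feed a probabilistic four-state cohort model
(hospitalized → recovered-from-ward / recovered-from-ICU / dead) that
yields per-patient incremental cost, QALYs and net monetary benefit
iNB = ΔQALY·λ − Δcost at willingness-to-pay λ = $100,000/QALY. A
regression-metamodel EVPPI and a Gaussian-approximation EVSI(n) price the
value of a new n-patient trial, and the four strategies are scored as

    ENB(approve) = iNB·(n_current + n_future)
    ENB(AWR)     = iNB·(n_current − (1−p)·n) + n_future·(max(iNB,0) + EVSI(n)) − cost(n)
    ENB(OIR)     = iNB·p·n + n_future·(max(iNB,0) + EVSI(n)) − cost(n)
    ENB(reject)  = 0

where n_current / n_future are expected hospitalizations during and after
the trial window, taken from a dated forecast vintage (prospective) or
from the final vintage (retrospective reference). The expected loss of an
approach is ENB_ref(reference optimum) − ENB_ref(its choice) ≥ 0.

See `docs/methods.md` for the full model description, parameter meanings,
defaults and limitations. **All packaged inputs are synthetic stand-ins**
mirroring realistic structure (a 22-comparison, 10,031-patient evidence
stream; multi-peak admissions curves at 3,000–5,500/day; beta/gamma
parameter distributions), generated by the package's own simulators.

## Worked example

```python
import datetime as dt
import approvoi as av
from approvoi.synthetic import SimSpec, gen_forecast, gen_params

trials = av.datasets.synthetic_evidence()          # 22 comparisons, synthetic counts
meta = av.pool_random_effects(trials)
print(f"pooled RR {meta.rr:.2f} [{meta.ci_low:.2f}, {meta.ci_high:.2f}], "
      f"p={meta.p_value:.3f}, I2={meta.i2:.0f}%  ->  {av.cma_decision(meta).value}")

sim = SimSpec(master_seed=1)
vintages = sorted({(t.publication_date - dt.timedelta(days=3)).isoformat()
                   for t in trials} | {"2021-12-20"})
store = gen_forecast(sim, vintages)                # one vintage per issue date
_, dist = gen_params(seed=1)                       # synthetic parameter distributions
res = av.run_timeline(trials, store, dist,
                      av.datasets.synthetic_policy_schedule(),
                      av.AnalysisConfig(n_iter=4000, master_seed=1))
row = res.table.iloc[-1]
print(f"k={row.k} ({row.date}): iNB ${row.inb_pp:,.0f}/patient, "
      f"prospective {row.pros_strategy}, retrospective {row.retro_strategy}, "
      f"policy {row.policy_strategy}, CMA {row.cma_strategy}")
print(f"max expected loss  policy ${res.table.loss_policy.max()/1e6:,.0f}M, "
      f"CMA ${res.table.loss_cma.max()/1e6:,.0f}M, "
      f"prospective VOI ${res.table.loss_pvoi.max()/1e6:,.0f}M")
```

prints

```
pooled RR 0.92 [0.86, 0.99], p=0.033, I2=0%  ->  approve
k=20 (2021-10-31): iNB $9,298/patient, prospective awr, retrospective awr, policy awr, CMA approve
max expected loss  policy $5,676M, CMA $1,253M, prospective VOI $201M
```

Reading: after all 22 comparisons the pooled relative risk is
significantly below 1, so the meta-analysis rule would approve; both VOI
analyses still prefer approval-with-research (a further trial retains
value for the forecast future population), and over the whole timeline
the significance rule is the costliest guide while prospective VOI stays
closest to the hindsight reference.

The same analysis is available from the shell:

```sh
approvoi simulate --seed 1 --out-dir inputs        # synthetic evidence/forecasts/params/policy
approvoi cma --evidence inputs/evidence.csv        # cumulative meta-analysis table
approvoi timeline --config run.yaml --seed 1 --out-dir results
```

where `run.yaml` points at the four input files (see
`approvoi.config.RunConfig`; scenario switches: `wtp_150k`, `trial_3mo`,
`fda_subset`, `no_extension`, `single_study`, `no_hk`, `il6_subset`).
`timeline` writes a per-event summary, a decisions timeline, an
expected-loss table and a run manifest.

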
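"""Timeline orchestration: forecast vintages, patient horizons, and the
per-publication-event comparison of the four decision approaches.

At every publication event k the pipeline (1) re-pools the evidence
accrued so far, (2) propagates the pooled effect through the cohort model
(seeded PSA), (3) runs a prospective VOI analysis on the admissions
forecast that was current at the event date (optionally extended when a
forecast ends mid-peak, assuming pandemic peaks decline as symmetrically
as they rise), (4) runs the retrospective reference VOI on the final
vintage, and (5) records the strategy suggested by the policy schedule,
the meta-analysis significance rule, and both VOI analyses, together with
each approach's expected loss against the retrospective reference.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import logging
import time
import warnings
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import cea_summarize, sample_psa
from .core import ConfigError, InputError, Strategy
from .evidence import (
    MetaConfig,
    MetaResult,
    TrialComparison,
    cma_decision,
    filter_evidence,
    pool_random_effects,
    publication_groups,
)
from .strategy import (
    DecisionOutcome,
    PatientHorizon,
    StrategyENB,
    compare_approaches,
    enb_matrix,
)
from .voi import TrialCostModel, VOIResult, voi_analysis

__all__ = [
    "ForecastSeries",
    "ForecastStore",
    "TimelineEvent",
    "AnalysisConfig",
    "TimelineResult",
    "extend_forecast",
    "patient_horizon",
    "policy_strategy",
    "run_timeline",
    "scenario",
    "SCENARIOS",
]

log = logging.getLogger(__name__)


@dataclasses.dataclass
class ForecastSeries:
    """One forecast vintage: daily admissions, observed then predicted."""

    vintage_date: dt.date
    df: pd.DataFrame  # columns: date (datetime.date), admissions, flag
    extended: bool = False

    def __post_init__(self) -> None:
        d = self.df
        required = {"date", "admissions", "flag"}
        if not required.issubset(d.columns):
            raise InputError(f"forecast frame needs columns {sorted(required)}")
        dates = list(d["date"])
        if any(b <= a for a, b in zip(dates, dates[1:])):
            raise InputError("forecast dates must be strictly increasing")
        if (d["admissions"] < 0).any():
            raise InputError("admissions must be non-negative")

    @classmethod
    def from_csv(cls, path: str | Path) -> "ForecastSeries":
        path = Path(path)
        df = pd.read_csv(path)
        df["date"] = pd.to_datetime(df["date"]).dt.date
        vintage = dt.date.fromisoformat(path.stem)
        return cls(vintage_date=vintage, df=df)

    def to_csv(self, directory: str | Path) -> Path:
        out = Path(directory) / f"{self.vintage_date.isoformat()}.csv"
        self.df.to_csv(out, index=False)
        return out


class ForecastStore:
    """Collection of forecast vintages keyed by issue date."""

    def __init__(self, series: Sequence[ForecastSeries]):
        if not series:
            raise InputError("forecast store is empty")
        self._by_date = {s.vintage_date: s for s in series}
        self.vintage_dates = sorted(self._by_date)

    @classmethod
    def from_dir(cls, directory: str | Path) -> "ForecastStore":
        paths = sorted(Path(directory).glob("*.csv"))
        return cls([ForecastSeries.from_csv(p) for p in paths])

    def latest_at(self, date: dt.date, event: str = "") -> ForecastSeries:
        """Most recent vintage issued on or before ``date`` (prospective
        use: never look into the future)."""
        eligible = [v for v in self.vintage_dates if v <= date]
        if not eligible:
            raise InputError(
                f"no forecast vintage available on or before {date}"
                + (f" (event {event})" if event else "")
            )
        return self._by_date[eligible[-1]]

    def final(self) -> ForecastSeries:
        return self._by_date[self.vintage_dates[-1]]


@dataclasses.dataclass(frozen=True)
class TimelineEvent:
    k: int
    date: dt.date
    trial_ids: tuple[str, ...]


def extend_forecast(s: ForecastSeries, frac: float = 0.5) -> ForecastSeries:
    """Mirror-extend a forecast that ends mid-peak.

    A series ends mid-peak when its final value still exceeds ``frac`` of
    the last local maximum and the stretch from that maximum to the end is
    monotone non-increasing.  The decline is then completed with the
    mirror image of the incline about the peak, day by day, down to the
    pre-peak baseline.  Observed entries are never touched; a series that
    has already declined (or never peaked) is returned unchanged.
    """
    v = s.df["admissions"].to_numpy(dtype=float)
    n = len(v)
    last = n - 1
    # last local maximum (plateaus count via non-strict comparison)
    m = None
    for i in range(last, -1, -1):
        left_ok = i == 0 or v[i] >= v[i - 1]
        right_ok = i == last or v[i] >= v[i + 1]
        if left_ok and right_ok:
            m = i
            break
    if m is None:
        return dataclasses.replace(s, extended=False)
    # peak must sit inside the final monotone non-increasing segment
    if np.any(np.diff(v[m:]) > 0):
        return dataclasses.replace(s, extended=False)
    if v[last] < frac * v[m]:
        return dataclasses.replace(s, extended=False)
    # walk back along the incline to the pre-peak baseline (trough)
    s0 = m
    while s0 > 0 and v[s0 - 1] <= v[s0]:
        s0 -= 1
    if s0 == m or v[m] <= v[s0]:
        return dataclasses.replace(s, extended=False)
    already = last - m  # decline days already present
    mirror = [v[m - j] for j in range(already + 1, m - s0 + 1)]
    if not mirror:
        return dataclasses.replace(s, extended=False)
    last_date = s.df["date"].iloc[-1]
    new_rows = pd.DataFrame(
        {
            "date": [last_date + dt.timedelta(days=j) for j in range(1, len(mirror) + 1)],
            "admissions": mirror,
            "flag": "predicted",
        }
    )
    df = pd.concat([s.df, new_rows], ignore_index=True)
    return ForecastSeries(vintage_date=s.vintage_date, df=df, extended=True)


def patient_horizon(
    s: ForecastSeries,
    decision_date: dt.date,
    window_months: float = 2.0,
    days_per_month: float = 30.5,
) -> PatientHorizon:
    """Split expected admissions into current (inside the trial window,
    ``(decision_date, decision_date + window]``) and future (window end
    to series end)."""
    dates = s.df["date"]
    if decision_date > dates.iloc[-1]:
        raise InputError("decision date lies beyond the forecast series")
    window_days = int(round(window_months * days_per_month))
    window_end = decision_date + dt.timedelta(days=window_days)
    if window_end > dates.iloc[-1]:
        warnings.warn(
            f"forecast ends {dates.iloc[-1]} before window end {window_end}; "
            "counting available days only", stacklevel=2
        )
    adm = s.df["admissions"]
    in_window = (dates > decision_date) & (dates <= window_end)
    beyond = dates > window_end
    return PatientHorizon(
        n_current=float(adm[in_window].sum()),
        n_future=float(adm[beyond].sum()),
        window_months=window_months,
    )


_POLICY_MAP = {"none": Strategy.OIR, "eua": Strategy.AWR, "approved": Strategy.APPROVE}


def policy_strategy(
    schedule: Sequence[tuple[dt.date, str]], date: dt.date
) -> Strategy:
    """Strategy implied by the regulator's schedule at a date: no
    authorization -> OIR, emergency use authorization -> AWR, full
    approval -> approve."""
    status = "none"
    for d, st in sorted(schedule, key=lambda x: x[0]):
        if st not in _POLICY_MAP:
            raise InputError(f"unknown policy status {st!r}")
        if d <= date:
            status = st
    return _POLICY_MAP[status]


@dataclasses.dataclass(frozen=True)
class AnalysisConfig:
    """Every analysis switch of the pipeline, with the main-analysis
    defaults: $100,000/QALY threshold, 2-month (61-day) trial window,
    Knapp-Hartung pooling, forecast peak extension on, 10,000 PSA
    iterations, cubic metamodel, trial caps 2,500 (feasible) and 10,000
    (search)."""

    wtp: float = 100_000.0
    disc: float = 0.03
    window_months: float = 2.0
    days_per_month: float = 30.5
    hartung_knapp: bool = True
    continuity_correction: float = 0.5
    extend_forecast: bool = True
    extend_frac: float = 0.5
    evidence_mode: str = "all"
    single_study: bool = False
    n_iter: int = 10_000
    metamodel_degree: int = 3
    n_grid_step: int = 50
    c_fixed: float = 2_000_000.0
    c_var: float = 12_000.0
    n_max_feasible: int = 2_500
    n_cap: int = 10_000
    alloc_p: float = 0.5
    master_seed: int = 20240603

    @property
    def meta_config(self) -> MetaConfig:
        return MetaConfig(
            continuity_correction=self.continuity_correction,
            hartung_knapp=self.hartung_knapp,
        )

    @property
    def cost_model(self) -> TrialCostModel:
        return TrialCostModel(
            c_fixed=self.c_fixed,
            c_var=self.c_var,
            n_max_feasible=self.n_max_feasible,
            n_cap=self.n_cap,
            alloc_p=self.alloc_p,
        )


SCENARIOS: dict[str, dict] = {
    "wtp_150k": {"wtp": 150_000.0},
    "trial_3mo": {"window_months": 3.0},
    "fda_subset": {"evidence_mode": "fda_subset"},
    "no_extension": {"extend_forecast": False},
    "single_study": {"single_study": True},
    "no_hk": {"hartung_knapp": False},
    "il6_subset": {"evidence_mode": "il6_subset"},
}


def scenario(config: AnalysisConfig, name: str) -> AnalysisConfig:
    """Return a copy of the config with exactly one sensitivity switch
    flipped."""
    if name not in SCENARIOS:
        raise ConfigError(
            f"unknown scenario {name!r}; valid: {sorted(SCENARIOS)}"
        )
    return dataclasses.replace(config, **SCENARIOS[name])


@dataclasses.dataclass
class TimelineResult:
    """Per-event results table plus decision outcomes."""

    table: pd.DataFrame
    outcomes: list[DecisionOutcome]
    config: AnalysisConfig


def _voi_block(
    psa, meta: MetaResult, config: AnalysisConfig, horizon: PatientHorizon,
) -> tuple[VOIResult, StrategyENB]:
    """VOI analysis and ENB matrix for one horizon (prospective or
    retrospective)."""
    cost = config.cost_model
    p0 = float(np.clip(psa.df["p_death_28d_ctrl"].mean(), 1e-6, 1 - 1e-6))
    p1 = float(np.clip(p0 * meta.rr, 1e-6, 1 - 1e-6))
    theta, inb = psa.theta, psa.inb
    voi = voi_analysis(
        theta, inb, meta, cost,
        n_future=horizon.n_future,
        p1=p1, p0=p0,
        n_horizon=horizon.n_current + horizon.n_future,
        degree=config.metamodel_degree,
        step=config.n_grid_step,
    )
    n_used = min(voi.n_opt, cost.n_max_feasible)
    evsi_at_n = voi.evsi_curve.get(n_used)
    if evsi_at_n is None:
        from .voi import evsi_gaussian, fit_metamodel

        g = fit_metamodel(theta, inb, degree=config.metamodel_degree)
        evsi_at_n = evsi_gaussian(theta, inb, n_used, voi.n0, metamodel=g) \
            if voi.evppi_pp > 0 and n_used > 0 else 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # n may exceed a tiny horizon
        enb = enb_matrix(float(np.mean(inb)), evsi_at_n, n_used, cost, horizon)
    return voi, enb


def run_timeline(
    trials: Sequence[TrialComparison],
    store: ForecastStore,
    dist_spec: Mapping[str, Mapping[str, float]],
    policy_schedule: Sequence[tuple[dt.date, str]],
    config: AnalysisConfig | None = None,
) -> TimelineResult:
    """Run the full four-approach comparison over the evidence stream."""
    config = config or AnalysisConfig()
    selected = filter_evidence(trials, config.evidence_mode)
    groups = publication_groups(selected)
    meta_cfg = config.meta_config

    final_vintage = store.final()
    if config.extend_forecast:
        final_vintage = extend_forecast(final_vintage, config.extend_frac)

    from .cohort import params_from_spec

    params = params_from_spec(dist_spec, wtp=config.wtp, disc=config.disc)

    rows = []
    refs: list[StrategyENB] = []
    strategies: dict[str, list[Strategy]] = {"policy": [], "cma": [], "pvoi": []}
    ks, dates = [], []
    acc: list[TrialComparison] = []
    for k, group in enumerate(groups, start=1):
        t0 = time.perf_counter()
        acc.extend(group)
        date = group[0].publication_date
        pool = list(group) if config.single_study else list(acc)
        meta = pool_random_effects(pool, meta_cfg)

        seed = np.random.SeedSequence([config.master_seed, k])
        psa = sample_psa(dist_spec, meta, n_iter=config.n_iter, seed=seed,
                         params=params)
        cea = cea_summarize(psa, config.wtp)

        vintage = store.latest_at(date, event=f"k{k}")
        if config.extend_forecast:
            vintage = extend_forecast(vintage, config.extend_frac)
        h_pros = patient_horizon(
            vintage, date, config.window_months, config.days_per_month
        )
        h_retro = patient_horizon(
            final_vintage, date, config.window_months, config.days_per_month
        )

        voi_pros, enb_pros = _voi_block(psa, meta, config, h_pros)
        voi_retro, enb_retro = _voi_block(psa, meta, config, h_retro)

        s_policy = policy_strategy(policy_schedule, date)
        s_cma = cma_decision(meta)
        s_pvoi = enb_pros.optimal

        ks.append(k)
        dates.append(date)
        refs.append(enb_retro)
        strategies["policy"].append(s_policy)
        strategies["cma"].append(s_cma)
        strategies["pvoi"].append(s_pvoi)

        rows.append(
            {
                "k": k,
                "date": date,
                "trial_ids": ";".join(t.id for t in group),
                "n_comparisons": meta.k,
                "rr": meta.rr,
                "ci_low": meta.ci_low,
                "ci_high": meta.ci_high,
                "p_value": meta.p_value,
                "tau2": meta.tau2,
                "i2": meta.i2,
                "d_cost": cea.d_cost,
                "d_qaly": cea.d_qaly,
                "icer": cea.icer,
                "icer_code": cea.icer_code,
                "ce_class": cea.ce_class,
                "inb_pp": cea.inb_mean,
                "p_ce": cea.p_ce,
                "pros_n_current": h_pros.n_current,
                "pros_n_future": h_pros.n_future,
                "pros_pop_evppi": voi_pros.pop_evppi,
                "pros_n_opt": voi_pros.n_opt,
                "pros_n_used": enb_pros.n_used,
                "pros_evsi_pp": enb_pros.evsi_at_n,
                "pros_strategy": s_pvoi.value,
                "pros_net_value": enb_pros.enb(s_pvoi),
                "retro_n_current": h_retro.n_current,
                "retro_n_future": h_retro.n_future,
                "retro_pop_evppi": voi_retro.pop_evppi,
                "retro_n_opt": voi_retro.n_opt,
                "retro_n_used": enb_retro.n_used,
                "retro_evsi_pp": enb_retro.evsi_at_n,
                "retro_strategy": enb_retro.optimal.value,
                "retro_net_value": enb_retro.enb(enb_retro.optimal),
                "policy_strategy": s_policy.value,
                "cma_strategy": s_cma.value,
            }
        )
        log.info("event k=%d (%s) done in %.2fs", k, date, time.perf_counter() - t0)

    outcomes = compare_approaches(ks, dates, strategies, refs)
    table = pd.DataFrame(rows)
    for o in outcomes:
        table.loc[table["k"] == o.k, "loss_policy"] = o.loss_policy
        table.loc[table["k"] == o.k, "loss_cma"] = o.loss_cma
        table.loc[table["k"] == o.k, "loss_pvoi"] = o.loss_pvoi
    return TimelineResult(table=table, outcomes=outcomes, config=config)
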
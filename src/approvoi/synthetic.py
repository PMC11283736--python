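"""Synthetic trial streams, admissions forecasts, and model parameters.

The generators emulate the statistical structure of the evidence the
pipeline consumes: a stream of 10-22 binomial two-arm mortality trials of
30-4,116 subjects around a true relative risk near 0.9, multi-peak daily
hospital-admission curves on the scale of 3,000-5,500/day, and beta /
gamma parameter distributions for the cohort model.  Every generator is
reproducible under a master seed.  All outputs are synthetic stand-ins,
not transcriptions of any published data set.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import math
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .core import InputError
from .cohort import ModelParams, params_from_spec
from .evidence import TrialComparison
from .timeline import ForecastSeries, ForecastStore

__all__ = [
    "SimSpec",
    "gen_trials",
    "gen_forecast",
    "gen_params",
    "write_fixtures",
    "DEFAULT_PEAKS",
]

#: Three pandemic waves on top of the baseline floor; the combined curve
#: stays inside the 3,000-5,500 admissions/day range the analysis assumes.
DEFAULT_PEAKS: tuple[tuple[str, float, float], ...] = (
    ("2020-12-28", 2500.0, 45.0),
    ("2021-08-30", 1500.0, 40.0),
    ("2021-12-24", 2200.0, 30.0),
)


@dataclasses.dataclass(frozen=True)
class SimSpec:
    """Study conditions for the synthetic generators.

    ``true_rr`` is the generative relative risk of 28-day death;
    ``size_range`` the per-trial total size drawn log-uniformly;
    ``p0_range`` the control-arm 28-day death risk drawn uniformly;
    ``peak_spec`` lists (center date, peak height/day, Gaussian width in
    days) of the admissions waves on top of ``floor`` admissions/day;
    ``het_sd`` adds optional lognormal between-trial heterogeneity on the
    trial-level log-RR (0 = plain binomial model).
    """

    true_rr: float = 0.9
    k_trials: int = 22
    size_range: tuple[int, int] = (30, 4116)
    p0_range: tuple[float, float] = (0.10, 0.30)
    date_range: tuple[str, str] = ("2020-09-12", "2021-12-15")
    peak_spec: Sequence[tuple[str, float, float]] = DEFAULT_PEAKS
    floor: float = 3000.0
    noise_sd: float = 60.0
    het_sd: float = 0.0
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.true_rr <= 0:
            raise InputError("true_rr must be positive")
        if self.size_range[0] < 2:
            raise InputError("trial sizes must be >= 2")
        lo, hi = self.p0_range
        if not (0.0 < lo <= hi < 1.0):
            raise InputError("p0_range must lie strictly inside (0, 1)")


def gen_trials(spec: SimSpec) -> list[TrialComparison]:
    """Draw a dated stream of binomial two-arm mortality trials.

    Per trial: total n log-uniform in ``size_range`` split 1:1, control
    risk uniform in ``p0_range``, deaths binomial with that risk and
    ``min(1, true_rr * p0)`` (optionally perturbed by lognormal
    heterogeneity), publication dates sorted within ``date_range``.
    """
    rng = np.random.default_rng(spec.master_seed)
    lo, hi = spec.size_range
    sizes = np.exp(rng.uniform(math.log(lo), math.log(hi), spec.k_trials))
    sizes = np.maximum(2, np.rint(sizes)).astype(int)
    d0 = dt.date.fromisoformat(spec.date_range[0])
    d1 = dt.date.fromisoformat(spec.date_range[1])
    span = (d1 - d0).days
    offsets = np.sort(rng.choice(span + 1, size=spec.k_trials, replace=False)) \
        if span + 1 >= spec.k_trials else np.sort(rng.integers(0, span + 1, spec.k_trials))
    trials = []
    for i in range(spec.k_trials):
        n = int(sizes[i])
        n_treat = n // 2
        n_ctrl = n - n_treat
        p0 = float(rng.uniform(*spec.p0_range))
        rr_i = spec.true_rr
        if spec.het_sd > 0:
            rr_i *= float(rng.lognormal(0.0, spec.het_sd))
        p1 = min(1.0, rr_i * p0)
        trials.append(
            TrialComparison(
                id=f"SYN{i + 1:02d}",
                publication_date=d0 + dt.timedelta(days=int(offsets[i])),
                events_treat=int(rng.binomial(n_treat, p1)),
                n_treat=n_treat,
                events_ctrl=int(rng.binomial(n_ctrl, p0)),
                n_ctrl=n_ctrl,
                drug=f"drug{i % 6}",
                drug_class="il6" if i % 3 != 2 else "other",
                in_fda_subset=(i in (2, 6, 10, 14)),
            )
        )
    return trials


def _admissions_curve(spec: SimSpec, dates: Sequence[dt.date],
                      rng: np.random.Generator) -> np.ndarray:
    t = np.array([(d - dates[0]).days for d in dates], dtype=float)
    v = np.full(t.shape, spec.floor)
    for center, height, width in spec.peak_spec:
        c = (dt.date.fromisoformat(center) - dates[0]).days
        v += height * np.exp(-0.5 * ((t - c) / width) ** 2)
    if spec.noise_sd > 0:
        v = np.maximum(0.0, v + rng.normal(0.0, spec.noise_sd, size=v.shape))
    return v


def gen_forecast(
    spec: SimSpec,
    vintage_dates: Sequence[dt.date | str],
    horizon_days: int = 120,
    start: dt.date | str = "2020-09-01",
    end: dt.date | str = "2022-03-01",
) -> ForecastStore:
    """Build one forecast vintage per requested date.

    Each vintage covers ``start`` up to ``vintage + horizon_days`` (capped
    at ``end``); entries on or before the vintage date are flagged
    observed, later ones predicted.  Truncation at the horizon naturally
    leaves some vintages ending mid-peak, exercising the symmetric-peak
    extension.
    """
    start = dt.date.fromisoformat(start) if isinstance(start, str) else start
    end = dt.date.fromisoformat(end) if isinstance(end, str) else end
    rng = np.random.default_rng(np.random.SeedSequence([spec.master_seed, 7]))
    all_dates = [start + dt.timedelta(days=i) for i in range((end - start).days + 1)]
    base = _admissions_curve(spec, all_dates, rng)
    series = []
    for v in vintage_dates:
        v = dt.date.fromisoformat(v) if isinstance(v, str) else v
        stop = min(end, v + dt.timedelta(days=horizon_days))
        mask = [d <= stop for d in all_dates]
        dts = [d for d, m in zip(all_dates, mask) if m]
        df = pd.DataFrame(
            {
                "date": dts,
                "admissions": base[: len(dts)],
                "flag": ["observed" if d <= v else "predicted" for d in dts],
            }
        )
        series.append(ForecastSeries(vintage_date=v, df=df))
    return ForecastStore(series)


def gen_params(
    seed: int = 0, point_mass: bool = False
) -> tuple[ModelParams, dict[str, dict[str, float]]]:
    """Plausible synthetic cohort-model parameters with their PSA
    distributions.

    Means sit in clinically sensible ranges for a severe respiratory
    hospitalization (28-day usual-care mortality 0.1-0.3, ICU fraction
    0.2-0.4, ICU dearer than ward); ``point_mass`` zeroes every sd for
    deterministic tests.  Synthetic stand-ins, not a published parameter
    set.
    """
    rng = np.random.default_rng(seed)
    u = lambda a, b: float(rng.uniform(a, b))
    means = {
        "p_death_28d_ctrl": u(0.10, 0.30),
        "p_icu": u(0.20, 0.40),
        "los_ward": u(6.0, 10.0),
        "los_icu": u(12.0, 18.0),
        "c_day_ward": u(2000.0, 3000.0),
        "c_day_icu": u(5000.0, 8000.0),
        "c_drug": u(3500.0, 4500.0),
        "u_hosp": u(0.4, 0.6),
        "u_post_ward": u(0.75, 0.85),
        "u_post_icu": u(0.65, 0.80),
        "le_post_ward": u(12.0, 18.0),
        "le_post_icu": u(10.0, 15.0),
    }
    beta_like = {"p_death_28d_ctrl", "p_icu", "u_hosp", "u_post_ward", "u_post_icu"}
    spec: dict[str, dict[str, float]] = {}
    for name, mean in means.items():
        family = "beta" if name in beta_like else "gamma"
        sd = 0.0 if point_mass else (0.1 * mean if family == "beta" else 0.15 * mean)
        if family == "beta":
            sd = min(sd, 0.3 * math.sqrt(mean * (1 - mean)))
        spec[name] = {"family": family, "mean": round(mean, 6), "sd": round(sd, 6)}
    return params_from_spec(spec), spec


def write_fixtures(
    out_dir: str | Path,
    spec: SimSpec | None = None,
    vintage_dates: Sequence[str] | None = None,
    seed: int = 0,
) -> dict[str, Path]:
    """Write the three fixture families (evidence CSV, forecast store,
    parameter YAML) plus a policy schedule to ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spec = spec or SimSpec(master_seed=seed)
    trials = gen_trials(spec)
    ev = pd.DataFrame(
        [
            {
                "id": t.id,
                "publication_date": t.publication_date.isoformat(),
                "events_treat": t.events_treat,
                "n_treat": t.n_treat,
                "events_ctrl": t.events_ctrl,
                "n_ctrl": t.n_ctrl,
                "drug": t.drug,
                "drug_class": t.drug_class,
                "in_fda_subset": t.in_fda_subset,
            }
            for t in trials
        ]
    )
    ev_path = out / "evidence.csv"
    ev.to_csv(ev_path, index=False)

    if vintage_dates is None:
        vintage_dates = [
            (t.publication_date - dt.timedelta(days=3)).isoformat() for t in trials[::2]
        ] + [spec.date_range[1]]
    store = gen_forecast(spec, vintage_dates)
    fdir = out / "forecasts"
    fdir.mkdir(exist_ok=True)
    for vd in store.vintage_dates:
        store.latest_at(vd).to_csv(fdir)

    _, dist = gen_params(seed=seed)
    params_path = out / "params.yaml"
    with open(params_path, "w") as fh:
        yaml.safe_dump({"parameters": dist, "provenance": "synthetic"}, fh)

    policy_path = out / "policy.csv"
    pd.DataFrame(
        {"date": ["2021-06-24", "2022-12-21"], "status": ["eua", "approved"]}
    ).to_csv(policy_path, index=False)

    return {
        "evidence": ev_path,
        "forecasts": fdir,
        "params": params_path,
        "policy": policy_path,
    }
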
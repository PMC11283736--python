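"""Four-state cohort model of a hospitalized infectious-disease episode.

States: hospitalized, recovered (ward was the highest level of care),
recovered (ICU was the highest level of care), dead.  The cohort enters
fully hospitalized and splits at admission into a ward pathway (fraction
``1 - p_icu``) and an ICU pathway (``p_icu``).  Each pathway applies a
constant daily death probability calibrated so that the cumulative
in-hospital death risk equals the arm's 28-day mortality risk (the
meta-analysis endpoint); survivors are discharged at the pathway length of
stay and accrue post-discharge QALYs as a continuously discounted annuity
over their remaining life expectancy.  The treatment arm multiplies the
28-day risk by a relative risk and adds a one-off drug cost.

Daily cycles, no half-cycle correction (the acute phase is short), 3%/yr
discounting of both costs and effects by default.

The probabilistic sensitivity analysis draws beta (probabilities,
utilities), gamma (costs, stays, life expectancies) and lognormal
(relative risk) parameters and pushes every draw through both arms,
yielding per-draw incremental net monetary benefit.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .core import ConfigError, InputError
from .evidence import MetaResult

__all__ = [
    "ModelParams",
    "PSASample",
    "PSAResult",
    "CEAResult",
    "run_cohort",
    "cohort_trace",
    "sample_psa",
    "cea_summarize",
    "ceac_curve",
    "net_monetary_benefit",
]

DAYS_PER_YEAR = 365.0


@dataclasses.dataclass(frozen=True)
class ModelParams:
    """Deterministic (mean) cohort-model parameters.

    Probabilities and utilities are dimensionless in [0, 1]; lengths of
    stay in days; costs in USD; life expectancies in undiscounted years;
    ``wtp`` in USD/QALY; ``disc`` is the annual discount rate applied to
    both costs and effects.
    """

    p_death_28d_ctrl: float
    p_icu: float
    los_ward: float
    los_icu: float
    c_day_ward: float
    c_day_icu: float
    c_drug: float
    u_hosp: float
    u_post_ward: float
    u_post_icu: float
    le_post_ward: float
    le_post_icu: float
    wtp: float = 100_000.0
    disc: float = 0.03
    cycle_days: float = 1.0

    def __post_init__(self) -> None:
        for name in ("p_death_28d_ctrl", "p_icu", "u_hosp", "u_post_ward", "u_post_icu"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise InputError(f"{name}={v} outside [0, 1]")
        for name in (
            "los_ward", "los_icu", "c_day_ward", "c_day_icu", "c_drug",
            "le_post_ward", "le_post_icu", "disc",
        ):
            if getattr(self, name) < 0:
                raise InputError(f"{name} must be non-negative")
        if self.wtp <= 0:
            raise InputError("wtp must be positive")


def _annuity(le, disc):
    """Present value at discharge of 1 QALY/yr over ``le`` years,
    continuously discounted."""
    le = np.asarray(le, dtype=float)
    if disc == 0.0:
        return le
    return (1.0 - np.exp(-disc * le)) / disc


def _pathway(risk28, los, c_day, u_hosp, u_post, le_post, disc):
    """Vectorized cost/QALY of one pathway per person entering it.

    Returns (cost, qaly, survivors); all inputs broadcastable arrays.
    Death can only occur in hospital: the daily death probability solves
    ``1 - (1-q)^los = risk28`` so the cumulative 28-day death risk equals
    the arm's target.
    """
    risk28 = np.asarray(risk28, dtype=float)
    los = np.maximum(1, np.rint(np.asarray(los, dtype=float))).astype(int)
    risk28, los, c_day, u_post, le_post = np.broadcast_arrays(
        risk28, los, np.asarray(c_day, float), np.asarray(u_post, float),
        np.asarray(le_post, float),
    )
    q = 1.0 - (1.0 - risk28) ** (1.0 / los)
    cost = np.zeros(risk28.shape)
    qaly = np.zeros(risk28.shape)
    alive = np.ones(risk28.shape)
    for t in range(int(los.max())):
        active = t < los
        df = math.exp(-disc * t / DAYS_PER_YEAR)
        cost += np.where(active, alive * c_day * df, 0.0)
        qaly += np.where(active, alive * (u_hosp / DAYS_PER_YEAR) * df, 0.0)
        alive = np.where(active, alive * (1.0 - q), alive)
    survivors = alive
    df_dis = np.exp(-disc * los / DAYS_PER_YEAR)
    qaly += survivors * u_post * _annuity(le_post, disc) * df_dis
    return cost, qaly, survivors


def _arm_outputs(p: ModelParams, rr, *, treat: bool, draws: Mapping | None = None):
    """Discounted per-patient (cost, qaly) for one arm; vectorized over
    PSA draws when ``draws`` maps parameter names to arrays."""
    g = (lambda k: draws[k]) if draws is not None else (lambda k: getattr(p, k))
    rr = np.asarray(rr, dtype=float)
    if np.any(rr <= 0):
        raise InputError("relative risk must be positive")
    base = np.asarray(g("p_death_28d_ctrl"), dtype=float)
    risk = base * rr if treat else base * np.ones_like(rr)
    if draws is None and np.any(risk > 1.0 + 1e-12):
        raise InputError("rr * p_death_28d_ctrl exceeds 1")
    risk = np.minimum(risk, 1.0)
    disc = p.disc
    c_ward, q_ward, _ = _pathway(
        risk, g("los_ward"), g("c_day_ward"), g("u_hosp"),
        g("u_post_ward"), g("le_post_ward"), disc,
    )
    c_icu, q_icu, _ = _pathway(
        risk, g("los_icu"), g("c_day_icu"), g("u_hosp"),
        g("u_post_icu"), g("le_post_icu"), disc,
    )
    p_icu = np.asarray(g("p_icu"), dtype=float)
    cost = (1 - p_icu) * c_ward + p_icu * c_icu
    qaly = (1 - p_icu) * q_ward + p_icu * q_icu
    if treat:
        cost = cost + np.asarray(g("c_drug"), dtype=float)
    return cost, qaly


def run_cohort(p: ModelParams, rr: float, arm: str) -> tuple[float, float]:
    """Discounted per-patient (cost, QALY) of one arm.

    ``arm`` is ``"treat"`` (28-day risk multiplied by ``rr``, drug cost
    added) or ``"ctrl"``.
    """
    if arm not in ("treat", "ctrl"):
        raise InputError(f"unknown arm {arm!r}")
    cost, qaly = _arm_outputs(p, rr, treat=(arm == "treat"))
    return float(cost), float(qaly)


def cohort_trace(p: ModelParams, rr: float, arm: str, n_cycles: int = 60) -> pd.DataFrame:
    """Daily state-occupancy trace (hospitalized / recovered_ward /
    recovered_icu / dead); rows sum to 1 by construction of the model,
    which the test suite verifies numerically."""
    if arm not in ("treat", "ctrl"):
        raise InputError(f"unknown arm {arm!r}")
    risk = p.p_death_28d_ctrl * (rr if arm == "treat" else 1.0)
    if rr <= 0:
        raise InputError("relative risk must be positive")
    if risk > 1.0:
        raise InputError("rr * p_death_28d_ctrl exceeds 1")
    rows = []
    for frac, los, label in (
        (1.0 - p.p_icu, p.los_ward, "ward"),
        (p.p_icu, p.los_icu, "icu"),
    ):
        L = max(1, int(round(los)))
        q = 1.0 - (1.0 - risk) ** (1.0 / L)
        hosp, rec, dead = 1.0, 0.0, 0.0
        occ = []
        for t in range(n_cycles + 1):
            occ.append((hosp, rec, dead))
            if t < L:
                dead += hosp * q
                hosp *= 1.0 - q
                if t == L - 1:
                    rec, hosp = hosp, 0.0
        rows.append((frac, label, occ))
    records = []
    for t in range(n_cycles + 1):
        rec_w = rows[0][2][t]
        rec_i = rows[1][2][t]
        records.append(
            {
                "cycle": t,
                "hospitalized": rows[0][0] * rec_w[0] + rows[1][0] * rec_i[0],
                "recovered_ward": rows[0][0] * rec_w[1],
                "recovered_icu": rows[1][0] * rec_i[1],
                "dead": rows[0][0] * rec_w[2] + rows[1][0] * rec_i[2],
            }
        )
    return pd.DataFrame.from_records(records).set_index("cycle")


# ---------------------------------------------------------------------------
# Probabilistic sensitivity analysis


@dataclasses.dataclass(frozen=True)
class PSASample:
    """One joint parameter draw with its cohort outputs (all USD / QALY)."""

    rr: float
    cost_treat: float
    cost_ctrl: float
    qaly_treat: float
    qaly_ctrl: float
    inb: float


_BETA_PARAMS = {"p_death_28d_ctrl", "p_icu", "u_hosp", "u_post_ward", "u_post_icu"}
_GAMMA_PARAMS = {
    "los_ward", "los_icu", "c_day_ward", "c_day_icu", "c_drug",
    "le_post_ward", "le_post_icu",
}


def _draw(rng: np.random.Generator, family: str, mean: float, sd: float, size: int):
    if sd < 0:
        raise ConfigError("dispersion (sd) must be non-negative")
    if sd == 0.0:
        return np.full(size, mean)
    if family == "beta":
        if not (0.0 < mean < 1.0):
            raise ConfigError(f"beta mean {mean} outside (0, 1)")
        nu = mean * (1 - mean) / sd**2 - 1.0
        if nu <= 0:
            raise ConfigError(f"beta sd {sd} too large for mean {mean}")
        return rng.beta(mean * nu, (1 - mean) * nu, size=size)
    if family == "gamma":
        if mean <= 0:
            raise ConfigError(f"gamma mean {mean} must be positive")
        shape = (mean / sd) ** 2
        return rng.gamma(shape, scale=sd**2 / mean, size=size)
    if family == "lognormal":
        sigma2 = math.log(1 + (sd / mean) ** 2)
        mu = math.log(mean) - sigma2 / 2
        return rng.lognormal(mu, math.sqrt(sigma2), size=size)
    raise ConfigError(f"unknown distribution family {family!r}")


class PSAResult:
    """Container for a probabilistic sensitivity analysis.

    Holds the per-draw parameter and outcome arrays as a DataFrame
    (columns include every sampled parameter plus ``rr``, per-arm
    discounted ``cost_*``/``qaly_*`` and ``inb``).  Iterating yields
    :class:`PSASample` records.
    """

    def __init__(self, df: pd.DataFrame, params: ModelParams, wtp: float):
        self.df = df
        self.params = params
        self.wtp = wtp

    def __len__(self) -> int:
        return len(self.df)

    def __iter__(self) -> Iterator[PSASample]:
        cols = ["rr", "cost_treat", "cost_ctrl", "qaly_treat", "qaly_ctrl", "inb"]
        for row in self.df[cols].itertuples(index=False):
            yield PSASample(*row)

    @property
    def theta(self) -> np.ndarray:
        """Sampled log relative risks (the VOI target parameter)."""
        return np.log(self.df["rr"].to_numpy())

    @property
    def inb(self) -> np.ndarray:
        return self.df["inb"].to_numpy()


def sample_psa(
    dist_spec: Mapping[str, Mapping[str, float]],
    meta: MetaResult,
    n_iter: int = 10_000,
    seed: int | np.random.SeedSequence = 0,
    params: ModelParams | None = None,
) -> PSAResult:
    """Monte-Carlo propagation of parameter uncertainty through both arms.

    ``dist_spec`` maps parameter names to ``{family, mean, sd}`` blocks
    (beta for probabilities/utilities, gamma for costs/stays/life
    expectancies); ``sd = 0`` gives a point mass.  The relative risk is
    drawn lognormally around the pooled log-RR with its (adjusted)
    standard error.  Fully reproducible under a fixed seed.
    """
    if n_iter < 1:
        raise InputError("n_iter must be >= 1")
    if params is None:
        params = params_from_spec(dist_spec)
    rng = np.random.default_rng(seed)
    draws: dict[str, np.ndarray] = {}
    for name in sorted(set(_BETA_PARAMS) | set(_GAMMA_PARAMS)):
        block = dist_spec.get(name)
        if block is None:
            raise ConfigError(f"distribution spec missing parameter {name!r}")
        family = block.get("family", "beta" if name in _BETA_PARAMS else "gamma")
        draws[name] = _draw(
            rng, family, float(block["mean"]), float(block.get("sd", 0.0)), n_iter
        )
    rr = rng.lognormal(meta.log_rr_pooled, meta.se_pooled, size=n_iter) \
        if meta.se_pooled > 0 else np.full(n_iter, math.exp(meta.log_rr_pooled))

    cost_t, qaly_t = _arm_outputs(params, rr, treat=True, draws=draws)
    cost_c, qaly_c = _arm_outputs(params, np.ones_like(rr), treat=False, draws=draws)
    inb = (qaly_t - qaly_c) * params.wtp - (cost_t - cost_c)
    df = pd.DataFrame(draws)
    df["rr"] = rr
    df["cost_treat"], df["cost_ctrl"] = cost_t, cost_c
    df["qaly_treat"], df["qaly_ctrl"] = qaly_t, qaly_c
    df["inb"] = inb
    return PSAResult(df, params, params.wtp)


def params_from_spec(
    dist_spec: Mapping[str, Mapping[str, float]],
    wtp: float = 100_000.0,
    disc: float = 0.03,
) -> ModelParams:
    """Deterministic ModelParams at the distribution means."""
    means = {k: float(v["mean"]) for k, v in dist_spec.items()
             if k in _BETA_PARAMS | _GAMMA_PARAMS}
    missing = (_BETA_PARAMS | _GAMMA_PARAMS) - set(means)
    if missing:
        raise ConfigError(f"distribution spec missing parameters {sorted(missing)}")
    return ModelParams(wtp=wtp, disc=disc, **means)


# ---------------------------------------------------------------------------
# Cost-effectiveness summaries


@dataclasses.dataclass(frozen=True)
class CEAResult:
    """Mean incremental cost-effectiveness results at one time point."""

    d_cost: float
    d_qaly: float
    icer: float | None  # None when undefined (d_qaly == 0) or dominance
    icer_code: str  # "ratio", "undefined", "dominant", "dominated"
    inb_mean: float
    ce_class: str
    p_ce: float


def net_monetary_benefit(d_qaly: float, d_cost: float, wtp: float) -> float:
    """Incremental net monetary benefit: ``d_qaly * wtp - d_cost`` (USD)."""
    return d_qaly * wtp - d_cost


def _classify(d_cost: float, d_qaly: float, icer: float | None, wtp: float) -> str:
    if d_qaly > 0 and d_cost <= 0:
        return "dominant"
    if d_qaly > 0:
        return "cost_effective" if icer is not None and icer < wtp else "not_cost_effective"
    if d_qaly < 0 and d_cost >= 0:
        return "dominated"
    if d_qaly < 0 and d_cost < 0:
        return "qaly_losing"
    return "indifferent"


def cea_summarize(psa: PSAResult, wtp: float | None = None) -> CEAResult:
    """Mean incremental results over the PSA, with the ICER taken as the
    ratio of mean increments and the CEAC point ``p_ce = P(inb > 0)``."""
    if len(psa) == 0:
        raise InputError("empty PSA")
    wtp = psa.wtp if wtp is None else wtp
    df = psa.df
    d_cost = float((df["cost_treat"] - df["cost_ctrl"]).mean())
    d_qaly = float((df["qaly_treat"] - df["qaly_ctrl"]).mean())
    inb_s = (df["qaly_treat"] - df["qaly_ctrl"]) * wtp - (df["cost_treat"] - df["cost_ctrl"])
    if d_qaly == 0.0:
        icer, code = None, "undefined"
    elif d_qaly > 0 and d_cost <= 0:
        icer, code = None, "dominant"
    elif d_qaly < 0 and d_cost >= 0:
        icer, code = None, "dominated"
    else:
        icer, code = d_cost / d_qaly, "ratio"
    return CEAResult(
        d_cost=d_cost,
        d_qaly=d_qaly,
        icer=icer,
        icer_code=code,
        inb_mean=net_monetary_benefit(d_qaly, d_cost, wtp),
        ce_class=_classify(d_cost, d_qaly, icer, wtp),
        p_ce=float((inb_s > 0).mean()),
    )


def ceac_curve(psa: PSAResult, wtp_grid: Sequence[float]) -> list[tuple[float, float]]:
    """Cost-effectiveness acceptability curve: P(iNB > 0) per threshold."""
    if len(wtp_grid) == 0:
        raise InputError("empty WTP grid")
    if any(b < a for a, b in zip(wtp_grid, list(wtp_grid)[1:])):
        raise InputError("WTP grid must be ascending")
    df = psa.df
    dq = (df["qaly_treat"] - df["qaly_ctrl"]).to_numpy()
    dc = (df["cost_treat"] - df["cost_ctrl"]).to_numpy()
    return [(float(w), float((dq * w - dc > 0).mean())) for w in wtp_grid]
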
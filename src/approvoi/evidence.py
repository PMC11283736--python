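"""Cumulative meta-analysis of a dated stream of two-arm mortality trials.

Each trial contributes one 2x2 table (28-day deaths / randomized, per arm)
summarized as a log relative risk.  Pooling follows the convention of
standard meta-analysis software for binary outcomes: a Mantel-Haenszel
fixed-effect component on the raw tables, Cochran's Q and I^2 from
inverse-variance statistics, DerSimonian-Laird between-study variance, and
random-effects weights ``1/(v_i + tau^2)``.  Inference optionally applies
the Knapp-Hartung variance rescaling with Student-t(k-1) quantiles.

The cumulative series re-pools after every publication event, mirroring how
evidence actually accrued, and a four-quadrant decision rule maps each
pooled result to a suggested regulatory strategy.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import math
from typing import Iterable, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.contingency_tables import StratifiedTable

from .core import (
    EmptyEvidenceError,
    InputError,
    Strategy,
    UndefinedEffectError,
)

__all__ = [
    "TrialComparison",
    "EffectEstimate",
    "MetaResult",
    "MetaConfig",
    "study_effect",
    "pool_random_effects",
    "cumulative_series",
    "cma_decision",
    "filter_evidence",
]


@dataclasses.dataclass(frozen=True)
class TrialComparison:
    """One dated treatment-vs-control comparison with 2x2 mortality counts.

    A multi-arm article contributes several comparisons that share the
    control arm; each enters the analysis as an independent row (a known
    source of double counting, retained for fidelity to common practice).
    """

    id: str
    publication_date: dt.date
    events_treat: int
    n_treat: int
    events_ctrl: int
    n_ctrl: int
    drug: str = ""
    drug_class: str = "other"
    in_fda_subset: bool = False

    def __post_init__(self) -> None:
        if self.n_treat < 1 or self.n_ctrl < 1:
            raise InputError(f"{self.id}: arm sizes must be >= 1")
        if not (0 <= self.events_treat <= self.n_treat):
            raise InputError(f"{self.id}: treatment events outside [0, n]")
        if not (0 <= self.events_ctrl <= self.n_ctrl):
            raise InputError(f"{self.id}: control events outside [0, n]")

    @property
    def double_zero(self) -> bool:
        return self.events_treat == 0 and self.events_ctrl == 0


@dataclasses.dataclass(frozen=True)
class EffectEstimate:
    """Log relative risk of one comparison with its standard error."""

    log_rr: float
    se_log_rr: float
    continuity_corrected: bool = False

    def __post_init__(self) -> None:
        if not self.se_log_rr > 0:
            raise InputError("se_log_rr must be positive")

    @property
    def rr(self) -> float:
        return math.exp(self.log_rr)


@dataclasses.dataclass(frozen=True)
class MetaResult:
    """Pooled treatment effect at one time point of the evidence stream."""

    k: int
    log_rr_pooled: float
    se_pooled: float
    ci_low: float
    ci_high: float
    p_value: float
    tau2: float
    i2: float
    q: float
    #: Mantel-Haenszel fixed-effect pooled RR (diagnostic companion).
    rr_mh: float = float("nan")
    hk_applied: bool = False

    @property
    def rr(self) -> float:
        return math.exp(self.log_rr_pooled)


@dataclasses.dataclass(frozen=True)
class MetaConfig:
    """Pooling options.

    continuity_correction
        Constant added to all four cells of a table that has a zero cell
        (double-zero tables are excluded from pooling entirely).
    hartung_knapp
        Apply the Knapp-Hartung variance rescaling (factor truncated at 1)
        with t(k-1) inference; a single study always falls back to the
        normal Wald interval.
    tau2_method
        Between-study variance estimator; only "dl" (DerSimonian-Laird)
        is implemented.
    """

    continuity_correction: float = 0.5
    hartung_knapp: bool = True
    tau2_method: str = "dl"
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.tau2_method != "dl":
            raise InputError(f"unknown tau2 estimator {self.tau2_method!r}")


def study_effect(t: TrialComparison, cc: float = 0.5) -> EffectEstimate:
    """Relative risk of death, intervention vs control, from one 2x2 table.

    ``log RR = log((a/n1) / (c/n2))`` with standard error
    ``sqrt(1/a - 1/n1 + 1/c - 1/n2)``.  When the table contains a zero
    cell (zero events or zero non-events in either arm), ``cc`` is added
    to all four cells of that table before computing both quantities.
    """
    a, n1 = float(t.events_treat), float(t.n_treat)
    c, n2 = float(t.events_ctrl), float(t.n_ctrl)
    corrected = False
    zero_cell = a == 0.0 or c == 0.0 or a == n1 or c == n2
    if zero_cell:
        if t.double_zero and cc == 0:
            raise UndefinedEffectError(
                f"{t.id}: zero events in both arms and no continuity correction"
            )
        if cc > 0:
            a, c = a + cc, c + cc
            n1, n2 = n1 + 2 * cc, n2 + 2 * cc
            corrected = True
        elif a == 0.0 or c == 0.0 or a == n1 or c == n2:
            raise UndefinedEffectError(
                f"{t.id}: zero cell with continuity correction disabled"
            )
    log_rr = math.log((a / n1) / (c / n2))
    se = math.sqrt(1 / a - 1 / n1 + 1 / c - 1 / n2)
    return EffectEstimate(log_rr=log_rr, se_log_rr=se, continuity_corrected=corrected)


def _mh_pooled_rr(trials: Sequence[TrialComparison]) -> float:
    """Mantel-Haenszel fixed-effect pooled risk ratio on the raw tables."""
    tables = np.array(
        [
            [
                [t.events_treat, t.n_treat - t.events_treat],
                [t.events_ctrl, t.n_ctrl - t.events_ctrl],
            ]
            for t in trials
        ],
        dtype=float,
    )
    # StratifiedTable expects shape (2, 2, k)
    st = StratifiedTable(np.moveaxis(tables, 0, -1))
    return float(st.riskratio_pooled)


def pool_random_effects(
    trials: Sequence[TrialComparison], config: MetaConfig | None = None
) -> MetaResult:
    """Random-effects pooled relative risk over a set of comparisons.

    Double-zero tables carry no information about the relative risk and are
    dropped before pooling; pooling an otherwise empty set is an error.
    """
    config = config or MetaConfig()
    if len(trials) == 0:
        raise InputError("cannot pool an empty set of comparisons")
    usable = [t for t in trials if not t.double_zero]
    if not usable:
        raise EmptyEvidenceError("all comparisons are double-zero tables")

    effs = [study_effect(t, cc=config.continuity_correction) for t in usable]
    y = np.array([e.log_rr for e in effs])
    v = np.array([e.se_log_rr**2 for e in effs])
    k = len(usable)
    rr_mh = _mh_pooled_rr(usable)

    if k == 1:
        se = math.sqrt(v[0])
        z = stats.norm.ppf(1 - config.alpha / 2)
        mu = float(y[0])
        p = 2 * stats.norm.sf(abs(mu) / se)
        return MetaResult(
            k=1, log_rr_pooled=mu, se_pooled=se,
            ci_low=math.exp(mu - z * se), ci_high=math.exp(mu + z * se),
            p_value=float(p), tau2=0.0, i2=0.0, q=0.0,
            rr_mh=rr_mh, hk_applied=False,
        )

    # Inverse-variance fixed-effect statistics feed Q, I^2 and DL tau^2.
    w = 1.0 / v
    mu_iv = float(np.sum(w * y) / np.sum(w))
    q = float(np.sum(w * (y - mu_iv) ** 2))
    df = k - 1
    denom = float(np.sum(w) - np.sum(w**2) / np.sum(w))
    tau2 = max(0.0, (q - df) / denom) if denom > 0 else 0.0
    i2 = max(0.0, (q - df) / q) * 100.0 if q > 0 else 0.0

    w_re = 1.0 / (v + tau2)
    mu = float(np.sum(w_re * y) / np.sum(w_re))
    var_re = 1.0 / float(np.sum(w_re))

    hk_applied = bool(config.hartung_knapp)
    if hk_applied:
        # HK factor: weighted residual mean square relative to var_re,
        # truncated at 1 so the adjusted CI never undercuts the normal one.
        q_hk = float(np.sum(w_re * (y - mu) ** 2)) / df
        factor = max(1.0, q_hk)
        se = math.sqrt(factor * var_re)
        crit = stats.t.ppf(1 - config.alpha / 2, df)
        p = 2 * stats.t.sf(abs(mu) / se, df)
    else:
        se = math.sqrt(var_re)
        crit = stats.norm.ppf(1 - config.alpha / 2)
        p = 2 * stats.norm.sf(abs(mu) / se)

    return MetaResult(
        k=k, log_rr_pooled=mu, se_pooled=se,
        ci_low=math.exp(mu - crit * se), ci_high=math.exp(mu + crit * se),
        p_value=float(min(1.0, p)), tau2=tau2, i2=i2, q=q,
        rr_mh=rr_mh, hk_applied=hk_applied,
    )


def sort_by_date(trials: Iterable[TrialComparison]) -> list[TrialComparison]:
    """Stable sort by publication date (ties keep input order)."""
    return sorted(trials, key=lambda t: t.publication_date)


def publication_groups(
    trials: Sequence[TrialComparison],
) -> list[list[TrialComparison]]:
    """Group date-sorted comparisons by publication date.

    Comparisons sharing a date (typically arms of one article) enter the
    cumulative analysis simultaneously.
    """
    ordered = sort_by_date(trials)
    groups: list[list[TrialComparison]] = []
    for t in ordered:
        if groups and groups[-1][0].publication_date == t.publication_date:
            groups[-1].append(t)
        else:
            groups.append([t])
    return groups


def cumulative_series(
    trials: Sequence[TrialComparison], config: MetaConfig | None = None
) -> list[MetaResult]:
    """Re-pool after every publication event, in date order.

    Element j pools all comparisons published up to and including event j;
    the last element therefore equals ``pool_random_effects`` over the full
    set.
    """
    config = config or MetaConfig()
    groups = publication_groups(trials)
    if not groups:
        raise InputError("no comparisons supplied")
    out: list[MetaResult] = []
    acc: list[TrialComparison] = []
    for g in groups:
        acc.extend(g)
        out.append(pool_random_effects(acc, config))
    return out


def cma_decision(m: MetaResult, alpha: float = 0.05) -> Strategy:
    """Map a pooled result to the four-quadrant significance rule.

    A mortality reduction that is statistically significant suggests
    approval, a non-significant reduction approval-with-research, a
    non-significant increase only-in-research, and a significant increase
    rejection.  A pooled RR of exactly 1 falls to only-in-research.
    """
    if m.log_rr_pooled < 0:
        return Strategy.APPROVE if m.p_value <= alpha else Strategy.AWR
    if m.log_rr_pooled > 0:
        return Strategy.REJECT if m.p_value <= alpha else Strategy.OIR
    return Strategy.OIR


def filter_evidence(
    trials: Sequence[TrialComparison],
    mode: str = "all",
    k: int | None = None,
) -> list[TrialComparison]:
    """Select the evidence subset for a scenario.

    Modes: ``all`` (identity), ``fda_subset`` (comparisons flagged as
    cited in the regulator's authorization), ``il6_subset`` (IL-6(R)
    inhibitor drug class), ``single_study_k`` (exactly the k-th comparison
    in date order, 1-based — the non-cumulative scenario).
    """
    if mode == "all":
        selected = list(trials)
    elif mode == "fda_subset":
        selected = [t for t in trials if t.in_fda_subset]
    elif mode == "il6_subset":
        selected = [t for t in trials if t.drug_class == "il6"]
    elif mode == "single_study_k":
        ordered = sort_by_date(trials)
        if k is None or not (1 <= k <= len(ordered)):
            raise InputError(f"single_study_k requires 1 <= k <= {len(ordered)}")
        selected = [ordered[k - 1]]
    else:
        raise InputError(f"unknown evidence filter mode {mode!r}")
    if not selected:
        raise EmptyEvidenceError(f"evidence filter {mode!r} selected no comparisons")
    return selected
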
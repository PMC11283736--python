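"""Value-of-information analysis for the pooled treatment effect.

EVPPI for the single log relative-risk parameter is estimated with a
linear-regression metamodel: least-squares fit of sampled incremental net
benefit on a low-order polynomial basis of the sampled log-RR, giving a
noise-free estimate of the conditional mean iNB.  EVSI for a new two-arm
trial of size n uses the Gaussian (preposterior shrinkage) approximation:
the prior is assigned an effective sample size n0, each sampled log-RR is
shrunk toward the prior mean by sqrt(n / (n + n0)), and the metamodel is
re-evaluated at the shrunken values.  The optimal trial size maximizes
population EVSI minus trial cost over an integer grid.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Callable, Mapping, Sequence

import numpy as np

from .core import InputError
from .evidence import MetaResult

__all__ = [
    "TrialCostModel",
    "VOIResult",
    "Metamodel",
    "fit_metamodel",
    "evppi",
    "evpi",
    "effective_prior_n",
    "evsi_gaussian",
    "pop_scale",
    "optimal_sample_size",
    "voi_analysis",
]


@dataclasses.dataclass(frozen=True)
class TrialCostModel:
    """Cost of a new RCT: ``c_fixed + c_var * n`` USD for n > 0, 0 for n=0.

    ``n_max_feasible`` is the largest trial considered recruitable in the
    decision window; ``n_cap`` bounds the optimal-size search; ``alloc_p``
    is the fraction randomized to the intervention arm.
    """

    c_fixed: float = 2_000_000.0
    c_var: float = 12_000.0
    n_max_feasible: int = 2_500
    n_cap: int = 10_000
    alloc_p: float = 0.5

    def __post_init__(self) -> None:
        if self.c_fixed < 0 or self.c_var < 0:
            raise InputError("trial costs must be non-negative")
        if not (0.0 < self.alloc_p < 1.0):
            raise InputError("alloc_p must lie in (0, 1)")
        if self.n_max_feasible > self.n_cap:
            raise InputError("n_max_feasible cannot exceed n_cap")

    def cost(self, n: float) -> float:
        return 0.0 if n <= 0 else self.c_fixed + self.c_var * n


@dataclasses.dataclass(frozen=True)
class VOIResult:
    """Per-person and population value-of-information summary."""

    evppi_pp: float
    pop_evppi: float
    n0: float
    evsi_curve: dict[int, float]
    n_opt: int
    n_opt_capped_feasible: int
    net_gain_at_n_opt: float
    research_worthwhile: bool
    trial_cost_at: dict[int, float]


class Metamodel:
    """Polynomial conditional-mean estimate of iNB given log-RR."""

    def __init__(self, theta: np.ndarray, inb: np.ndarray, degree: int = 3):
        theta = np.asarray(theta, dtype=float)
        inb = np.asarray(inb, dtype=float)
        if theta.shape != inb.shape or theta.ndim != 1:
            raise InputError("theta and inb must be 1-d vectors of equal length")
        if theta.size < 100:
            raise InputError("metamodel needs at least 100 PSA draws")
        self.degenerate = bool(np.ptp(theta) == 0.0)
        self._mean_inb = float(inb.mean())
        if self.degenerate:
            self._poly = None
        else:
            # Polynomial.fit rescales theta to [-1, 1] internally, which
            # keeps the normal equations well conditioned.
            self._poly = np.polynomial.Polynomial.fit(theta, inb, deg=degree)

    def __call__(self, theta) -> np.ndarray:
        theta = np.asarray(theta, dtype=float)
        if self._poly is None:
            return np.full(theta.shape, self._mean_inb)
        return self._poly(theta)


def fit_metamodel(theta, inb, degree: int = 3) -> Metamodel:
    """Least-squares polynomial regression of sampled iNB on sampled
    log-RR (default cubic); degenerate (constant) theta yields the
    constant mean."""
    return Metamodel(theta, inb, degree=degree)


def _partial_value(ghat: np.ndarray) -> float:
    """``mean(max(ghat, 0)) - max(mean(ghat), 0)``.

    The baseline uses the fitted values' own mean (identical to the mean
    sampled iNB for a least-squares fit with intercept), which makes the
    degenerate cases — sign-constant conditional mean, constant theta,
    zero shrinkage — exactly zero instead of leaving metamodel-curvature
    residue.
    """
    mean_g = float(np.mean(ghat))
    val = float(np.mean(np.maximum(ghat, 0.0))) - max(mean_g, 0.0)
    return max(0.0, val)


def evppi(theta, inb, degree: int = 3, metamodel: Metamodel | None = None) -> float:
    """Per-person expected value of perfect information on log-RR:
    the expected gain of deciding after observing theta, over deciding on
    the current mean net benefit; never negative."""
    g = metamodel or fit_metamodel(theta, inb, degree=degree)
    return _partial_value(g(np.asarray(theta, float)))


def evpi(inb) -> float:
    """Per-person expected value of perfect information on everything,
    straight from the samples (upper bound for any EVPPI)."""
    inb = np.asarray(inb, dtype=float)
    return max(0.0, float(np.mean(np.maximum(inb, 0.0))) - max(float(inb.mean()), 0.0))


def effective_prior_n(
    meta: MetaResult, alloc_p: float, p1: float, p0: float
) -> float:
    """Effective prior sample size of the pooled log-RR.

    ``v1 = (1-p1)/(p1*alloc_p) + (1-p0)/(p0*(1-alloc_p))`` is the log-RR
    variance contributed by a single-patient trial with event risks p1
    (treated) and p0 (control); the prior is worth ``v1 / se_pooled^2``
    patients.
    """
    if not (0.0 < p1 < 1.0 and 0.0 < p0 < 1.0):
        raise InputError("event probabilities must lie strictly in (0, 1)")
    if not (0.0 < alloc_p < 1.0):
        raise InputError("alloc_p must lie in (0, 1)")
    if meta.se_pooled <= 0:
        raise InputError("se_pooled must be positive")
    v1 = (1 - p1) / (p1 * alloc_p) + (1 - p0) / (p0 * (1 - alloc_p))
    return v1 / meta.se_pooled**2


def evsi_gaussian(
    theta,
    inb,
    n: float,
    n0: float,
    metamodel: Metamodel | None = None,
    degree: int = 3,
) -> float:
    """Per-person EVSI of an n-patient trial by preposterior shrinkage.

    Each sampled log-RR is pulled toward the sample mean by the Gaussian
    preposterior factor ``sqrt(n / (n + n0))`` and the metamodel is
    evaluated at the shrunken values; n = 0 collapses every draw to the
    mean (zero value), n -> inf recovers EVPPI.
    """
    if n < 0:
        raise InputError("n must be non-negative")
    if n0 <= 0:
        raise InputError("n0 must be positive")
    theta = np.asarray(theta, dtype=float)
    inb = np.asarray(inb, dtype=float)
    g = metamodel or fit_metamodel(theta, inb, degree=degree)
    shrink = math.sqrt(n / (n + n0))
    theta_pp = theta.mean() + (theta - theta.mean()) * shrink
    return _partial_value(g(theta_pp))


def pop_scale(per_person: float, n_patients: float) -> float:
    """Scale a per-person value to a patient population (no within-horizon
    discounting; horizons are months)."""
    if n_patients < 0:
        raise InputError("n_patients must be non-negative")
    return per_person * n_patients


def optimal_sample_size(
    evsi_fn: Callable[[float], float],
    cost: TrialCostModel,
    n_future: float,
    step: int = 50,
) -> tuple[int, float, int, bool]:
    """Maximize ``f(n) = n_future * evsi(n) - cost(n)`` over 0..n_cap.

    Returns ``(n_opt, net_gain_at_n_opt, min(n_opt, n_max_feasible),
    research_worthwhile)``; n = 0 (no trial, zero cost, zero value) is
    always a candidate, so the flag is simply ``n_opt > 0``.
    """
    if n_future < 0:
        raise InputError("n_future must be non-negative")
    grid = np.unique(np.concatenate([
        np.arange(0, cost.n_cap + 1, step), [cost.n_cap, cost.n_max_feasible]
    ]))
    f = np.array([n_future * evsi_fn(float(n)) - cost.cost(float(n)) for n in grid])
    i = int(np.argmax(f))
    n_opt = int(grid[i])
    gain = float(f[i])
    return n_opt, gain, min(n_opt, cost.n_max_feasible), bool(n_opt > 0 and gain > 0)


def voi_analysis(
    theta,
    inb,
    meta: MetaResult,
    cost: TrialCostModel,
    n_future: float,
    p1: float,
    p0: float,
    n_horizon: float,
    degree: int = 3,
    step: int = 50,
    n0: float | None = None,
) -> VOIResult:
    """One-stop VOI summary at a time point.

    ``n_horizon`` is the population used for popEVPPI (all expected
    hospitalizations of the active horizon, current + future); EVSI and
    the optimal size are computed only when EVPPI is positive.
    """
    g = fit_metamodel(theta, inb, degree=degree)
    evppi_pp = evppi(theta, inb, metamodel=g)
    n0_val = float(n0) if n0 is not None else effective_prior_n(
        meta, cost.alloc_p, p1, p0
    )
    if evppi_pp > 0.0:
        fn = lambda n: evsi_gaussian(theta, inb, n, n0_val, metamodel=g)
        n_opt, gain, n_capped, worthwhile = optimal_sample_size(
            fn, cost, n_future, step=step
        )
        curve_ns = sorted({0, 250, 500, 1000, cost.n_max_feasible,
                           5000, cost.n_cap, n_opt})
        curve = {int(n): fn(float(n)) for n in curve_ns}
    else:
        n_opt, gain, n_capped, worthwhile = 0, 0.0, 0, False
        curve = {0: 0.0}
    return VOIResult(
        evppi_pp=evppi_pp,
        pop_evppi=pop_scale(evppi_pp, n_horizon),
        n0=n0_val,
        evsi_curve=curve,
        n_opt=n_opt,
        n_opt_capped_feasible=n_capped,
        net_gain_at_n_opt=gain,
        research_worthwhile=worthwhile,
        trial_cost_at={int(n): cost.cost(float(n)) for n in curve},
    )
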
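"""Expected-net-benefit decision matrix over approve / AWR / OIR / reject.

For a per-person incremental net benefit iNB, a candidate new trial of
size n (fraction p randomized to treatment, recruited from the patients
hospitalized during the trial window), per-person EVSI(n), a trial cost
function, and a patient horizon split into current (during-trial) and
future patients:

    ENB(approve) = iNB * (n_current + n_future)
    ENB(AWR)     = iNB * (n_current - (1-p) * n)
                   + n_future * (max(iNB, 0) + EVSI(n)) - cost(n)
    ENB(OIR)     = iNB * p * n
                   + n_future * (max(iNB, 0) + EVSI(n)) - cost(n)
    ENB(reject)  = 0

EVSI enters over and above the benefit of the currently optimal treatment
(hence the max(iNB, 0) term for future patients), and implementation and
reversal costs are taken as zero.  The optimal strategy is the argmax;
exact ties resolve to the least committal option (reject > OIR > AWR >
approve).  The expected loss of choosing some strategy is measured on a
reference (hindsight) ENB matrix as ENB(reference optimum) - ENB(chosen).
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import warnings
from typing import Mapping, Sequence

from .core import InputError, Strategy, TIE_ORDER
from .voi import TrialCostModel

__all__ = [
    "PatientHorizon",
    "StrategyENB",
    "DecisionOutcome",
    "enb_matrix",
    "select_strategy",
    "expected_loss",
    "compare_approaches",
]


@dataclasses.dataclass(frozen=True)
class PatientHorizon:
    """Expected hospitalizations during the trial window (current) and
    from the window's end to the horizon's end (future)."""

    n_current: float
    n_future: float
    window_months: float = 2.0

    def __post_init__(self) -> None:
        if self.n_current < 0 or self.n_future < 0:
            raise InputError("patient counts must be non-negative")
        if self.window_months <= 0:
            raise InputError("window_months must be positive")


@dataclasses.dataclass(frozen=True)
class StrategyENB:
    """Expected net benefit (USD) of the four strategies at one time point."""

    enb_approve: float
    enb_awr: float
    enb_oir: float
    enb_reject: float = 0.0
    n_used: int = 0
    inb: float = 0.0
    evsi_at_n: float = 0.0
    cost_at_n: float = 0.0

    def enb(self, s: Strategy) -> float:
        return {
            Strategy.APPROVE: self.enb_approve,
            Strategy.AWR: self.enb_awr,
            Strategy.OIR: self.enb_oir,
            Strategy.REJECT: self.enb_reject,
        }[s]

    @property
    def optimal(self) -> Strategy:
        return select_strategy(self)


@dataclasses.dataclass(frozen=True)
class DecisionOutcome:
    """Strategies of the four approaches at one event, with expected
    losses against the retrospective reference."""

    k: int
    date: dt.date
    strategy_policy: Strategy
    strategy_cma: Strategy
    strategy_pvoi: Strategy
    strategy_rvoi: Strategy
    loss_policy: float
    loss_cma: float
    loss_pvoi: float


def enb_matrix(
    inb: float,
    evsi_at_n: float,
    n: float,
    cost: TrialCostModel,
    h: PatientHorizon,
) -> StrategyENB:
    """Evaluate the four-quadrant ENB matrix.

    Trial participants are drawn from current patients, so n is truncated
    (with a warning) at ``h.n_current``.
    """
    if n < 0:
        raise InputError("n must be non-negative")
    if n > h.n_current:
        warnings.warn(
            f"trial size {n:.0f} exceeds current patients "
            f"{h.n_current:.0f}; truncating", stacklevel=2
        )
        n = h.n_current
    p = cost.alloc_p
    c_n = cost.cost(n)
    future_val = h.n_future * (max(inb, 0.0) + evsi_at_n)
    # approve is summed term-by-term so the exact n=0 degeneracy
    # (AWR == approve for beneficial treatment) survives floating point
    return StrategyENB(
        enb_approve=inb * h.n_current + inb * h.n_future,
        enb_awr=inb * (h.n_current - (1.0 - p) * n) + future_val - c_n,
        enb_oir=inb * p * n + future_val - c_n,
        enb_reject=0.0,
        n_used=int(n),
        inb=inb,
        evsi_at_n=evsi_at_n,
        cost_at_n=c_n,
    )


def select_strategy(e: StrategyENB) -> Strategy:
    """Argmax ENB; exact ties go to the least committal strategy."""
    best = max(TIE_ORDER, key=lambda s: e.enb(s))
    # max() keeps the first of equals, and TIE_ORDER lists reject first.
    return best


def expected_loss(reference: StrategyENB, chosen: Strategy) -> float:
    """Value lost by following ``chosen`` instead of the reference
    optimum, measured on the reference ENB matrix; zero on agreement."""
    if not isinstance(chosen, Strategy):
        chosen = Strategy(chosen)
    return reference.enb(reference.optimal) - reference.enb(chosen)


def compare_approaches(
    ks: Sequence[int],
    dates: Sequence[dt.date],
    strategies: Mapping[str, Sequence[Strategy]],
    references: Sequence[StrategyENB],
) -> list[DecisionOutcome]:
    """Per-event losses of the policy / CMA / prospective-VOI approaches
    against the retrospective reference ENB matrices.

    All sequences must be aligned on the same time points.
    """
    n = len(ks)
    for name in ("policy", "cma", "pvoi"):
        if name not in strategies:
            raise InputError(f"missing strategy sequence {name!r}")
    if not (len(dates) == n == len(references)) or any(
        len(strategies[a]) != n for a in ("policy", "cma", "pvoi")
    ):
        raise InputError("misaligned time points across approaches")
    out = []
    for i in range(n):
        ref = references[i]
        out.append(
            DecisionOutcome(
                k=ks[i],
                date=dates[i],
                strategy_policy=strategies["policy"][i],
                strategy_cma=strategies["cma"][i],
                strategy_pvoi=strategies["pvoi"][i],
                strategy_rvoi=ref.optimal,
                loss_policy=expected_loss(ref, strategies["policy"][i]),
                loss_cma=expected_loss(ref, strategies["cma"][i]),
                loss_pvoi=expected_loss(ref, strategies["pvoi"][i]),
            )
        )
    return out
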
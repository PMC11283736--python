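"""Shared vocabulary: regulatory strategies and package-level errors."""

from __future__ import annotations

import enum


class Strategy(str, enum.Enum):
    """Combined research-and-adoption strategy open to a regulator.

    APPROVE
        Adopt the treatment for all eligible patients; no further trial.
    AWR
        Approval with research: adopt for everyone (e.g., under an
        emergency use authorization) while a new trial runs.
    OIR
        Only in research: treatment available solely to the intervention
        arm of a new trial.
    REJECT
        Do not adopt and do not run further research.
    """

    APPROVE = "approve"
    AWR = "awr"
    OIR = "oir"
    REJECT = "reject"


#: Tie-break order when strategies have exactly equal expected net benefit:
#: the least committal option wins.
TIE_ORDER = (Strategy.REJECT, Strategy.OIR, Strategy.AWR, Strategy.APPROVE)


class ApprovoiError(Exception):
    """Base class for all package errors."""


class InputError(ApprovoiError, ValueError):
    """Invalid domain input (counts, probabilities, dates...)."""


class UndefinedEffectError(InputError):
    """A relative risk cannot be formed (e.g., zero events in both arms
    with no continuity correction)."""


class EmptyEvidenceError(InputError):
    """An evidence filter produced an empty trial set."""


class ConfigError(ApprovoiError, ValueError):
    """Invalid configuration (unknown scenario, bad distribution spec...)."""
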
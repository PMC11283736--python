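"""Packaged synthetic example data.

The evidence file mirrors the *structure* of a real monoclonal-antibody
evidence stream — 18 articles contributing 22 treatment comparisons and
10,031 randomized patients, the largest trial of 4,116 and the smallest
of 30 subjects, published September 2020 to December 2021, four
comparisons flagged as cited in the regulator's emergency authorization —
but every 2x2 count is synthetic, drawn binomially around a true relative
risk of 0.9.  The parameter file is likewise a plausible synthetic
stand-in, not a transcription of any published parameter set.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

from .evidence import TrialComparison
from .io import read_evidence_csv, read_params_yaml, read_policy_csv

__all__ = [
    "synthetic_evidence",
    "synthetic_params",
    "synthetic_policy_schedule",
    "data_path",
]


def data_path(name: str) -> Path:
    """Filesystem path of a packaged data file."""
    return Path(str(resources.files("approvoi").joinpath("data", name)))


def synthetic_evidence() -> list[TrialComparison]:
    """The 22-comparison synthetic evidence stream."""
    return read_evidence_csv(data_path("evidence_synthetic.csv"))


def synthetic_params() -> dict[str, dict[str, float]]:
    """Synthetic cohort-model parameter distributions."""
    return read_params_yaml(data_path("params_synthetic.yaml"))


def synthetic_policy_schedule():
    """Regulator schedule: emergency authorization 2021-06-24, full
    approval 2022-12-21 (beyond the study timeline)."""
    return read_policy_csv(data_path("policy_schedule_synthetic.csv"))
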
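"""Readers and writers for the pipeline's tabular interfaces."""

from __future__ import annotations

import datetime as dt
import hashlib
import json
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from .core import ConfigError, Strategy
from .evidence import TrialComparison
from .strategy import DecisionOutcome
from .timeline import TimelineResult

__all__ = [
    "read_evidence_csv",
    "read_policy_csv",
    "read_params_yaml",
    "render_reports",
]

_EVIDENCE_COLUMNS = [
    "id", "publication_date", "events_treat", "n_treat",
    "events_ctrl", "n_ctrl", "drug", "drug_class", "in_fda_subset",
]


def read_evidence_csv(path: str | Path) -> list[TrialComparison]:
    """One row per treatment comparison; dates ISO-8601."""
    df = pd.read_csv(path)
    missing = set(_EVIDENCE_COLUMNS) - set(df.columns)
    if missing:
        raise ConfigError(f"evidence file {path}: missing columns {sorted(missing)}")
    out = []
    for row in df.itertuples(index=False):
        out.append(
            TrialComparison(
                id=str(row.id),
                publication_date=dt.date.fromisoformat(str(row.publication_date)),
                events_treat=int(row.events_treat),
                n_treat=int(row.n_treat),
                events_ctrl=int(row.events_ctrl),
                n_ctrl=int(row.n_ctrl),
                drug=str(row.drug),
                drug_class=str(row.drug_class),
                in_fda_subset=bool(row.in_fda_subset),
            )
        )
    return out


def read_policy_csv(path: str | Path) -> list[tuple[dt.date, str]]:
    df = pd.read_csv(path)
    if not {"date", "status"}.issubset(df.columns):
        raise ConfigError(f"policy file {path}: needs columns date,status")
    return [
        (dt.date.fromisoformat(str(r.date)), str(r.status))
        for r in df.itertuples(index=False)
    ]


def read_params_yaml(path: str | Path) -> dict[str, dict[str, float]]:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "parameters" not in doc:
        raise ConfigError(f"parameter file {path}: missing 'parameters' block")
    return doc["parameters"]


def render_reports(
    result: TimelineResult,
    out_dir: str | Path,
    seed: int | None = None,
    config_source: str | Path | None = None,
) -> dict[str, Path]:
    """Write the per-event summary, decisions timeline, and losses CSVs
    plus a run manifest.

    Numbers are written unrounded; the documented display conventions are
    $ thousand for per-patient net benefit and $ million for population
    values.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    import dataclasses as _dc

    summary = out / "per_event_summary.csv"
    result.table.to_csv(summary, index=False)

    dec_rows = [
        {
            "k": o.k,
            "date": o.date.isoformat(),
            "policy": o.strategy_policy.value,
            "cma": o.strategy_cma.value,
            "prospective_voi": o.strategy_pvoi.value,
            "retrospective_voi": o.strategy_rvoi.value,
        }
        for o in result.outcomes
    ]
    decisions = out / "decisions.csv"
    pd.DataFrame(dec_rows, columns=[
        "k", "date", "policy", "cma", "prospective_voi", "retrospective_voi",
    ]).to_csv(decisions, index=False)

    loss_rows = [
        {
            "k": o.k,
            "date": o.date.isoformat(),
            "loss_policy": o.loss_policy,
            "loss_cma": o.loss_cma,
            "loss_pvoi": o.loss_pvoi,
        }
        for o in result.outcomes
    ]
    losses = out / "losses.csv"
    pd.DataFrame(loss_rows, columns=[
        "k", "date", "loss_policy", "loss_cma", "loss_pvoi",
    ]).to_csv(losses, index=False)

    cfg = _dc.asdict(result.config)
    manifest = out / "manifest.json"
    from . import __version__

    manifest.write_text(
        json.dumps(
            {
                "config": cfg,
                "config_hash": hashlib.sha256(
                    json.dumps(cfg, sort_keys=True).encode()
                ).hexdigest(),
                "seed": seed if seed is not None else result.config.master_seed,
                "config_source": str(config_source) if config_source else None,
                "approvoi_version": __version__,
            },
            indent=2,
        )
    )
    return {
        "summary": summary,
        "decisions": decisions,
        "losses": losses,
        "manifest": manifest,
    }
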
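"""Serialization of run results: plain CSV tables plus a JSON run manifest.

Numeric formatting: costs are written to cents (2 decimals), QALYs to 4
decimals, CEAC probabilities to 6 decimals.  Files are never overwritten
unless explicitly requested.
"""

from __future__ import annotations

import hashlib
import json
from importlib import metadata
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cea import FrontierEntry, StrategyResult
from .sensitivity import PSAResult, ScenarioResult, TornadoEntry

__all__ = [
    "frontier_frame",
    "ceac_frame",
    "tornado_frame",
    "write_results",
]


def frontier_frame(results: Mapping[str, StrategyResult],
                   frontier: Sequence[FrontierEntry]) -> pd.DataFrame:
    """Frontier table: one row per strategy with means, increments and status."""
    rows = []
    for entry in frontier:
        r = results[entry.strategy]
        rows.append({
            "strategy": entry.strategy,
            "avg_cost": round(r.mean_cost, 2),
            "avg_qaly": round(r.mean_qaly, 4),
            "incr_cost": round(entry.incr_cost, 2) if entry.incr_cost is not None else "",
            "incr_qaly": round(entry.incr_qaly, 4) if entry.incr_qaly is not None else "",
            "icer": round(entry.icer, 2) if entry.icer is not None else "",
            "status": entry.status,
        })
    return pd.DataFrame(rows)


def tornado_frame(entries: Sequence[TornadoEntry]) -> pd.DataFrame:
    return pd.DataFrame([{
        "parameter": e.parameter,
        "low_value": e.low_value,
        "high_value": e.high_value,
        "icer_at_low": round(e.icer_at_low, 2) if np.isfinite(e.icer_at_low) else e.icer_at_low,
        "icer_at_high": round(e.icer_at_high, 2) if np.isfinite(e.icer_at_high) else e.icer_at_high,
        "status_at_low": e.status_at_low,
        "status_at_high": e.status_at_high,
    } for e in entries])


def ceac_frame(psa: PSAResult) -> pd.DataFrame:
    out = psa.ceac.round(6).reset_index()
    out["wtp"] = out["wtp"].round(2)
    return out


def _config_hash(config: Mapping) -> str:
    canonical = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def write_results(output_dir: str | Path, *, seed: int,
                  config: Mapping | None = None,
                  results: Mapping[str, StrategyResult] | None = None,
                  frontier: Sequence[FrontierEntry] | None = None,
                  scenario: ScenarioResult | None = None,
                  tornado: Sequence[TornadoEntry] | None = None,
                  psa: PSAResult | None = None,
                  overwrite: bool = False) -> list[Path]:
    """Write whichever results are present to ``output_dir``.

    Emits ``frontier.csv`` (base case), ``scenario_<name>.csv``,
    ``tornado.csv``, ``ceac.csv``, and always ``manifest.json`` (seed,
    config hash, package versions).  Refuses to overwrite existing files
    unless ``overwrite=True``.  Returns the paths written.
    """
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit(name: str, frame: pd.DataFrame) -> None:
        path = out / name
        if path.exists() and not overwrite:
            raise FileExistsError(f"{path} exists; pass overwrite=True to replace it")
        frame.to_csv(path, index=False)
        written.append(path)

    if results is not None and frontier is not None:
        emit("frontier.csv", frontier_frame(results, frontier))
    if scenario is not None:
        emit(f"scenario_{scenario.scenario}.csv",
             frontier_frame(scenario.results, scenario.frontier))
    if tornado is not None:
        emit("tornado.csv", tornado_frame(tornado))
    if psa is not None:
        emit("ceac.csv", ceac_frame(psa))

    try:
        version = metadata.version("cannacea")
    except metadata.PackageNotFoundError:  # pragma: no cover
        version = "unknown"
    manifest = {
        "seed": seed,
        "config": dict(config or {}),
        "config_hash": _config_hash(config or {}),
        "versions": {"cannacea": version, "numpy": np.__version__,
                     "pandas": pd.__version__},
        "files": [p.name for p in written],
    }
    manifest_path = out / "manifest.json"
    if manifest_path.exists() and not overwrite:
        raise FileExistsError(f"{manifest_path} exists; pass overwrite=True to replace it")
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
    written.append(manifest_path)
    return written
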
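"""Result persistence and summary tables.

Per-run results go to JSON, traces to CSV; summaries are arithmetic means per
group with the three metric columns (energy, minutes, dRMSD), recomputable
from the per-run files they aggregate.
"""
from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd

from .engine import RunResult


def save_result(result: RunResult, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(result.to_dict(), fh, indent=2)


def load_result(path) -> Dict:
    """Load a persisted result as a plain dict (traces as lists)."""
    with open(path) as fh:
        return json.load(fh)


def trace_frame(result: RunResult) -> pd.DataFrame:
    t = result.trace
    return pd.DataFrame(
        {
            "cycle": np.arange(t.n_cycles),
            "temperature": t.temperature,
            "energy": t.energy,
            "e_min": t.e_min,
            "acceptance_rate": t.acceptance,
        }
    )


def result_row(result) -> Dict:
    """Flatten one result (RunResult or persisted dict) into a summary row."""
    if isinstance(result, RunResult):
        d = result.to_dict()
    else:
        d = result
    return {
        "variant": d["variant"],
        "seed": d["seed"],
        "energy": d["best_energy"],
        "time_min": d["wall_time_s"] / 60.0,
        "drmsd": d.get("drmsd"),
        "n_evals": d["n_evals"],
        "alpha_annealing": d.get("config", {}).get("schedule", {}).get("alpha_annealing"),
        "map": d.get("config", {}).get("chaos", {}).get("map"),
    }


def summarize(
    results: Sequence, group_by: Sequence[str] = ("variant",)
) -> pd.DataFrame:
    """Per-group means of energy, wall time (minutes) and dRMSD.

    Accepts RunResult objects or dicts loaded from per-run files; the means
    are exact arithmetic means, so a summary is always recomputable from the
    files it came from.
    """
    if not results:
        raise ValueError("summarize needs at least one result")
    rows = pd.DataFrame([result_row(r) for r in results])
    grouped = (
        rows.groupby(list(group_by), dropna=False)
        .agg(
            mean_energy=("energy", "mean"),
            mean_time_min=("time_min", "mean"),
            mean_drmsd=("drmsd", "mean"),
            n_seeds=("seed", "size"),
        )
        .reset_index()
    )
    return grouped
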
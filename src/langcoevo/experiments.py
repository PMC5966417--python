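"""Orchestration: replicate runs, parameter sweeps, manifests.

A "failed" trial is one whose language population empties at some
generation — after that no communication can ever succeed, so the run is
stagnant; the generation of total extinction is recorded per run.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
import subprocess
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core import RunTrace, SimParams, run_simulation

__all__ = [
    "SweepSpec",
    "run_replicates",
    "sweep",
    "summarize_run",
    "phase_start_generation",
    "cycle_period_estimate",
    "write_manifest",
]

log = logging.getLogger(__name__)

#: When sweeping the displacement unit F, the division threshold follows
#: Fd = F * FD_LINK_FACTOR unless the caller overrides it.
FD_LINK_FACTOR = 300.0


@dataclass
class SweepSpec:
    """One-axis parameter sweep with replicates per value."""

    base: SimParams
    axis: str
    values: Sequence
    replicates: int = 3
    seed0: int = 0
    link_fd: bool = True  # apply Fd = F * 300 when axis == "F"
    stop_on_extinction: bool = False

    def __post_init__(self):
        if self.axis not in SimParams().to_dict():
            raise ValueError(f"axis {self.axis!r} is not a SimParams field")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")

    def cell_params(self, value) -> SimParams:
        updates = {self.axis: value}
        if self.axis == "F" and self.link_fd:
            updates["Fd"] = value * FD_LINK_FACTOR
        return replace(self.base, **updates)


def _params_hash(params: SimParams) -> str:
    blob = json.dumps(params.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _code_version() -> str:
    try:
        out = subprocess.run(
            ["git", "describe", "--always", "--dirty"],
            capture_output=True, text=True, timeout=5,
            cwd=Path(__file__).parent,
        )
        if out.returncode == 0:
            return out.stdout.strip()
    except Exception:  # pragma: no cover - git may be absent
        pass
    try:
        from importlib.metadata import version
        return "langcoevo-" + version("langcoevo")
    except Exception:  # pragma: no cover
        return "unknown"


def run_replicates(
    params: SimParams,
    n: int,
    seeds: Sequence[int] | None = None,
    out_dir: str | Path | None = None,
    stop_on_extinction: bool = False,
) -> list[RunTrace]:
    """Run ``n`` independent seeded replicates (optionally persisted).

    ``seeds`` defaults to ``params.seed, params.seed + 1, ...``.  Per-run
    failures are isolated and logged; total extinction is an outcome, not a
    failure.  With ``out_dir`` each run is written to ``run_<k>/`` and a
    ``manifest.json`` records params hash, seed and code version per run.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if seeds is None:
        seeds = [params.seed + k for k in range(n)]
    if len(seeds) != n:
        raise ValueError("need exactly n seeds")
    traces: list[RunTrace] = []
    records = []
    for k, seed in enumerate(seeds):
        p = replace(params, seed=int(seed))
        try:
            tr = run_simulation(p, stop_on_extinction=stop_on_extinction)
        except Exception:
            log.exception("replicate %d (seed %d) failed", k, seed)
            records.append({"run": k, "seed": int(seed), "status": "error"})
            continue
        traces.append(tr)
        rec = {
            "run": k,
            "seed": int(seed),
            "status": "ok",
            "params_hash": _params_hash(p),
            "total_extinction_generation": tr.total_extinction_generation,
        }
        if tr.total_extinction_generation is not None:
            log.info("replicate %d: total extinction at generation %d",
                     k, tr.total_extinction_generation)
        records.append(rec)
        if out_dir is not None:
            run_dir = Path(out_dir) / f"run_{k}"
            tr.write(run_dir)
            rec["path"] = str(run_dir)
    if out_dir is not None:
        write_manifest(out_dir, params, records)
    return traces


def write_manifest(out_dir: str | Path, params: SimParams,
                   records: list[dict]) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "params": params.to_dict(),
        "params_hash": _params_hash(params),
        "code_version": _code_version(),
        "runs": records,
    }
    path = out / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2)
    return path


# ---------------------------------------------------------------------------
# per-run summaries
# ---------------------------------------------------------------------------


def phase_start_generation(trace: RunTrace) -> int | None:
    """First generation where mean plasticity drops below half its running
    maximum — a proxy for the onset of the low-plasticity coevolution phase."""
    p = np.asarray(trace.mean_p, dtype=float)
    if len(p) == 0:
        return None
    running_max = np.maximum.accumulate(p)
    below = np.nonzero(p < 0.5 * running_max)[0]
    return int(trace.gen[below[0]]) if len(below) else None


def cycle_period_estimate(trace: RunTrace, min_lag: int = 10) -> float:
    """Crude cycle-period proxy: the lag of the first autocorrelation peak
    of the mean-plasticity series beyond ``min_lag`` (NaN if none)."""
    p = np.asarray(trace.mean_p, dtype=float)
    p = p[np.isfinite(p)]
    if len(p) < 3 * min_lag:
        return math.nan
    x = p - p.mean()
    if np.allclose(x, 0):
        return math.nan
    ac = np.correlate(x, x, mode="full")[len(x) - 1:]
    ac = ac / ac[0]
    seg = ac[min_lag: len(ac) // 2]
    if len(seg) < 3:
        return math.nan
    # first local maximum with positive autocorrelation
    for k in range(1, len(seg) - 1):
        if seg[k] > seg[k - 1] and seg[k] >= seg[k + 1] and seg[k] > 0:
            return float(min_lag + k)
    return math.nan


def summarize_run(trace: RunTrace) -> dict:
    extinct = trace.total_extinction_generation
    last_lang = trace.mean_lang_pos[np.isfinite(trace.mean_lang_pos)]
    return {
        "generations": len(trace),
        "extinct": extinct is not None,
        "extinction_generation": extinct,
        "final_mean_a": float(trace.mean_a[-1]) if len(trace) else math.nan,
        "final_mean_lang_pos": float(last_lang[-1]) if len(last_lang) else math.nan,
        "phase_start": phase_start_generation(trace),
        "cycle_period": cycle_period_estimate(trace),
    }


def sweep(spec: SweepSpec, out_dir: str | Path | None = None) -> pd.DataFrame:
    """Run the sweep and return one row per (axis value, replicate).

    Cell summaries (extinction fraction, extinction-generation stats, final
    expressiveness, phase/cycle proxies) are straightforward group-bys on
    the returned table.
    """
    rows = []
    for value in spec.values:
        params = spec.cell_params(value)
        cell_dir = None
        if out_dir is not None:
            cell_dir = Path(out_dir) / f"{spec.axis}={value}"
        traces = run_replicates(
            params, spec.replicates,
            seeds=[spec.seed0 + k for k in range(spec.replicates)],
            out_dir=cell_dir,
            stop_on_extinction=spec.stop_on_extinction,
        )
        for k, tr in enumerate(traces):
            row = {"axis": spec.axis, "value": value, "replicate": k}
            row.update(summarize_run(tr))
            rows.append(row)
    df = pd.DataFrame(rows)
    if out_dir is not None and len(df):
        Path(out_dir).mkdir(parents=True, exist_ok=True)
        df.to_csv(Path(out_dir) / "sweep.csv", index=False)
    return df
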
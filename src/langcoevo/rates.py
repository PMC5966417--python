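"""Evolutionary rates in darwins, swept over measurement intervals.

A darwin here is one e-fold of change in a (positive) trait value per
generation: ``d = (ln v2 - ln v1) / dt``.  Biological rates are taken from
the per-generation mean innate ability series over non-overlapping windows
of length ``dt``; cultural rates are taken per cultural event (change one
sample, division and fusion two samples each, extinction none), with each
event's value pair re-evaluated at every ``dt`` on the grid so a single
event log yields a rate-versus-interval curve.

Reported rates are magnitudes ``|d|`` (signed values are kept in the sample
tables).  Samples with a non-positive endpoint are excluded and tallied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import CulturalEvent, RunTrace

__all__ = [
    "darwin_rate",
    "biological_rates",
    "cultural_rates",
    "rate_interval_sweep",
    "RateSweep",
    "DEFAULT_DT_GRID",
]

#: Ten measurement intervals (the source analysis used ten; the exact values
#: are not published, so this grid is configurable everywhere it is used).
DEFAULT_DT_GRID = (1, 10, 50, 110, 200, 400, 700, 1100, 1500, 2000)

SAMPLE_COLUMNS = ["dt", "source", "event_kind", "rate", "signed_rate"]


def darwin_rate(v1: float, v2: float, dt: float) -> float:
    """``(ln v2 - ln v1) / dt``; raises on non-positive inputs."""
    if not (v1 > 0 and v2 > 0):
        raise ValueError("darwin_rate requires positive trait values")
    if not dt > 0:
        raise ValueError("darwin_rate requires a positive interval")
    return (math.log(v2) - math.log(v1)) / dt


def _empty_samples() -> pd.DataFrame:
    return pd.DataFrame({
        "dt": pd.Series(dtype=int),
        "source": pd.Series(dtype=object),
        "event_kind": pd.Series(dtype=object),
        "rate": pd.Series(dtype=float),
        "signed_rate": pd.Series(dtype=float),
    })


def biological_rates(
    trace: RunTrace | np.ndarray | Sequence[float],
    dt_grid: Iterable[int] = DEFAULT_DT_GRID,
) -> tuple[pd.DataFrame, dict[int, int]]:
    """Rates of the mean innate-ability series at each interval.

    For each ``dt`` the series is sampled at ``t = 0, dt, 2dt, ...``
    (non-overlapping windows) and each consecutive pair yields one sample.
    Returns ``(samples, skipped)`` where ``skipped[dt]`` counts windows
    dropped for a non-positive endpoint.
    """
    series = trace.mean_a if isinstance(trace, RunTrace) else np.asarray(trace, float)
    series = np.asarray(series, dtype=float)
    frames = []
    skipped: dict[int, int] = {}
    for dt in dt_grid:
        dt = int(dt)
        if dt < 1:
            raise ValueError("dt values must be >= 1")
        starts = np.arange(0, len(series) - dt, dt)
        v1 = series[starts]
        v2 = series[starts + dt]
        ok = (v1 > 0) & (v2 > 0) & np.isfinite(v1) & np.isfinite(v2)
        skipped[dt] = int(len(starts) - ok.sum())
        signed = (np.log(v2[ok]) - np.log(v1[ok])) / dt
        frames.append(pd.DataFrame({
            "dt": dt,
            "source": "biological",
            "event_kind": "",
            "rate": np.abs(signed),
            "signed_rate": signed,
        }))
    samples = pd.concat(frames, ignore_index=True) if frames else _empty_samples()
    return samples, skipped


def _event_value_pairs(events: Iterable[CulturalEvent]
                       ) -> list[tuple[str, float, float]]:
    """(kind, v1, v2) pairs: change 1, division 2, fusion 2, extinction 0."""
    pairs: list[tuple[str, float, float]] = []
    for ev in events:
        if ev.kind == "change":
            pairs.append(("change", ev.parent_positions[0], ev.child_positions[0]))
        elif ev.kind == "division":
            for child in ev.child_positions:
                pairs.append(("division", ev.parent_positions[0], child))
        elif ev.kind == "fusion":
            for parent in ev.parent_positions:
                pairs.append(("fusion", parent, ev.child_positions[0]))
        # extinction: no rate
    return pairs


def cultural_rates(
    events: Iterable[CulturalEvent],
    dt_grid: Iterable[int] = DEFAULT_DT_GRID,
) -> tuple[pd.DataFrame, dict[int, int]]:
    """Per-event rates evaluated at every interval on the grid.

    Each event's ``(v1, v2)`` pair is treated as the change observed over a
    measurement window of length ``dt``, which carries the mechanical
    ``1/dt`` interval dependence under study.  Pairs with a non-positive
    endpoint are excluded (tallied per ``dt``).
    """
    pairs = _event_value_pairs(events)
    kinds = np.array([k for k, _, _ in pairs], dtype=object)
    v1 = np.array([a for _, a, _ in pairs], dtype=float)
    v2 = np.array([b for _, _, b in pairs], dtype=float)
    ok = (v1 > 0) & (v2 > 0)
    log_ratio = np.zeros(len(pairs))
    log_ratio[ok] = np.log(v2[ok]) - np.log(v1[ok])
    frames = []
    skipped: dict[int, int] = {}
    for dt in dt_grid:
        dt = int(dt)
        if dt < 1:
            raise ValueError("dt values must be >= 1")
        skipped[dt] = int((~ok).sum())
        signed = log_ratio[ok] / dt
        frames.append(pd.DataFrame({
            "dt": dt,
            "source": "cultural",
            "event_kind": kinds[ok],
            "rate": np.abs(signed),
            "signed_rate": signed,
        }))
    samples = pd.concat(frames, ignore_index=True) if frames else _empty_samples()
    return samples, skipped


@dataclass
class RateSweep:
    """Aggregated rate analysis over a grid of intervals."""

    samples: pd.DataFrame
    summary: pd.DataFrame
    cultural_spearman: tuple[float, float]  # (rho, p) of dt vs median cultural rate

    def median(self, dt: int, source: str, event_kind: str = "all") -> float:
        sel = self.summary[
            (self.summary["dt"] == dt)
            & (self.summary["source"] == source)
            & (self.summary["event_kind"] == event_kind)
        ]
        return float(sel["median"].iloc[0]) if len(sel) else math.nan


def _summarize(samples: pd.DataFrame, skipped: dict[int, int], source: str,
               by_kind: bool) -> pd.DataFrame:
    rows = []
    groups = [("all", samples)]
    if by_kind:
        groups += [(k, g) for k, g in samples.groupby("event_kind")]
    for kind, g in groups:
        for dt, gd in g.groupby("dt"):
            rows.append({
                "dt": int(dt),
                "source": source,
                "event_kind": kind,
                "n": len(gd),
                "median": float(gd["rate"].median()),
                "q25": float(gd["rate"].quantile(0.25)),
                "q75": float(gd["rate"].quantile(0.75)),
                "n_skipped": skipped.get(int(dt), 0),
            })
    return pd.DataFrame(rows)


def rate_interval_sweep(
    trace: RunTrace | Sequence[RunTrace],
    events: Iterable[CulturalEvent] | None = None,
    dt_grid: Iterable[int] = DEFAULT_DT_GRID,
) -> RateSweep:
    """Pool biological and cultural rate samples over the interval grid.

    Accepts one trace or several replicate traces (samples are pooled).
    ``events`` defaults to the traces' own event logs.  The summary holds
    per-``(dt, source, event_kind)`` medians and quartiles ("all" pools the
    cultural kinds), plus the Spearman correlation between ``dt`` and the
    pooled median cultural rate.
    """
    traces = [trace] if isinstance(trace, RunTrace) else list(trace)
    dt_grid = [int(d) for d in dt_grid]
    bio_frames, cult_frames = [], []
    bio_skipped: dict[int, int] = {d: 0 for d in dt_grid}
    cult_skipped: dict[int, int] = {d: 0 for d in dt_grid}
    for tr in traces:
        bs, bsk = biological_rates(tr, dt_grid)
        evs = tr.events if events is None else events
        cs, csk = cultural_rates(evs, dt_grid)
        bio_frames.append(bs)
        cult_frames.append(cs)
        for d in dt_grid:
            bio_skipped[d] += bsk.get(d, 0)
            cult_skipped[d] += csk.get(d, 0)
        if events is not None:
            break  # explicit event list: single pooled pass
    bio = pd.concat(bio_frames, ignore_index=True) if bio_frames else _empty_samples()
    cult = pd.concat(cult_frames, ignore_index=True) if cult_frames else _empty_samples()
    summary = pd.concat(
        [_summarize(bio, bio_skipped, "biological", by_kind=False),
         _summarize(cult, cult_skipped, "cultural", by_kind=True)],
        ignore_index=True,
    )
    cult_all = summary[(summary.source == "cultural") & (summary.event_kind == "all")]
    if len(cult_all) >= 2 and cult_all["median"].nunique() > 1:
        rho, p = stats.spearmanr(cult_all["dt"], cult_all["median"])
        spearman = (float(rho), float(p))
    else:
        spearman = (math.nan, math.nan)
    samples = pd.concat([bio, cult], ignore_index=True)
    return RateSweep(samples=samples, summary=summary, cultural_spearman=spearman)
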
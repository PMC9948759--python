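"""Event classification and transition statistics for microtubule tip traces.

The input is a manually traced (or simulated) tip trajectory: a time-ordered
polyline of (time, position) vertices.  Each inter-vertex segment is
classified by its velocity — faster than the cutoff is growth, faster
shrinkage than the cutoff is shrinkage, anything slower is a pause — and
consecutive same-state segments are merged into events.  Events that fail the
inclusion filters (growth/shrinkage excursions not longer than the minimum
length, pauses not longer than the minimum duration) are flagged
``included=False``; for the contiguous timeline used by state fractions and
transition frequencies they are absorbed into the preceding included event.

Transition frequency for an ordered state pair (s -> t) is the number of
s -> t transitions divided by the total time spent in state s ("the time the
event could have occurred").  Exits from shrinkage forced by the tip reaching
the stabilized seed are excluded from transition counts but their dwell time
stays in the denominator (censored-exponential estimate), so recovered
frequencies are directly comparable to simulator ground-truth rates.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .simulate.dynamics import TRANSITIONS, TipTrajectory

EVENT_COLUMNS = [
    "state", "t_start", "t_end", "x_start", "x_end",
    "duration_s", "length_um", "velocity_um_min", "included",
]


@dataclass
class Thresholds:
    """Classification cutoffs, in the units used for kymograph tracing."""

    v_min: float = 0.24            # µm/min; strictly faster counts as growth
    min_growth_length: float = 0.40  # µm; strictly longer is included
    min_pause_duration: float = 20.0  # s; strictly longer is included

    def __post_init__(self) -> None:
        if self.v_min <= 0 or self.min_growth_length <= 0 or self.min_pause_duration <= 0:
            raise ValueError("all thresholds must be > 0")


def classify_and_filter(times: Sequence[float], positions: Sequence[float],
                        thresholds: Thresholds | None = None) -> pd.DataFrame:
    """Classify a traced polyline into growth / pause / shrinkage events.

    Returns the contiguous, time-ordered event table with an ``included``
    flag.  Velocity classification is strict: a segment at exactly ±v_min is
    a pause.  Event velocity is recomputed from the event endpoints.
    """
    thr = thresholds or Thresholds()
    t = np.asarray(times, dtype=float)
    x = np.asarray(positions, dtype=float)
    if t.ndim != 1 or len(t) < 2 or len(t) != len(x):
        raise ValueError("need >= 2 (time, position) vertices")
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise ValueError("times must be strictly increasing (no duplicates)")
    v = np.diff(x) / dt * 60.0  # µm/min
    seg_state = np.where(v > thr.v_min, "growth",
                         np.where(v < -thr.v_min, "shrinkage", "pause"))

    rows = []
    start = 0
    for i in range(1, len(v) + 1):
        if i == len(v) or seg_state[i] != seg_state[start]:
            rows.append((seg_state[start], t[start], t[i], x[start], x[i]))
            start = i
    events = pd.DataFrame(rows, columns=["state", "t_start", "t_end", "x_start", "x_end"])
    events["duration_s"] = events.t_end - events.t_start
    events["length_um"] = (events.x_end - events.x_start).abs()
    events["velocity_um_min"] = (events.x_end - events.x_start) / events.duration_s * 60.0
    is_pause = events.state == "pause"
    events["included"] = np.where(
        is_pause,
        events.duration_s > thr.min_pause_duration,
        events.length_um > thr.min_growth_length,
    )
    return events[EVENT_COLUMNS]


def merge_excluded(events: pd.DataFrame) -> pd.DataFrame:
    """Contiguous effective timeline with sub-threshold events absorbed.

    Each excluded event is relabelled with the state of the preceding
    included event (leading excluded events take the state of the first
    included one); consecutive same-state stretches are then merged and event
    statistics recomputed from the merged endpoints.  If no event passes the
    filters the whole trace collapses to one event with the state of the
    longest raw event.
    """
    if events.empty:
        return events.copy()
    states = events.state.to_numpy(copy=True)
    inc = events.included.to_numpy()
    if inc.any():
        # backward fill from preceding included events; leading tail forward-fills
        eff = np.where(inc, states, None)
        last = None
        for i in range(len(eff)):
            if eff[i] is None:
                eff[i] = last
            else:
                last = eff[i]
        first_inc = next(s for s in eff if s is not None)
        eff = np.array([s if s is not None else first_inc for s in eff], dtype=object)
    else:
        dominant = events.loc[events.duration_s.idxmax(), "state"]
        eff = np.full(len(events), dominant, dtype=object)

    rows = []
    start = 0
    for i in range(1, len(eff) + 1):
        if i == len(eff) or eff[i] != eff[start]:
            rows.append((
                eff[start],
                events.t_start.iloc[start], events.t_end.iloc[i - 1],
                events.x_start.iloc[start], events.x_end.iloc[i - 1],
            ))
            start = i
    merged = pd.DataFrame(rows, columns=["state", "t_start", "t_end", "x_start", "x_end"])
    merged["duration_s"] = merged.t_end - merged.t_start
    merged["length_um"] = (merged.x_end - merged.x_start).abs()
    merged["velocity_um_min"] = (merged.x_end - merged.x_start) / merged.duration_s * 60.0
    merged["included"] = True
    return merged[EVENT_COLUMNS]


def transition_frequencies(events: pd.DataFrame,
                           boundary_position: Optional[float] = 0.0,
                           boundary_tol: float = 0.02) -> pd.DataFrame:
    """Counts and frequencies (1/s) for the six ordered state transitions.

    Operates on the effective (absorbed) timeline.  A transition out of
    shrinkage whose event ends at the seed (x_end within ``boundary_tol`` of
    ``boundary_position``) is a boundary artifact, not a stochastic rescue,
    and is excluded from the counts; pass ``boundary_position=None`` to count
    every transition.  ``boundary_tol`` should cover the position
    uncertainty of one sampling interval near the seed (default 0.02 µm).  States with zero total time get frequency NaN with
    ``defined=False`` (not zero).
    """
    if events.empty:
        raise ValueError("empty event table")
    merged = merge_excluded(events)
    time_in = merged.groupby("state").duration_s.sum()
    counts = {pair: 0 for pair in TRANSITIONS}
    for i in range(len(merged) - 1):
        src, dst = merged.state.iloc[i], merged.state.iloc[i + 1]
        if (boundary_position is not None and src == "shrinkage"
                and abs(merged.x_end.iloc[i] - boundary_position) <= boundary_tol):
            continue
        counts[(src, dst)] += 1
    rows = []
    for (src, dst) in TRANSITIONS:
        t_src = float(time_in.get(src, 0.0))
        defined = t_src > 0
        freq = counts[(src, dst)] / t_src if defined else math.nan
        rows.append((src, dst, counts[(src, dst)], t_src, freq, defined))
    return pd.DataFrame(
        rows, columns=["from", "to", "count", "time_in_state_s", "frequency_per_s", "defined"]
    )


@dataclass
class DynamicsSummary:
    """Pooled plus-end dynamics statistics over a set of microtubules."""

    growth_rate_mean: float
    growth_rate_sem: float
    pause_duration_mean: float
    pause_duration_sem: float
    state_fractions: dict[str, float]
    transitions: pd.DataFrame
    n_growth_events: int
    n_pauses: int
    n_mts: int

    def to_dict(self) -> dict:
        d = {
            "growth_rate_mean_um_min": self.growth_rate_mean,
            "growth_rate_sem_um_min": self.growth_rate_sem,
            "pause_duration_mean_s": self.pause_duration_mean,
            "pause_duration_sem_s": self.pause_duration_sem,
            "state_fractions": self.state_fractions,
            "n_growth_events": self.n_growth_events,
            "n_pauses": self.n_pauses,
            "n_mts": self.n_mts,
            "transitions": {
                f"{r['from']}->{r['to']}": {
                    "count": int(r["count"]),
                    "frequency_per_s": None if not r["defined"] else r["frequency_per_s"],
                }
                for _, r in self.transitions.iterrows()
            },
        }
        return d


def _mean_sem(values: np.ndarray) -> tuple[float, float]:
    if len(values) == 0:
        return math.nan, math.nan
    mean = float(np.mean(values))
    sem = float(np.std(values, ddof=1) / np.sqrt(len(values))) if len(values) > 1 else math.nan
    return mean, sem


def summarize_dynamics(event_tables: Iterable[pd.DataFrame],
                       boundary_position: Optional[float] = 0.0,
                       boundary_tol: float = 0.02) -> DynamicsSummary:
    """Pool event tables from many microtubules into one summary.

    Growth-rate and pause-duration statistics use the included raw events
    (mean ± SEM over events, sample SD with ddof=1); state time fractions and
    transition frequencies use the absorbed contiguous timelines, with counts
    and state times pooled before division.
    """
    tables = list(event_tables)
    if not tables:
        raise ValueError("need at least one microtubule")
    growth_v, pause_d = [], []
    time_in = {s: 0.0 for s in ("growth", "pause", "shrinkage")}
    counts = {pair: 0 for pair in TRANSITIONS}
    for ev in tables:
        inc = ev[ev.included]
        growth_v.extend(inc.loc[inc.state == "growth", "velocity_um_min"])
        pause_d.extend(inc.loc[inc.state == "pause", "duration_s"])
        tf = transition_frequencies(ev, boundary_position=boundary_position,
                                    boundary_tol=boundary_tol)
        for _, r in tf.iterrows():
            counts[(r["from"], r["to"])] += int(r["count"])
        merged = merge_excluded(ev)
        for s, d in merged.groupby("state").duration_s.sum().items():
            time_in[s] += float(d)
    total = sum(time_in.values())
    fractions = {s: (time_in[s] / total if total > 0 else math.nan) for s in time_in}
    rows = []
    for (src, dst) in TRANSITIONS:
        t_src = time_in[src]
        defined = t_src > 0
        freq = counts[(src, dst)] / t_src if defined else math.nan
        rows.append((src, dst, counts[(src, dst)], t_src, freq, defined))
    transitions = pd.DataFrame(
        rows, columns=["from", "to", "count", "time_in_state_s", "frequency_per_s", "defined"]
    )
    g_mean, g_sem = _mean_sem(np.asarray(growth_v))
    p_mean, p_sem = _mean_sem(np.asarray(pause_d))
    return DynamicsSummary(
        growth_rate_mean=g_mean, growth_rate_sem=g_sem,
        pause_duration_mean=p_mean, pause_duration_sem=p_sem,
        state_fractions=fractions, transitions=transitions,
        n_growth_events=len(growth_v), n_pauses=len(pause_d), n_mts=len(tables),
    )


@dataclass
class SurvivalResult:
    percent_surviving: float
    n: int
    n_survived: int
    n_censored: int  # records shorter than the horizon that never reached 0

    @property
    def partial(self) -> bool:
        return self.n_censored > 0


def seed_survival(trajectories: Iterable[TipTrajectory], horizon: float = 300.0,
                  tol: float = 1e-9) -> SurvivalResult:
    """Percentage of seeds whose length never reaches 0 before ``horizon`` s."""
    n = survived = censored = 0
    for traj in trajectories:
        n += 1
        within = traj.times <= horizon + tol
        died = bool(np.any(traj.positions[within] <= tol))
        if not died:
            survived += 1
            if traj.times[-1] < horizon - tol:
                censored += 1
    if n == 0:
        raise ValueError("no trajectories")
    return SurvivalResult(100.0 * survived / n, n, survived, censored)


def analyze_trajectory(traj: TipTrajectory,
                       thresholds: Thresholds | None = None) -> pd.DataFrame:
    """Classify a simulated/loaded trajectory's sampled polyline."""
    return classify_and_filter(traj.times, traj.positions, thresholds)
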
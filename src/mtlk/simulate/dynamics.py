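"""Three-state (growth / pause / shrinkage) tip-trajectory simulator.

Dynamic instability is modelled as a continuous-time Markov chain over the
three dynamic states, with exponential dwell times set by six ordered
transition rates (per second).  The tip position integrates +v_growth during
growth, 0 during pause and -v_shrink during shrinkage, and is floored at the
seed (position 0): on a stabilized seed the tip re-enters growth, while in
"stop" mode the record ends (a depolymerized seed).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

STATES = ("growth", "pause", "shrinkage")

#: ordered state pairs, in the conventional reporting order
TRANSITIONS = (
    ("growth", "shrinkage"),
    ("growth", "pause"),
    ("pause", "growth"),
    ("pause", "shrinkage"),
    ("shrinkage", "growth"),
    ("shrinkage", "pause"),
)


@dataclass
class DynamicsConfig:
    """Ground-truth parameters of a simulated dynamic microtubule.

    Velocities are in µm/min (the units used for kymograph measurements),
    transition rates in 1/s, times in seconds, positions in µm.
    """

    v_growth: float = 2.0
    v_shrink: float = 30.0
    growth_to_shrinkage: float = 0.0  # catastrophe
    growth_to_pause: float = 0.0
    pause_to_growth: float = 0.0
    pause_to_shrinkage: float = 0.0
    shrinkage_to_growth: float = 0.0  # rescue
    shrinkage_to_pause: float = 0.0
    duration: float = 600.0
    dt: float = 0.5
    seed_length: float = 0.0
    initial_state: str = "growth"
    boundary: str = "reset"  # "reset": re-enter growth at 0; "stop": record ends
    rng_seed: int = 0

    def rate(self, src: str, dst: str) -> float:
        return getattr(self, f"{src}_to_{dst}")

    def validate(self) -> None:
        for s, t in TRANSITIONS:
            r = self.rate(s, t)
            if not math.isfinite(r) or r < 0:
                raise ValueError(f"rate {s}->{t} must be finite and >= 0, got {r}")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.duration < self.dt:
            raise ValueError("duration must be >= dt")
        if self.v_growth <= 0 or self.v_shrink <= 0:
            raise ValueError("velocities must be > 0")
        if self.initial_state not in STATES:
            raise ValueError(f"unknown state {self.initial_state!r}")
        if self.boundary not in ("reset", "stop"):
            raise ValueError("boundary must be 'reset' or 'stop'")
        if self.seed_length < 0:
            raise ValueError("seed_length must be >= 0")


@dataclass
class TipTrajectory:
    """Sampled tip trajectory with, for simulations, per-sample truth labels.

    ``segments`` is the exact continuous-time record: one row per dwell with
    columns state, t0, t1, x0, x1 and a ``boundary`` flag marking dwells that
    were terminated by the tip hitting the seed rather than by a stochastic
    transition.
    """

    times: np.ndarray
    positions: np.ndarray
    true_states: Optional[np.ndarray] = None
    segments: Optional[pd.DataFrame] = None
    seed_length: float = 0.0
    config: Optional[DynamicsConfig] = None
    mt_id: int = 0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if len(self.times) != len(self.positions):
            raise ValueError("times and positions must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.positions < -1e-12):
            raise ValueError("positions must be >= 0")

    def __len__(self) -> int:
        return len(self.times)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"mt_id": self.mt_id, "time_s": self.times, "position_um": self.positions}
        )
        if self.true_states is not None:
            df["state"] = self.true_states
        return df


def _velocity(state: str, cfg: DynamicsConfig) -> float:
    """Signed tip velocity in µm/s for a given state."""
    if state == "growth":
        return cfg.v_growth / 60.0
    if state == "shrinkage":
        return -cfg.v_shrink / 60.0
    return 0.0


def simulate_dynamics(config: DynamicsConfig) -> TipTrajectory:
    """Simulate one tip trajectory with the Gillespie algorithm.

    Returns the trajectory sampled on the dt grid together with the exact
    continuous-time segment record and per-sample ground-truth state labels.
    Identical config (including ``rng_seed``) gives identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.rng_seed)

    t, x, state = 0.0, float(config.seed_length), config.initial_state
    seg_rows = []
    while t < config.duration:
        rates = {d: config.rate(state, d) for d in STATES if d != state}
        total = sum(rates.values())
        dwell = rng.exponential(1.0 / total) if total > 0 else math.inf
        t_next = min(t + dwell, config.duration)
        v = _velocity(state, config)
        x_next = x + v * (t_next - t)
        hit_seed = state == "shrinkage" and x_next <= 0.0 and x > 0.0
        if state == "shrinkage" and x <= 0.0:
            hit_seed = True  # already at the seed when shrinkage was entered
            t_next = t
        if hit_seed:
            t_hit = t + (x - 0.0) / (-v) if v < 0 else t
            t_hit = min(t_hit, config.duration)
            seg_rows.append((state, t, t_hit, x, 0.0, True))
            t, x = t_hit, 0.0
            if config.boundary == "stop":
                break
            state = "growth"
            continue
        seg_rows.append((state, t, t_next, x, x_next, False))
        t, x = t_next, x_next
        if t >= config.duration or total == 0:
            break
        # choose destination proportionally to the exit rates
        dests = sorted(rates)
        probs = np.array([rates[d] for d in dests]) / total
        state = dests[rng.choice(len(dests), p=probs)]

    segments = pd.DataFrame(
        seg_rows, columns=["state", "t0", "t1", "x0", "x1", "boundary"]
    )
    segments = segments[segments.t1 > segments.t0].reset_index(drop=True)
    t_end = seg_rows[-1][2] if seg_rows else 0.0
    times = np.arange(0.0, t_end + config.dt * 0.5, config.dt)
    if len(times) < 2:
        times = np.array([0.0, config.dt])
    positions = _sample_positions(segments, times, config)
    states = _sample_states(segments, times)
    return TipTrajectory(
        times=times,
        positions=positions,
        true_states=states,
        segments=segments,
        seed_length=config.seed_length,
        config=config,
    )


def _sample_positions(segments: pd.DataFrame, times: np.ndarray,
                      config: DynamicsConfig) -> np.ndarray:
    if segments.empty:
        return np.full_like(times, config.seed_length)
    knots_t = np.concatenate([[segments.t0.iloc[0]], segments.t1.to_numpy()])
    knots_x = np.concatenate([[segments.x0.iloc[0]], segments.x1.to_numpy()])
    return np.interp(times, knots_t, knots_x)


def _sample_states(segments: pd.DataFrame, times: np.ndarray) -> np.ndarray:
    if segments.empty:
        return np.full(len(times), "growth", dtype=object)
    idx = np.searchsorted(segments.t1.to_numpy(), times, side="left")
    idx = np.clip(idx, 0, len(segments) - 1)
    return segments.state.to_numpy()[idx]


def simulate_many(config: DynamicsConfig, n: int) -> list[TipTrajectory]:
    """Simulate ``n`` independent trajectories, seeded from ``config.rng_seed``."""
    seeds = np.random.default_rng(config.rng_seed).integers(0, 2**31 - 1, size=n)
    out = []
    for i, s in enumerate(seeds):
        traj = simulate_dynamics(replace(config, rng_seed=int(s)))
        traj.mt_id = i
        out.append(traj)
    return out


def render_kymograph(traj: TipTrajectory, pixel_size: float = 0.1,
                     line_time: float = 1.0, psf_sigma: float = 1.5,
                     background: float = 0.0, noise_sd: float = 0.0,
                     amplitude: float = 100.0, rng_seed: int = 0) -> np.ndarray:
    """Render a kymograph image (rows = time, columns = position).

    The tip appears as a Gaussian ridge of width ``psf_sigma`` pixels at
    x(t)/pixel_size; the kernel is truncated at 5 sigma so pixels far from the
    ridge are exactly ``background`` (before noise).  Intensities are clipped
    at zero after adding Gaussian noise.
    """
    if pixel_size <= 0 or line_time <= 0:
        raise ValueError("pixel_size and line_time must be > 0")
    t_total = traj.times[-1] - traj.times[0]
    n_rows = int(t_total / line_time)
    if n_rows < 1:
        raise ValueError("trajectory shorter than one kymograph row")
    row_times = traj.times[0] + (np.arange(n_rows) + 0.5) * line_time
    x_t = np.interp(row_times, traj.times, traj.positions)
    n_cols = int(np.ceil((traj.positions.max() / pixel_size) + 6 * psf_sigma + 2))
    img = np.full((n_rows, n_cols), float(background))
    cols = np.arange(n_cols)
    centers = x_t / pixel_size
    d = cols[None, :] - centers[:, None]
    ridge = np.where(np.abs(d) < 5 * psf_sigma,
                     amplitude * np.exp(-0.5 * (d / psf_sigma) ** 2), 0.0)
    img += ridge
    if noise_sd > 0:
        img += np.random.default_rng(rng_seed).normal(0.0, noise_sd, img.shape)
    return np.clip(img, 0.0, None).astype(np.float32)
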
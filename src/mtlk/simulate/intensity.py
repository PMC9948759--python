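"""Synthetic single-molecule intensity traces with stepwise arrivals.

Each trace models one membrane-distal binding site: a first molecule is bound
at t = 0 and up to ``plateau_molecules - 1`` further molecules arrive with
exponential waiting times at rate ``k_assoc``, so the expected molecule
number follows 1 + (plateau - 1)(1 - exp(-k t)).  Per-molecule brightness is
lognormal; filament-bound signal may be attenuated by a TIRF z-factor.  A
separate off-filament single-fluorophore calibration sample (no attenuation)
is generated alongside.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class IntensitySimSpec:
    mu_log: float = float(np.log(100.0))  # natural-log mean of brightness (a.u.)
    sigma_log: float = 0.35
    plateau_molecules: float = 2.0
    k_assoc: float = 0.1        # 1/s
    z_attenuation: float = 1.0  # in (0, 1]; applied to filament-bound signal
    frame_interval: float = 1.0  # s
    n_traces: int = 54
    trace_length: int = 60      # frames
    noise_sd: float = 0.0       # additive a.u. per frame
    n_single: int = 2000        # size of the calibration sample
    rng_seed: int = 0

    def validate(self) -> None:
        if self.sigma_log < 0:
            raise ValueError("sigma_log must be >= 0")
        if not (0 < self.z_attenuation <= 1):
            raise ValueError("z_attenuation must be in (0, 1]")
        if self.plateau_molecules < 1:
            raise ValueError("plateau_molecules must be >= 1")
        if self.frame_interval <= 0 or self.trace_length < 1 or self.n_traces < 1:
            raise ValueError("invalid trace geometry")


@dataclass
class IntensityTraces:
    """Simulated traces plus ground truth and the calibration sample."""

    times: np.ndarray            # (T,) s
    traces: np.ndarray           # (n_traces, T) a.u.
    arrival_times: list          # per trace, arrival times of molecules 2..m
    single_sample: np.ndarray    # off-filament single-fluorophore intensities
    spec: IntensitySimSpec


def simulate_intensity_traces(spec: IntensitySimSpec) -> IntensityTraces:
    spec.validate()
    rng = np.random.default_rng(spec.rng_seed)
    times = np.arange(spec.trace_length) * spec.frame_interval

    n_full = int(np.floor(spec.plateau_molecules - 1.0))
    frac = (spec.plateau_molecules - 1.0) - n_full

    traces = np.empty((spec.n_traces, spec.trace_length))
    arrivals_all = []
    for i in range(spec.n_traces):
        n_slots = n_full + (1 if (frac > 0 and rng.random() < frac) else 0)
        if np.isinf(spec.k_assoc):
            arrivals = np.zeros(n_slots)
        elif spec.k_assoc > 0:
            arrivals = rng.exponential(1.0 / spec.k_assoc, size=n_slots)
        else:
            arrivals = np.full(n_slots, np.inf)
        brightness = np.exp(rng.normal(spec.mu_log, spec.sigma_log, size=1 + n_slots))
        sig = np.full(spec.trace_length, brightness[0])
        for a, b in zip(arrivals, brightness[1:]):
            sig = sig + b * (times >= a)
        sig = sig * spec.z_attenuation
        if spec.noise_sd > 0:
            sig = sig + rng.normal(0.0, spec.noise_sd, size=spec.trace_length)
        traces[i] = sig
        arrivals_all.append(arrivals)

    single = np.exp(rng.normal(spec.mu_log, spec.sigma_log, size=spec.n_single))
    return IntensityTraces(times=times, traces=traces, arrival_times=arrivals_all,
                           single_sample=single, spec=spec)
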
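"""Single-molecule intensity stoichiometry.

Single-fluorophore brightness is calibrated by a lognormal fit whose mode,
exp(µ − σ²), serves as the one-molecule reference.  Accumulation intensities
divided by the single-molecule reference give molecule numbers; binding
kinetics are summarized by a one-phase association fit
I(t) = I0 + (plateau − I0)(1 − exp(−k t)); and intensity build-up profiles
are aligned at the half-maximum time of a Hill fit before averaging.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.optimize import curve_fit


@dataclass
class LognormalFit:
    mu_log: float
    sigma_log: float
    mode: float          # exp(µ − σ²)
    median: float        # exp(µ)
    quartiles: tuple     # (Q1, Q3)
    n: int


def fit_lognormal_mode(intensities: Sequence[float]) -> LognormalFit:
    """Closed-form maximum-likelihood lognormal fit of an intensity sample.

    µ and σ are the mean and SD of log-intensity (MLE, ddof=0); the reported
    mode exp(µ − σ²) is the single-fluorophore brightness reference.
    """
    x = np.asarray(intensities, dtype=float)
    if len(x) < 30:
        raise ValueError("need at least 30 intensities")
    if np.any(x <= 0):
        raise ValueError("intensities must be positive")
    logs = np.log(x)
    mu = float(np.mean(logs))
    sigma = float(np.std(logs, ddof=0))
    z = 0.6744897501960817  # standard-normal upper quartile
    return LognormalFit(
        mu_log=mu, sigma_log=sigma,
        mode=math.exp(mu - sigma**2), median=math.exp(mu),
        quartiles=(math.exp(mu - z * sigma), math.exp(mu + z * sigma)),
        n=len(x),
    )


def molecules_per_8nm(integrated_intensity: float, accumulation_length_nm: float,
                      single_mean_intensity: float) -> float:
    """Molecules per 8 nm of accumulation (one αβ-tubulin dimer layer).

    The integrated accumulation intensity is divided by the average single
    fluorophore intensity and normalized to an 8-nm accumulation length.
    """
    if accumulation_length_nm <= 0:
        raise ValueError("accumulation length must be > 0")
    if single_mean_intensity <= 0:
        raise ValueError("single-fluorophore mean intensity must be > 0")
    return (integrated_intensity / single_mean_intensity) * (8.0 / accumulation_length_nm)


@dataclass
class BindingRatio:
    ratio: float                  # modal on-filament / single-fluorophore mode
    ratio_corrected: float        # after optional z-attenuation correction
    is_monomer: bool
    band: tuple
    on_filament_mode: float
    single_mode: float


def initial_binding_ratio(first_frame_intensities: Sequence[float],
                          single_sample: Sequence[float],
                          z_attenuation: Optional[float] = None,
                          monomer_band: tuple = (0.6, 1.3)) -> BindingRatio:
    """Ratio of initial on-filament brightness to the single-fluorophore mode.

    Both samples are fitted with lognormals and compared by their modes.  If
    ``z_attenuation`` is given (e.g. ~0.8 for TIRF signal loss of
    filament-bound fluorophores further from the coverslip) the ratio is
    divided by it before the monomer call.
    """
    on = np.asarray(first_frame_intensities, dtype=float)
    single = np.asarray(single_sample, dtype=float)
    if len(on) == 0 or len(single) == 0:
        raise ValueError("both samples must be non-empty")
    on_mode = fit_lognormal_mode(on).mode if len(on) >= 30 else float(np.exp(
        np.mean(np.log(on)) - np.var(np.log(on))))
    single_mode = fit_lognormal_mode(single).mode if len(single) >= 30 else float(np.exp(
        np.mean(np.log(single)) - np.var(np.log(single))))
    ratio = on_mode / single_mode
    corrected = ratio / z_attenuation if z_attenuation else ratio
    return BindingRatio(
        ratio=ratio, ratio_corrected=corrected,
        is_monomer=monomer_band[0] <= corrected <= monomer_band[1],
        band=monomer_band, on_filament_mode=on_mode, single_mode=single_mode,
    )


@dataclass
class AssociationFit:
    i0: float        # molecules at t = 0
    plateau: float   # molecules
    k: float         # 1/s
    residual_rms: float
    converged: bool


def _one_phase(t, i0, plateau, k):
    return i0 + (plateau - i0) * (1.0 - np.exp(-k * t))


def fit_one_phase_association(times: Sequence[float],
                              intensities: Sequence[float]) -> AssociationFit:
    """Least-squares one-phase association fit of a mean intensity trace."""
    t = np.asarray(times, dtype=float)
    y = np.asarray(intensities, dtype=float)
    if len(t) < 5:
        raise ValueError("need at least 5 time points")
    i0_guess = float(y[0])
    plat_guess = float(np.mean(y[-max(len(y) // 5, 1):]))
    span = t[-1] - t[0]
    k_guess = 2.0 / span if span > 0 else 1.0
    try:
        popt, _ = curve_fit(
            _one_phase, t, y, p0=[i0_guess, plat_guess, k_guess],
            bounds=([-np.inf, -np.inf, 1e-9], [np.inf, np.inf, np.inf]),
            maxfev=20000,
        )
        converged = True
    except RuntimeError:
        popt, converged = [i0_guess, plat_guess, k_guess], False
    resid = y - _one_phase(t, *popt)
    return AssociationFit(i0=float(popt[0]), plateau=float(popt[1]), k=float(popt[2]),
                          residual_rms=float(np.sqrt(np.mean(resid**2))),
                          converged=converged)


def normalized_auc(times: Sequence[float], intensities: Sequence[float]) -> float:
    """Trapezoidal area under a max-normalized intensity profile."""
    t = np.asarray(times, dtype=float)
    y = np.asarray(intensities, dtype=float)
    if y.max() <= 0:
        raise ValueError("profile has no positive intensity")
    return float(np.trapezoid(y / y.max(), t))


def _hill(t, imax, K, n):
    t = np.asarray(t, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = imax * t**n / (K**n + t**n)
    return np.where(t <= 0, 0.0, out)


def _logistic(t, imax, t_half, slope):
    return imax / (1.0 + np.exp(-(t - t_half) / slope))


@dataclass
class AlignedProfiles:
    grid: np.ndarray          # common time grid, s (0 = half-maximum reference)
    mean: np.ndarray
    sem: np.ndarray
    references: np.ndarray    # per-profile half-maximum times, s (NaN = excluded)
    auc: np.ndarray           # per-profile trapezoidal AUC of the normalized profile
    n_used: int


def align_and_average_profiles(profiles: Iterable[tuple[np.ndarray, np.ndarray]],
                               model: str = "hill",
                               grid_step: Optional[float] = None) -> AlignedProfiles:
    """Normalize, align at the fitted half-maximum time, and average profiles.

    Each ``(times, intensity)`` profile is normalized to its maximum and
    fitted with a Hill curve I = Imax·tⁿ/(Kⁿ+tⁿ) (reference time = K, where
    I = Imax/2) or a generic logistic sigmoid (reference = its midpoint).
    Profiles are shifted so the references coincide at 0, interpolated to a
    common grid covering the overlap, and averaged with SEM.  Profiles whose
    fit fails are excluded and reported with reference NaN.
    """
    prof = [(np.asarray(t, float), np.asarray(y, float)) for t, y in profiles]
    if len(prof) < 2:
        raise ValueError("need at least 2 profiles")
    refs = np.full(len(prof), math.nan)
    normed = []
    aucs = np.full(len(prof), math.nan)
    for i, (t, y) in enumerate(prof):
        ymax = y.max()
        if ymax <= 0:
            continue
        yn = y / ymax
        aucs[i] = float(np.trapezoid(yn, t))
        try:
            if model == "hill":
                # anchor the Hill origin at the profile's own start so the
                # fit (and hence the reference) is shift-equivariant
                ts = t - t[0]
                popt, _ = curve_fit(
                    _hill, ts, yn, p0=[1.0, max(np.median(ts), 1e-6), 2.0],
                    bounds=([0.1, 1e-9, 0.5], [10.0, np.inf, 8.0]), maxfev=20000,
                )
                refs[i] = t[0] + popt[1]
            elif model == "generic-sigmoid":
                popt, _ = curve_fit(
                    _logistic, t, yn,
                    p0=[1.0, float(np.median(t)), max((t[-1] - t[0]) / 10, 1e-6)],
                    maxfev=20000,
                )
                refs[i] = popt[1]
            else:
                raise ValueError(f"unknown model {model!r}")
        except RuntimeError:
            continue
        normed.append((t - refs[i], yn))
    if len(normed) < 2:
        raise ValueError("fewer than 2 profiles survived alignment")
    lo = max(t.min() for t, _ in normed)
    hi = min(t.max() for t, _ in normed)
    if grid_step is None:
        grid_step = float(np.median([np.median(np.diff(t)) for t, _ in normed]))
    grid = np.arange(lo, hi + grid_step / 2, grid_step)
    stack = np.vstack([np.interp(grid, t, y) for t, y in normed])
    mean = stack.mean(axis=0)
    sem = stack.std(axis=0, ddof=1) / math.sqrt(len(stack))
    return AlignedProfiles(grid=grid, mean=mean, sem=sem, references=refs,
                           auc=aucs, n_used=len(normed))
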
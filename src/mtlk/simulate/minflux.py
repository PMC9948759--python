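"""Synthetic MINFLUX localization tables for line-like filaments.

Fluorophores are placed along a filament polyline either on the axis
(luminal labeling), on a cylinder surface of the lattice radius projected to
the imaging plane, or on an enlarged "outside" cylinder.  Each fluorophore
emits a consecutive run of localizations sharing a trace id, with i.i.d.
Gaussian localization error per axis, and carries a detector-channel-ratio
(dcr) component drawn from a two-Gaussian mixture.  Uniform background
localizations can be added.  Ground-truth columns travel with the table.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

LOC_COLUMNS = ["tid", "t_s", "x_nm", "y_nm", "z_nm", "dcr"]


@dataclass
class FilamentSpec:
    """Geometry and acquisition parameters of one simulated filament field."""

    polyline: np.ndarray = field(
        default_factory=lambda: np.array([[0.0, 0.0], [1000.0, 0.0]])
    )  # (N, 2) control points, nm
    labeling_mode: str = "axial"  # axial | surface | outside
    surface_radius: float = 12.5  # nm; microtubule lattice radius
    outside_offset: float = 5.0   # nm added to the radius in "outside" mode
    sigma_xy: float = 3.5         # nm localization SD per lateral axis
    sigma_z: float = 0.0          # nm; 0 -> 2D acquisition (z column = 0)
    n_localizations: int = 2000   # signal localizations (exact)
    background_density: float = 0.0  # localizations per µm²
    background_margin: float = 50.0  # nm padding of the field around the filament
    dcr_components: tuple = (0.30, 0.05, 0.5, 0.80, 0.05, 0.5)  # µ1,σ1,w1,µ2,σ2,w2
    trace_group_size: float = 8.0  # mean localizations per fluorophore
    loc_interval: float = 0.001    # s between successive localizations
    rng_seed: int = 0

    def validate(self) -> None:
        poly = np.asarray(self.polyline, dtype=float)
        if poly.ndim != 2 or poly.shape[0] < 2 or poly.shape[1] != 2:
            raise ValueError("polyline must be an (N>=2, 2) array in nm")
        if self.labeling_mode not in ("axial", "surface", "outside"):
            raise ValueError(f"unknown labeling_mode {self.labeling_mode!r}")
        if self.surface_radius <= 0:
            raise ValueError("surface_radius must be > 0")
        m1, s1, w1, m2, s2, w2 = self.dcr_components
        if not (0 <= m1 < m2 <= 1):
            raise ValueError("dcr means must satisfy 0 <= µ1 < µ2 <= 1")
        if abs(w1 + w2 - 1.0) > 1e-9:
            raise ValueError("dcr component weights must sum to 1")
        if self.n_localizations < 1:
            raise ValueError("n_localizations must be >= 1")
        if self.trace_group_size < 1:
            raise ValueError("trace_group_size must be >= 1")


def _polyline_frames(poly: np.ndarray):
    """Arc-length table plus unit tangents/normals per segment."""
    seg = np.diff(poly, axis=0)
    seg_len = np.linalg.norm(seg, axis=1)
    if np.any(seg_len <= 0):
        raise ValueError("degenerate polyline segment")
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    tangents = seg / seg_len[:, None]
    normals = np.stack([-tangents[:, 1], tangents[:, 0]], axis=1)
    return cum, tangents, normals


def simulate_minflux(spec: FilamentSpec) -> pd.DataFrame:
    """Generate a localization table for one filament.

    Output columns are ``tid, t_s, x_nm, y_nm, z_nm, dcr`` plus ground truth
    ``fluor_id`` (-1 for background), ``is_background``, ``u_true`` (signed
    perpendicular offset of the fluorophore from the axis, nm) and ``s_true``
    (arc-length coordinate, nm).  Row count is exactly ``n_localizations``
    plus the Poisson background count.
    """
    spec.validate()
    rng = np.random.default_rng(spec.rng_seed)
    poly = np.asarray(spec.polyline, dtype=float)
    cum, tangents, normals = _polyline_frames(poly)
    total_len = cum[-1]

    # fluorophore group sizes: 1 + Poisson(mean - 1), truncated to the exact total
    sizes = []
    remaining = spec.n_localizations
    while remaining > 0:
        k = 1 + int(rng.poisson(spec.trace_group_size - 1.0))
        k = min(k, remaining)
        sizes.append(k)
        remaining -= k
    n_fluor = len(sizes)

    s = rng.uniform(0.0, total_len, size=n_fluor)
    seg_idx = np.clip(np.searchsorted(cum, s, side="right") - 1, 0, len(tangents) - 1)
    base = poly[seg_idx] + (s - cum[seg_idx])[:, None] * tangents[seg_idx]

    if spec.labeling_mode == "axial":
        u = np.zeros(n_fluor)
        z_true = np.zeros(n_fluor)
    else:
        r = spec.surface_radius
        if spec.labeling_mode == "outside":
            r = r + spec.outside_offset
        theta = rng.uniform(0.0, 2 * np.pi, size=n_fluor)
        u = r * np.cos(theta)          # in-plane offset: projected ring
        z_true = r * np.sin(theta)
    ground = base + u[:, None] * normals[seg_idx]

    m1, s1, w1, m2, s2, w2 = spec.dcr_components
    comp = rng.random(n_fluor) >= w1  # False -> component 1
    dcr_mu = np.where(comp, m2, m1)
    dcr_sd = np.where(comp, s2, s1)

    reps = np.asarray(sizes)
    fluor_id = np.repeat(np.arange(n_fluor), reps)
    xy = ground[fluor_id] + rng.normal(0.0, spec.sigma_xy, size=(spec.n_localizations, 2))
    if spec.sigma_z > 0:
        z = z_true[fluor_id] + rng.normal(0.0, spec.sigma_z, size=spec.n_localizations)
    else:
        z = np.zeros(spec.n_localizations)
    dcr = np.clip(rng.normal(dcr_mu[fluor_id], dcr_sd[fluor_id]), 0.0, 1.0)

    df = pd.DataFrame({
        "tid": fluor_id,
        "t_s": np.arange(spec.n_localizations) * spec.loc_interval,
        "x_nm": xy[:, 0],
        "y_nm": xy[:, 1],
        "z_nm": z,
        "dcr": dcr,
        "fluor_id": fluor_id,
        "is_background": False,
        "u_true": u[fluor_id],
        "s_true": s[fluor_id],
    })

    if spec.background_density > 0:
        lo = poly.min(axis=0) - spec.background_margin
        hi = poly.max(axis=0) + spec.background_margin
        area_um2 = np.prod((hi - lo) / 1000.0)
        n_bg = int(rng.poisson(spec.background_density * area_um2))
        if n_bg > 0:
            bg_xy = rng.uniform(lo, hi, size=(n_bg, 2))
            bg_comp = rng.random(n_bg) >= w1
            bg_dcr = np.clip(
                rng.normal(np.where(bg_comp, m2, m1), np.where(bg_comp, s2, s1)), 0, 1
            )
            bg = pd.DataFrame({
                "tid": n_fluor + np.arange(n_bg),
                "t_s": (spec.n_localizations + np.arange(n_bg)) * spec.loc_interval,
                "x_nm": bg_xy[:, 0],
                "y_nm": bg_xy[:, 1],
                "z_nm": 0.0,
                "dcr": bg_dcr,
                "fluor_id": -1,
                "is_background": True,
                "u_true": np.nan,
                "s_true": np.nan,
            })
            df = pd.concat([df, bg], ignore_index=True)
    return df


def perpendicular_offsets(df: pd.DataFrame, polyline: np.ndarray) -> np.ndarray:
    """Signed perpendicular distance of each localization to a polyline (nm).

    Ground-truth helper used in tests: distance to the nearest point of the
    (densely interpolated) polyline, signed by the local normal.
    """
    poly = np.asarray(polyline, dtype=float)
    cum, tangents, normals = _polyline_frames(poly)
    pts = df[["x_nm", "y_nm"]].to_numpy()
    best = np.full(len(pts), np.inf)
    signed = np.zeros(len(pts))
    for i in range(len(poly) - 1):
        a, t_hat, n_hat = poly[i], tangents[i], normals[i]
        rel = pts - a
        proj = np.clip(rel @ t_hat, 0.0, cum[i + 1] - cum[i])
        foot = a + proj[:, None] * t_hat
        d = np.linalg.norm(pts - foot, axis=1)
        upd = d < best
        best[upd] = d[upd]
        signed[upd] = (pts[upd] - foot[upd]) @ n_hat
    return signed
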
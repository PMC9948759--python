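"""Synthetic protofilament flares at microtubule ends.

Each microtubule end carries ``n_protofilaments`` traces arranged on a
cylinder of the lattice radius (axis along +z).  A trace runs straight up the
lattice to its deflection point — whose axial coordinate is drawn from
Normal(0, raggedness_sd²), the ground truth for end raggedness — and then
curls outward in the radial-axial plane as a constant-curvature arc of drawn
length and curvature.  Curvature is parameterized in degrees per 8 nm of
arc, the axial tubulin-dimer repeat.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

PF_COLUMNS = ["mt_id", "pf_id", "point_idx", "x_nm", "y_nm", "z_nm"]


@dataclass
class FlareSimSpec:
    n_protofilaments: int = 13
    lattice_radius: float = 12.5   # nm
    lattice_length: float = 100.0  # nm of straight lattice before the deflection
    flare_length_mean: float = 40.0  # nm (arc length)
    flare_length_sd: float = 10.0
    curvature_mean: float = 4.58   # degrees per 8 nm of arc
    curvature_sd: float = 1.0
    raggedness_sd: float = 12.0    # nm; SD of deflection-point axial coordinates
    point_spacing: float = 4.0     # nm between trace points
    noise_sd: float = 0.0          # nm isotropic coordinate noise
    rng_seed: int = 0

    def validate(self) -> None:
        if self.n_protofilaments < 2:
            raise ValueError("need at least 2 protofilaments")
        for name in ("flare_length_sd", "curvature_sd", "raggedness_sd", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.point_spacing <= 0 or self.lattice_radius <= 0:
            raise ValueError("point_spacing and lattice_radius must be > 0")


def simulate_flares(spec: FlareSimSpec, n_ends: int = 1) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate ``n_ends`` microtubule ends.

    Returns ``(points, truth)``: the point table with columns
    ``mt_id, pf_id, point_idx, x_nm, y_nm, z_nm`` and the ground-truth table
    with per-protofilament ``deflection_index``, ``deflection_z_nm``,
    ``flare_length_nm`` and ``curvature_deg_per_8nm``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.rng_seed)
    rows, truth_rows = [], []
    for mt in range(n_ends):
        for pf in range(spec.n_protofilaments):
            phi = 2 * np.pi * pf / spec.n_protofilaments
            e_r = np.array([np.cos(phi), np.sin(phi), 0.0])
            e_z = np.array([0.0, 0.0, 1.0])
            d_z = rng.normal(0.0, spec.raggedness_sd)
            length = max(rng.normal(spec.flare_length_mean, spec.flare_length_sd),
                         2 * spec.point_spacing)
            curv = max(rng.normal(spec.curvature_mean, spec.curvature_sd), 0.0)
            kappa = np.deg2rad(curv) / 8.0  # rad per nm of arc

            z_lat = np.arange(d_z - spec.lattice_length, d_z + spec.point_spacing / 2,
                              spec.point_spacing)
            z_lat[-1] = d_z  # deflection point is the last lattice point
            lattice = spec.lattice_radius * e_r[None, :] + z_lat[:, None] * e_z[None, :]

            s = np.arange(spec.point_spacing, length + spec.point_spacing / 2,
                          spec.point_spacing)
            if kappa > 0:
                R = 1.0 / kappa
                axial = R * np.sin(kappa * s)
                radial = R * (1.0 - np.cos(kappa * s))
            else:
                axial, radial = s, np.zeros_like(s)
            flare = (spec.lattice_radius + radial)[:, None] * e_r[None, :] \
                + (d_z + axial)[:, None] * e_z[None, :]

            pts = np.vstack([lattice, flare])
            if spec.noise_sd > 0:
                pts = pts + rng.normal(0.0, spec.noise_sd, size=pts.shape)
            for idx, p in enumerate(pts):
                rows.append((mt, pf, idx, p[0], p[1], p[2]))
            truth_rows.append((mt, pf, len(z_lat) - 1, d_z, float(s[-1]) if len(s) else 0.0,
                               curv))
    points = pd.DataFrame(rows, columns=PF_COLUMNS)
    truth = pd.DataFrame(
        truth_rows,
        columns=["mt_id", "pf_id", "deflection_index", "deflection_z_nm",
                 "flare_length_nm", "curvature_deg_per_8nm"],
    )
    return points, truth
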
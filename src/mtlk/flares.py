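"""Geometry statistics of protofilament flares and lattice annotations.

A protofilament trace is an ordered 3D polyline from the microtubule lattice
out to the protofilament tip.  The first deflection point is the first trace
point whose radial distance from the microtubule axis exceeds the lattice
radius by more than a tolerance and stays above it for the rest of the
trace.  Per-flare metrics (arc length, terminal and total curvature) are
computed from the deflection point onward; end raggedness is the sample SD
of the deflection points' axial coordinates across the protofilaments of one
end — a measure of end taper.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd


@dataclass
class AxisFrame:
    """Microtubule axis as a point + unit direction (toward the tip)."""

    origin: np.ndarray
    direction: np.ndarray

    def axial(self, points: np.ndarray) -> np.ndarray:
        return (points - self.origin) @ self.direction

    def radial(self, points: np.ndarray) -> np.ndarray:
        rel = points - self.origin
        ax = rel @ self.direction
        return np.linalg.norm(rel - ax[:, None] * self.direction[None, :], axis=1)


def fit_axis(points: np.ndarray) -> AxisFrame:
    """Principal axis of a point set, oriented toward the last point."""
    pts = np.asarray(points, dtype=float)
    center = pts.mean(axis=0)
    _, _, vt = np.linalg.svd(pts - center, full_matrices=False)
    direction = vt[0]
    if (pts[-1] - pts[0]) @ direction < 0:
        direction = -direction
    return AxisFrame(origin=center, direction=direction)


def find_deflection_point(points: np.ndarray, lattice_radius: float = 12.5,
                          tol: float = 1.5, axis: Optional[AxisFrame] = None
                          ) -> tuple[int, float]:
    """First trace index with sustained radial excess beyond the lattice.

    Returns ``(index, axial_coordinate_nm)``.  The axial coordinate is the
    interpolated position where the radial excess crosses the threshold
    (between the deflection point and its predecessor), which removes the
    trace-sampling quantization of the integer index.  If the trace never
    leaves the lattice cylinder the deflection is the last point (a blunt
    protofilament).  When no axis is supplied it is fitted as the principal
    axis of the pre-deflection (lattice) points, with one refinement pass.
    """
    pts = np.asarray(points, dtype=float)
    if len(pts) < 3:
        raise ValueError("trace needs at least 3 points")
    threshold = lattice_radius + tol

    def _locate(frame: AxisFrame) -> int:
        excess = frame.radial(pts) > threshold
        sustained = np.minimum.accumulate(excess[::-1])[::-1]
        hits = np.flatnonzero(sustained)
        return int(hits[0]) if len(hits) else len(pts) - 1

    if axis is None:
        frame = fit_axis(pts)
        idx = _locate(frame)
        frame = fit_axis(pts[: max(idx, 3)])
        idx = _locate(frame)
    else:
        frame = axis
        idx = _locate(frame)

    radial = frame.radial(pts)
    axial = frame.axial(pts)
    coord = float(axial[idx])
    if 0 < idx and radial[idx] > threshold > radial[idx - 1]:
        f = (threshold - radial[idx - 1]) / (radial[idx] - radial[idx - 1])
        coord = float(axial[idx - 1] + f * (axial[idx] - axial[idx - 1]))
    return idx, coord


@dataclass
class FlareMetrics:
    deflection_index: int
    deflection_axial_nm: float
    flare_length_nm: float          # 3D arc length, deflection point to tip
    terminal_curvature_deg_8nm: float  # mean turning per 8 nm over the last window
    total_curvature_deg: float      # sum of turning angles over the flare


def _turning_angles(pts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Turning angle (deg) at each interior vertex + chord arc lengths."""
    seg = np.diff(pts, axis=0)
    seg_len = np.linalg.norm(seg, axis=1)
    keep = seg_len > 0
    seg, seg_len = seg[keep], seg_len[keep]
    if len(seg) < 2:
        return np.array([]), seg_len
    unit = seg / seg_len[:, None]
    cosang = np.clip((unit[:-1] * unit[1:]).sum(axis=1), -1.0, 1.0)
    return np.degrees(np.arccos(cosang)), seg_len


def flare_metrics(points: np.ndarray, deflection_index: int,
                  terminal_window_nm: float = 24.0) -> FlareMetrics:
    """Length and curvature of the flare distal to the deflection point.

    Total curvature is the sum of polyline turning angles (degrees);
    terminal curvature is the turning accumulated over the final
    ``terminal_window_nm`` of arc, expressed per 8 nm of arc length.  Flares
    with fewer than 3 points report NaN curvatures but still a length.
    """
    pts = np.asarray(points, dtype=float)
    flare = pts[deflection_index:]
    seg_len = np.linalg.norm(np.diff(flare, axis=0), axis=1)
    length = float(seg_len.sum())
    angles, seg_len = _turning_angles(flare)
    if len(flare) < 3 or len(angles) == 0:
        return FlareMetrics(deflection_index, float("nan"), length,
                            math.nan, math.nan)
    total = float(angles.sum())
    # arc position of each interior vertex, measured backward from the tip
    arc_from_tip = np.cumsum(seg_len[::-1])[::-1][1:]  # vertex i sits after seg i
    in_window = arc_from_tip <= terminal_window_nm
    if in_window.any():
        window_turn = float(angles[in_window].sum())
        window_arc = float(min(terminal_window_nm, seg_len.sum()))
        terminal = window_turn / window_arc * 8.0
    else:
        terminal = math.nan
    return FlareMetrics(deflection_index, float("nan"), length, terminal, total)


@dataclass
class EndSummary:
    raggedness_nm: float    # sample SD (ddof=1) of deflection axial coordinates
    n_protofilaments: int
    per_flare: pd.DataFrame

    @property
    def defined(self) -> bool:
        return math.isfinite(self.raggedness_nm)


def end_raggedness(traces: Iterable[np.ndarray], lattice_radius: float = 12.5,
                   tol: float = 1.5, axis: Optional[AxisFrame] = None,
                   terminal_window_nm: float = 24.0) -> EndSummary:
    """Raggedness and per-flare metrics for one microtubule end.

    Raggedness is the sample standard deviation, along the microtubule axis,
    of the protofilaments' first deflection points; it is undefined (NaN,
    ``defined=False``) for fewer than two protofilaments.

    All protofilaments of an end share one axis frame: the supplied one, or
    the principal axis of the pooled trace points (per-trace frames would
    re-center each protofilament and cancel the axial spread that raggedness
    measures).
    """
    traces = [np.asarray(t, dtype=float) for t in traces]
    if axis is None and traces:
        def _oriented(points_list: list[np.ndarray]) -> AxisFrame:
            frame = fit_axis(np.vstack(points_list))
            tipward = np.mean([t[-1] - t[0] for t in traces], axis=0)
            if tipward @ frame.direction < 0:
                frame = AxisFrame(frame.origin, -frame.direction)
            return frame

        # First pass on all points; then refine the direction as the average
        # of per-protofilament lattice-line directions.  Lattice stubs run
        # parallel to the axis, so their directions are immune to the
        # end-raggedness coupling that tilts a pooled PCA fit (a tilt of a
        # fraction of a degree is amplified several-fold by the shallow
        # radial-excess slope at the deflection point).
        axis = _oriented(traces)
        dirs, lattice_pts = [], []
        for pts in traces:
            idx, _ = find_deflection_point(pts, lattice_radius, tol, axis)
            stub = pts[: max(idx + 1, 3)]
            lattice_pts.append(stub)
            d = fit_axis(stub).direction
            dirs.append(d if d @ axis.direction >= 0 else -d)
        mean_dir = np.mean(dirs, axis=0)
        mean_dir /= np.linalg.norm(mean_dir)
        # equal weight per protofilament keeps the origin on the cylinder
        # axis even when the traced stubs have unequal lengths
        origin = np.mean([stub.mean(axis=0) for stub in lattice_pts], axis=0)
        axis = AxisFrame(origin, mean_dir)
    rows = []
    for pf_id, pts in enumerate(traces):
        idx, axial = find_deflection_point(pts, lattice_radius, tol, axis)
        m = flare_metrics(pts, idx, terminal_window_nm)
        rows.append((pf_id, idx, axial, m.flare_length_nm,
                     m.terminal_curvature_deg_8nm, m.total_curvature_deg))
    per_flare = pd.DataFrame(
        rows, columns=["pf_id", "deflection_index", "deflection_axial_nm",
                       "flare_length_nm", "terminal_curvature_deg_8nm",
                       "total_curvature_deg"],
    )
    if len(per_flare) >= 2:
        ragged = float(np.std(per_flare.deflection_axial_nm, ddof=1))
    else:
        ragged = math.nan
    return EndSummary(raggedness_nm=ragged, n_protofilaments=len(per_flare),
                      per_flare=per_flare)


def traces_from_frame(points: pd.DataFrame, mt_id: int) -> list[np.ndarray]:
    """Per-protofilament coordinate arrays for one MT from a point table."""
    sub = points[points.mt_id == mt_id]
    return [
        grp.sort_values("point_idx")[["x_nm", "y_nm", "z_nm"]].to_numpy()
        for _, grp in sub.groupby("pf_id")
    ]


def lattice_summaries(annotations: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Defect density and intraluminal-particle fraction per tomogram.

    ``annotations`` needs columns ``tomogram_id, mt_id, length_um, n_defects,
    has_ilp``.  Per tomogram: defects/µm = Σ defects ÷ Σ length and
    %ILP = 100 × (#MTs with luminal density) ÷ (#MTs); pooled output is the
    mean ± sample SD (ddof=1) across tomograms.
    """
    if annotations.empty:
        raise ValueError("empty annotation table")
    if (annotations.length_um <= 0).any():
        raise ValueError("MT lengths must be > 0")
    per = annotations.groupby("tomogram_id").apply(
        lambda g: pd.Series({
            "defects_per_um": g.n_defects.sum() / g.length_um.sum(),
            "pct_ilp": 100.0 * g.has_ilp.sum() / len(g),
            "n_mts": len(g),
        }),
        include_groups=False,
    ).reset_index()

    def _stats(v):
        return {
            "mean": float(np.mean(v)),
            "sd": float(np.std(v, ddof=1)) if len(v) > 1 else math.nan,
        }

    pooled = {
        "defects_per_um": _stats(per.defects_per_um),
        "pct_ilp": _stats(per.pct_ilp),
        "n_tomograms": len(per),
    }
    return per, pooled
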
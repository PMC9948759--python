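"""MINFLUX localization analysis: dcr unmixing, rendering, filament width.

The workflow mirrors image-based filament-width measurement on localization
data: localizations are rendered as a count density map on a regular voxel
grid; filament centerlines are extracted by ridge enhancement, thresholding
and morphological skeletonization; the map intensity near each centerline is
binned by signed perpendicular distance and summed along the filament; the
full width at half maximum (FWHM) of this profile estimates the signal
width.  Two-channel acquisitions are separated beforehand by fitting a
two-component Gaussian mixture to the detector-channel-ratio (dcr) values
and keeping only localizations inside [0, µ1 + 0.5σ1] (channel 1) or
[µ2 − 0.5σ2, 1] (channel 2).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage.filters import sato
from skimage.morphology import skeletonize


# --------------------------------------------------------------------------
# dcr mixture unmixing

@dataclass
class DcrMixtureFit:
    """Two-component 1D Gaussian mixture, components ordered by mean."""

    mu1: float
    sigma1: float
    w1: float
    mu2: float
    sigma2: float
    w2: float
    log_likelihood: float
    n_iterations: int
    converged: bool

    @property
    def cutoff1(self) -> float:
        """Upper dcr bound of channel 1: µ1 + 0.5 σ1."""
        return self.mu1 + 0.5 * self.sigma1

    @property
    def cutoff2(self) -> float:
        """Lower dcr bound of channel 2: µ2 − 0.5 σ2."""
        return self.mu2 - 0.5 * self.sigma2


def _normal_pdf(x: np.ndarray, mu: float, sd: float) -> np.ndarray:
    return np.exp(-0.5 * ((x - mu) / sd) ** 2) / (sd * math.sqrt(2 * math.pi))


def fit_dcr_mixture(dcr: Sequence[float], max_iter: int = 500,
                    tol: float = 1e-8) -> DcrMixtureFit:
    """Fit a two-Gaussian mixture to dcr values by expectation-maximization.

    Initialization is deterministic (no random restarts): the sample is split
    at its median, component means/SDs start from the two halves, weights at
    0.5.  Convergence when the log-likelihood change falls below ``tol``.
    """
    x = np.asarray(dcr, dtype=float)
    if len(x) < 50:
        raise ValueError("need at least 50 dcr values")
    if np.ptp(x) == 0:
        raise ValueError("degenerate dcr sample (all values identical)")
    med = np.median(x)
    lo, hi = x[x <= med], x[x > med]
    if len(hi) == 0:  # heavy ties at the median
        lo, hi = x[x < med], x[x >= med]
    mu = np.array([lo.mean(), hi.mean()])
    sd = np.array([max(lo.std(), 1e-3), max(hi.std(), 1e-3)])
    w = np.array([0.5, 0.5])

    ll_prev = -np.inf
    converged = False
    for it in range(1, max_iter + 1):
        pdf = np.stack([w[k] * _normal_pdf(x, mu[k], sd[k]) for k in (0, 1)])
        norm = pdf.sum(axis=0)
        norm = np.where(norm <= 0, np.finfo(float).tiny, norm)
        resp = pdf / norm
        ll = float(np.log(norm).sum())
        nk = resp.sum(axis=1)
        mu = (resp @ x) / nk
        sd = np.sqrt(np.maximum((resp * (x - mu[:, None]) ** 2).sum(axis=1) / nk, 1e-8))
        w = nk / len(x)
        if abs(ll - ll_prev) < tol:
            converged = True
            break
        ll_prev = ll
    order = np.argsort(mu)
    mu, sd, w = mu[order], sd[order], w[order]
    return DcrMixtureFit(float(mu[0]), float(sd[0]), float(w[0]),
                         float(mu[1]), float(sd[1]), float(w[1]),
                         ll, it, converged)


def assign_channels(table: pd.DataFrame, fit: DcrMixtureFit) -> pd.DataFrame:
    """Label rows with ``channel`` 1, 2 or 0 (unassigned) from their dcr.

    Channel 1 is the closed interval [0, µ1 + 0.5σ1]; channel 2 is
    [µ2 − 0.5σ2, 1]; everything between is unassigned and excluded from
    rendering.  Raises if the two intervals overlap (unusable mixture).
    """
    if fit.cutoff1 >= fit.cutoff2:
        raise ValueError(
            f"channel intervals overlap (µ1+0.5σ1 = {fit.cutoff1:.3f} >= "
            f"µ2-0.5σ2 = {fit.cutoff2:.3f}); mixture unusable for assignment"
        )
    out = table.copy()
    dcr = out["dcr"].to_numpy()
    channel = np.zeros(len(out), dtype=int)
    channel[dcr <= fit.cutoff1] = 1
    channel[dcr >= fit.cutoff2] = 2
    out["channel"] = channel
    return out


# --------------------------------------------------------------------------
# localization precision QC

@dataclass
class PrecisionResult:
    sd_x: np.ndarray        # per-group sample SD along x, nm
    sd_y: np.ndarray
    modal_x: float          # mode of the SD histogram, nm
    modal_y: float
    bin_width: float
    n_groups: int

    @property
    def empty(self) -> bool:
        return self.n_groups == 0


def localization_precision(table: pd.DataFrame, min_group: int = 5,
                           bin_width: float = 0.25) -> PrecisionResult:
    """Per-axis localization precision from repeated fluorophore localizations.

    Groups are runs of consecutive rows sharing a trace id; only groups of
    more than four successive localizations (>= ``min_group``) qualify.  The
    modal per-axis sample SD (histogram bin center, ddof=1) is reported.
    """
    if "tid" not in table:
        raise ValueError("trace ids required")
    tid = table["tid"].to_numpy()
    breaks = np.flatnonzero(np.diff(tid) != 0) + 1
    sds_x, sds_y = [], []
    for grp in np.split(np.arange(len(tid)), breaks):
        if len(grp) >= min_group:
            sds_x.append(float(np.std(table["x_nm"].to_numpy()[grp], ddof=1)))
            sds_y.append(float(np.std(table["y_nm"].to_numpy()[grp], ddof=1)))
    sds_x, sds_y = np.asarray(sds_x), np.asarray(sds_y)

    def modal(v: np.ndarray) -> float:
        if len(v) == 0:
            return math.nan
        edges = np.arange(0.0, v.max() + 2 * bin_width, bin_width)
        hist, _ = np.histogram(v, bins=edges)
        i = int(np.argmax(hist))
        return float(0.5 * (edges[i] + edges[i + 1]))

    return PrecisionResult(sds_x, sds_y, modal(sds_x), modal(sds_y),
                           bin_width, len(sds_x))


# --------------------------------------------------------------------------
# density rendering

@dataclass
class DensityMap:
    """Localization count histogram on a regular grid.

    ``counts`` is indexed [iy, ix] (image convention) for 2D and
    [iz, iy, ix] for 3D; ``origin`` is the low corner in nm; voxel index of a
    coordinate is floor((coord − origin) / voxel_size).
    """

    counts: np.ndarray
    origin: np.ndarray
    voxel_size: float

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    def index_of(self, *coords: float) -> tuple[int, ...]:
        return tuple(int(np.floor((c - o) / self.voxel_size))
                     for c, o in zip(coords, self.origin))

    def voxel_centers(self) -> tuple[np.ndarray, ...]:
        """Per-axis center coordinates (x, y[, z]) in nm."""
        shape = self.counts.shape[::-1]  # (nx, ny[, nz])
        return tuple(self.origin[i] + (np.arange(shape[i]) + 0.5) * self.voxel_size
                     for i in range(len(shape)))


def render_density(table: pd.DataFrame, voxel_size: float = 1.0, dims: int = 2,
                   channel: Optional[int] = None,
                   origin: Optional[Sequence[float]] = None,
                   pad: float = 5.0) -> DensityMap:
    """Histogram localizations onto a regular 2D or 3D grid.

    ``channel`` selects rows by an existing ``channel`` column.  The origin
    defaults to the per-axis minimum minus ``pad`` voxels, snapped to the
    voxel grid.  Total counts equal the number of rendered localizations.
    """
    if voxel_size <= 0:
        raise ValueError("voxel_size must be > 0")
    df = table
    if channel is not None:
        if "channel" not in df:
            raise ValueError("no channel column; run assign_channels first")
        df = df[df.channel == channel]
    if len(df) == 0:
        raise ValueError("empty localization selection")
    cols = ["x_nm", "y_nm"] + (["z_nm"] if dims == 3 else [])
    coords = df[cols].to_numpy()
    if origin is None:
        origin = np.floor(coords.min(axis=0) / voxel_size - pad) * voxel_size
    origin = np.asarray(origin, dtype=float)
    idx = np.floor((coords - origin) / voxel_size).astype(int)
    shape = idx.max(axis=0) + 1 + int(pad)
    counts = np.zeros(shape[::-1], dtype=np.float32)  # [iy,ix] or [iz,iy,ix]
    np.add.at(counts, tuple(idx[:, ::-1].T), 1.0)
    return DensityMap(counts=counts, origin=origin, voxel_size=voxel_size)


def project_cross_section(dmap: DensityMap, axis_window_nm: float = 800.0,
                          center_nm: Optional[float] = None) -> np.ndarray:
    """Maximum-intensity projection of a 3D map's cross-section over an
    along-axis (x) window of ``axis_window_nm`` (for end-on views)."""
    if dmap.counts.ndim != 3:
        raise ValueError("cross-section projection needs a 3D map")
    nx = dmap.counts.shape[2]
    if center_nm is None:
        i0 = max(0, nx // 2 - int(axis_window_nm / dmap.voxel_size / 2))
    else:
        i0 = max(0, int((center_nm - dmap.origin[0]) / dmap.voxel_size
                        - axis_window_nm / dmap.voxel_size / 2))
    i1 = min(nx, i0 + int(axis_window_nm / dmap.voxel_size))
    return dmap.counts[:, :, i0:i1].max(axis=2)


# --------------------------------------------------------------------------
# centerline extraction

def _skeleton_paths(mask: np.ndarray) -> list[np.ndarray]:
    """Longest path (in pixels, [row, col]) through each skeleton component."""
    skel = skeletonize(mask)
    labeled, n = ndimage.label(skel, structure=np.ones((3, 3)))
    paths = []
    for lab in range(1, n + 1):
        pix = np.argwhere(labeled == lab)
        if len(pix) < 2:
            continue
        index = {tuple(p): i for i, p in enumerate(pix)}
        g = nx.Graph()
        g.add_nodes_from(range(len(pix)))
        for i, (r, c) in enumerate(pix):
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    if dr == dc == 0:
                        continue
                    j = index.get((r + dr, c + dc))
                    if j is not None and j > i:
                        g.add_edge(i, j, weight=math.hypot(dr, dc))
        # tree-diameter heuristic: farthest node from an arbitrary node, then
        # the farthest node from that one; the connecting path is the spine
        a = max(nx.single_source_dijkstra_path_length(g, 0).items(),
                key=lambda kv: kv[1])[0]
        lengths, spines = nx.single_source_dijkstra(g, a)
        b = max(lengths.items(), key=lambda kv: kv[1])[0]
        paths.append(pix[spines[b]])
    return paths


def _smooth_polyline(poly: np.ndarray, window: int) -> np.ndarray:
    if window <= 1 or len(poly) <= window:
        return poly
    kernel = np.ones(window) / window
    out = np.column_stack([
        np.convolve(np.pad(poly[:, k], window // 2, mode="edge"), kernel, "valid")
        for k in range(poly.shape[1])
    ])
    return out[: len(poly)]


def polyline_length(poly: np.ndarray) -> float:
    return float(np.linalg.norm(np.diff(poly, axis=0), axis=1).sum())


def _regularize_polyline(poly: np.ndarray, degree: int = 3) -> np.ndarray:
    """Replace a jagged skeleton path by a low-order polynomial centerline.

    The path is rotated into its principal frame and the lateral coordinate
    is fitted as a polynomial of the axial one.  This suppresses the local
    wander of the skeleton toward density fluctuations (individual
    fluorophore clusters) while following gentle filament curvature.  Falls
    back to the input for paths too short or too curved to order along the
    principal axis.
    """
    if len(poly) <= degree + 2:
        return poly
    center = poly.mean(axis=0)
    _, _, vt = np.linalg.svd(poly - center, full_matrices=False)
    axis, lateral = vt[0], vt[1]
    s = (poly - center) @ axis
    order = np.argsort(s)
    s_sorted = s[order]
    # folded paths (non-monotone axial coordinate) cannot be regularized this way
    if np.ptp(s_sorted) < 1e-9 or len(np.unique(np.round(s_sorted, 6))) < degree + 2:
        return poly
    t = (poly - center) @ lateral
    coeffs = np.polyfit(s_sorted, t[order], degree)
    t_fit = np.polyval(coeffs, s_sorted)
    return center + s_sorted[:, None] * axis + t_fit[:, None] * lateral


def extract_centerlines(dmap: DensityMap, min_length: float = 200.0,
                        ridge_scale_nm: float = 15.0,
                        threshold_frac: float = 0.08,
                        threshold_quantile: Optional[float] = None,
                        smooth_window: int = 11,
                        end_trim_nm: float = 10.0,
                        regularize_degree: Optional[int] = 3) -> list[np.ndarray]:
    """Extract filament centerlines from a 2D density map, in nm coordinates.

    The map is blurred, ridge-enhanced with a curvilinear (tubeness) filter
    at the expected filament width, thresholded, skeletonized, and each
    skeleton's spine is pruned to its longest path, converted to nm,
    smoothed and end-trimmed.  The default threshold is a fraction of the
    maximum ridge response (robust to how tightly the map is cropped);
    passing ``threshold_quantile`` switches to a quantile of the filtered
    image instead.  Only polylines longer than ``min_length`` are returned;
    an empty list is valid.
    """
    if dmap.counts.ndim != 2:
        raise ValueError("centerline extraction operates on 2D maps")
    scale_vox = max(ridge_scale_nm / dmap.voxel_size, 2.0)
    img = ndimage.gaussian_filter(dmap.counts.astype(float), sigma=scale_vox / 3.0)
    if img.max() <= 0:
        return []
    ridge = sato(img, sigmas=[scale_vox / 2.0], black_ridges=False)
    if threshold_quantile is not None:
        thr = np.quantile(ridge, threshold_quantile)
    else:
        thr = threshold_frac * ridge.max()
    mask = ridge > thr
    if not mask.any():
        return []
    out = []
    trim = int(round(end_trim_nm / dmap.voxel_size))
    for path in _skeleton_paths(mask):
        if trim > 0 and len(path) > 2 * trim + 4:
            path = path[trim:-trim]
        # [row, col] -> (x, y) nm at voxel centers
        poly = np.column_stack([
            dmap.origin[0] + (path[:, 1] + 0.5) * dmap.voxel_size,
            dmap.origin[1] + (path[:, 0] + 0.5) * dmap.voxel_size,
        ])
        poly = _smooth_polyline(poly, smooth_window)
        if regularize_degree is not None:
            poly = _regularize_polyline(poly, regularize_degree)
        if polyline_length(poly) >= min_length:
            out.append(poly)
    return out


# --------------------------------------------------------------------------
# perpendicular profile and FWHM

@dataclass
class WidthProfile:
    """Summed perpendicular intensity profile of one filament."""

    distances: np.ndarray    # signed bin centers, nm
    intensity: np.ndarray
    fwhm: float              # nm; NaN when flagged undefined
    peak_position: float     # nm
    filament_length: float   # nm
    n_localizations: float   # total intensity contributing to the profile
    filament_id: int = 0

    @property
    def fwhm_defined(self) -> bool:
        return math.isfinite(self.fwhm)


def profile_fwhm(x: np.ndarray, y: np.ndarray,
                 crossing: str = "nearest") -> tuple[float, float]:
    """FWHM and peak position of a sampled profile.

    Half-maximum crossings are located by linear interpolation between
    samples.  ``crossing="nearest"`` uses the crossings nearest the profile
    peak; ``crossing="envelope"`` uses the outermost crossings (the edges of
    the region that ever reaches half maximum), which bridges brief sampling
    dips below half maximum in multi-peaked profiles.  Returns (NaN, peak)
    when a side never falls below half maximum.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    i_pk = int(np.argmax(y))
    half = y[i_pk] / 2.0
    left = right = math.nan
    if crossing == "nearest":
        i_lo, i_hi = i_pk, i_pk
    elif crossing == "envelope":
        above = np.flatnonzero(y >= half)
        i_lo, i_hi = int(above[0]), int(above[-1])
    else:
        raise ValueError(f"unknown crossing rule {crossing!r}")
    for i in range(i_lo, 0, -1):
        if y[i - 1] < half <= y[i]:
            f = (half - y[i - 1]) / (y[i] - y[i - 1])
            left = x[i - 1] + f * (x[i] - x[i - 1])
            break
    for i in range(i_hi, len(y) - 1):
        if y[i + 1] < half <= y[i]:
            f = (y[i] - half) / (y[i] - y[i + 1])
            right = x[i] + f * (x[i + 1] - x[i])
            break
    width = right - left if math.isfinite(left) and math.isfinite(right) else math.nan
    return width, float(x[i_pk])


def _adaptive_profile_fwhm(x: np.ndarray, y: np.ndarray,
                           crossing: str = "envelope", cross_window: int = 5,
                           level_frac: float = 0.75,
                           max_level_window: int = 21) -> tuple[float, float]:
    """FWHM of a noisy binned profile with adaptive peak-level estimation.

    The crossings are read from a lightly Savitzky-Golay-smoothed profile;
    the half-maximum *level* comes from a second SG pass whose window scales
    with a first-pass width estimate (``level_frac`` × width), so the peak
    height is averaged over a region matched to the feature size.  This
    suppresses the upward bias of taking the maximum of a noisy profile
    (which otherwise systematically shrinks the FWHM) without flattening
    narrow peaks.
    """
    from scipy.signal import savgol_filter

    y = np.asarray(y, dtype=float)
    if y.max() <= 0 or len(y) < cross_window:
        return math.nan, math.nan
    yc = savgol_filter(y, cross_window, 2)
    w0, peak_pos = profile_fwhm(x, yc, crossing=crossing)
    if not math.isfinite(w0):
        return math.nan, peak_pos
    bin_w = float(x[1] - x[0])
    lw = int(round(np.clip(level_frac * w0 / bin_w, cross_window, max_level_window)))
    lw = min(lw + (1 - lw % 2), len(y) - (1 - len(y) % 2))  # odd, within bounds
    yl = savgol_filter(y, lw, 2)
    half = yl.max() / 2.0
    width = _crossing_width(x, yc, half, crossing)
    return width, peak_pos


def _crossing_width(x: np.ndarray, y: np.ndarray, half: float,
                    crossing: str) -> float:
    """Width between interpolated crossings of ``y`` at level ``half``."""
    i_pk = int(np.argmax(y))
    if crossing == "nearest":
        i_lo, i_hi = i_pk, i_pk
    else:
        above = np.flatnonzero(y >= half)
        if len(above) == 0:
            return math.nan
        i_lo, i_hi = int(above[0]), int(above[-1])
    left = right = math.nan
    for i in range(i_lo, 0, -1):
        if y[i - 1] < half <= y[i]:
            f = (half - y[i - 1]) / (y[i] - y[i - 1])
            left = x[i - 1] + f * (x[i] - x[i - 1])
            break
    for i in range(i_hi, len(y) - 1):
        if y[i + 1] < half <= y[i]:
            f = (y[i] - half) / (y[i] - y[i + 1])
            right = x[i] + f * (x[i + 1] - x[i])
            break
    return right - left if math.isfinite(left) and math.isfinite(right) else math.nan


def _signed_distances(points: np.ndarray, centerline: np.ndarray,
                      step: float) -> tuple[np.ndarray, np.ndarray]:
    """Signed perpendicular distance to the centerline + inside-span mask."""
    seg = np.diff(centerline, axis=0)
    seg_len = np.linalg.norm(seg, axis=1)
    keep = seg_len > 0
    seg, seg_len = seg[keep], seg_len[keep]
    starts = centerline[:-1][keep]
    # densify for nearest-point lookup
    dense_pts, dense_tan = [], []
    for a, d, L in zip(starts, seg, seg_len):
        n_sub = max(int(np.ceil(L / step)), 1)
        frac = (np.arange(n_sub) + 0.5) / n_sub
        dense_pts.append(a + frac[:, None] * d)
        dense_tan.append(np.tile(d / L, (n_sub, 1)))
    dense_pts = np.vstack(dense_pts)
    dense_tan = np.vstack(dense_tan)
    tree = cKDTree(dense_pts)
    _, nearest = tree.query(points, k=1)
    rel = points - dense_pts[nearest]
    tan = dense_tan[nearest]
    signed = rel[:, 0] * (-tan[:, 1]) + rel[:, 1] * tan[:, 0]
    # exclude points whose nearest dense sample is an endpoint: their foot
    # projects beyond the filament span (end-flare contamination guard)
    inside = (nearest > 0) & (nearest < len(dense_pts) - 1)
    return signed, inside


def filament_fwhm(source: "DensityMap | pd.DataFrame", centerline: np.ndarray,
                  max_dist: float = 50.0, bin_width: float = 1.0,
                  crossing: str = "envelope", smooth: Optional[str] = "adaptive",
                  filament_id: int = 0) -> WidthProfile:
    """Perpendicular intensity profile and FWHM of one filament.

    ``source`` is a rendered 2D density map (default workflow: every nonzero
    voxel contributes its count at its center) or a raw localization table
    (bin-free variant: each row contributes unit weight).  Intensities are
    binned by signed perpendicular distance within ``max_dist`` of the
    centerline and summed along its length.  The FWHM is measured with the
    adaptive noisy-profile estimator by default (``smooth="adaptive"``);
    ``smooth=None`` reads raw interpolated half-maximum crossings.  The
    stored profile is always the raw histogram.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    if isinstance(source, DensityMap):
        if source.counts.ndim != 2:
            raise ValueError("FWHM analysis operates on 2D maps")
        iy, ix = np.nonzero(source.counts)
        pts = np.column_stack([
            source.origin[0] + (ix + 0.5) * source.voxel_size,
            source.origin[1] + (iy + 0.5) * source.voxel_size,
        ])
        weights = source.counts[iy, ix].astype(float)
    else:
        pts = source[["x_nm", "y_nm"]].to_numpy(dtype=float)
        weights = np.ones(len(pts))
    signed, inside = _signed_distances(pts, centerline, step=bin_width / 2.0)
    sel = inside & (np.abs(signed) <= max_dist)
    edges = np.arange(-max_dist, max_dist + bin_width / 2, bin_width)
    hist, _ = np.histogram(signed[sel], bins=edges, weights=weights[sel])
    centers = 0.5 * (edges[:-1] + edges[1:])
    if smooth == "adaptive":
        fwhm, peak = _adaptive_profile_fwhm(centers, hist, crossing=crossing)
    elif smooth is None:
        fwhm, peak = profile_fwhm(centers, hist, crossing=crossing)
    else:
        raise ValueError(f"unknown smooth mode {smooth!r}")
    return WidthProfile(distances=centers, intensity=hist, fwhm=fwhm,
                        peak_position=peak, filament_length=polyline_length(centerline),
                        n_localizations=float(weights[sel].sum()),
                        filament_id=filament_id)


def measure_filaments(table: pd.DataFrame, voxel_size: float = 1.0,
                      channel: Optional[int] = None, min_length: float = 200.0,
                      max_dist: float = 50.0, bin_width: float = 1.0,
                      **centerline_kwargs) -> list[WidthProfile]:
    """Full width workflow: render, extract centerlines, profile each one."""
    dmap = render_density(table, voxel_size=voxel_size, channel=channel)
    lines = extract_centerlines(dmap, min_length=min_length, **centerline_kwargs)
    return [
        filament_fwhm(dmap, line, max_dist=max_dist, bin_width=bin_width, filament_id=i)
        for i, line in enumerate(lines)
    ]
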
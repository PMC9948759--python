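"""Synthetic spot (comet) images: filled discs on an uneven background.

Blobs are rendered as filled discs of the requested areas; the ground-truth
table records the rendered pixel area of each blob and whether it is above
the counting cutoff, so detector output can be compared against construction.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd


@dataclass
class CometImageSpec:
    image_shape: tuple = (512, 512)   # (rows, cols) px
    pixel_size: float = 0.107         # µm/px
    blob_table: Sequence = ()         # rows of (x_px, y_px, area_um2, peak)
    background: tuple = (10.0, 0.0)   # (offset a.u., gradient a.u. per px along x)
    noise_sd: float = 0.0
    rng_seed: int = 0

    def validate(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        for (x, y, area, peak) in self.blob_table:
            if area <= 0:
                raise ValueError("blob areas must be > 0")
            if not (0 <= x < self.image_shape[1] and 0 <= y < self.image_shape[0]):
                raise ValueError("blob centers must lie inside the image")


def simulate_comet_image(spec: CometImageSpec,
                         area_cutoff: float = 0.10) -> tuple[np.ndarray, pd.DataFrame]:
    """Render the blob field; returns ``(image, truth)``.

    ``truth`` has one row per requested blob with the rendered pixel area in
    µm², an ``above_cutoff`` class and an ``overlaps`` flag for blobs whose
    discs touch another disc (flagged, not dropped).
    """
    spec.validate()
    rng = np.random.default_rng(spec.rng_seed)
    h, w = spec.image_shape
    yy, xx = np.mgrid[0:h, 0:w]
    offset, slope = spec.background
    img = offset + slope * xx.astype(float)

    blob_mask = np.zeros((h, w), dtype=int)
    truth_rows = []
    radii = []
    for i, (x, y, area, peak) in enumerate(spec.blob_table):
        r_px = np.sqrt(area / np.pi) / spec.pixel_size
        disc = (xx - x) ** 2 + (yy - y) ** 2 <= r_px**2
        img = img + peak * disc
        blob_mask += disc
        area_px = int(disc.sum())
        area_um2 = area_px * spec.pixel_size**2
        truth_rows.append((i, x, y, area, area_um2, area_um2 >= area_cutoff, peak))
        radii.append(r_px)
    overlaps = []
    blobs = list(spec.blob_table)
    for i in range(len(blobs)):
        o = False
        for j in range(len(blobs)):
            if i == j:
                continue
            d = np.hypot(blobs[i][0] - blobs[j][0], blobs[i][1] - blobs[j][1])
            if d <= radii[i] + radii[j] + 1:
                o = True
        overlaps.append(o)
    truth = pd.DataFrame(
        truth_rows,
        columns=["blob_id", "x_px", "y_px", "area_um2_requested", "area_um2_rendered",
                 "above_cutoff", "peak"],
    )
    truth["overlaps"] = overlaps
    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, img.shape)
    return np.clip(img, 0.0, None).astype(np.float32), truth


def random_blob_table(n_above: int, n_below: int, image_shape=(512, 512),
                      pixel_size: float = 0.107, area_cutoff: float = 0.10,
                      peak: float = 200.0, margin: float = 12.0,
                      min_separation: float = 16.0, rng_seed: int = 0) -> list:
    """Place non-overlapping blobs, ``n_above`` well above and ``n_below``
    well below the area cutoff (0.3–0.5× below, 1.5–4× above, to keep the
    classes unambiguous after rasterization)."""
    rng = np.random.default_rng(rng_seed)
    h, w = image_shape
    placed, table = [], []
    areas = np.concatenate([
        rng.uniform(1.5 * area_cutoff, 4.0 * area_cutoff, n_above),
        rng.uniform(0.3 * area_cutoff, 0.5 * area_cutoff, n_below),
    ])
    rng.shuffle(areas)
    for area in areas:
        for _ in range(10000):
            x = rng.uniform(margin, w - margin)
            y = rng.uniform(margin, h - margin)
            if all(np.hypot(x - px, y - py) >= min_separation for px, py in placed):
                placed.append((x, y))
                table.append((x, y, float(area), peak))
                break
        else:
            raise RuntimeError("could not place all blobs; image too crowded")
    return table
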
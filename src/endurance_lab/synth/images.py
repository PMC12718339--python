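"""Synthetic triple-label immunofluorescence coverslip images.

Channels (pages): anti-TH, anti-Glycogen, anti-Glycogen-Synthase. Cells are
non-overlapping disks over a flat background. Per-cell GS abundance is
log-normal with hierarchical variation (culture x coverslip x cell) so the
population spans more than an order of magnitude; glycogen is proportional
to GS with multiplicative residual noise, scaled up in TH-positive cells by
the ground-truth TH factor (1.7, the dopaminergic enrichment), and scaled
down to 0.546 of that in the sulpiride condition (the 45.4% depletion).
"""

from __future__ import annotations

import zlib
from typing import Optional, Tuple, Union

import numpy as np
import pandas as pd

from ..errors import ValidationError
from ..params import PRESET_NAMES
from .traces import GroundTruth

__all__ = ["simulate_if_image", "IF_CHANNELS", "TH_FACTOR_DEFAULT", "SULPIRIDE_SCALE"]

IF_CHANNELS = ("th", "glycogen", "gs")
TH_FACTOR_DEFAULT = 1.7     # TH+/TH- glycogen enrichment
SULPIRIDE_SCALE = 0.546     # residual TH+ glycogen after chronic D2R block

_BACKGROUND = {"th": 20.0, "glycogen": 15.0, "gs": 18.0}
_SIGMA_LOG10_CELL = 0.25
_SIGMA_LOG10_COVERSLIP = 0.15
_SIGMA_LOG10_CULTURE = 0.10
_GLY_RESIDUAL_SD = 0.2      # log-sd of the glycogen-about-GS residual
_LN10 = np.log(10.0)


def simulate_if_image(
    condition: str,
    n_cells: int = 60,
    frame_shape: Tuple[int, int] = (256, 256),
    seed: Union[int, np.random.SeedSequence, np.random.Generator] = 0,
    coverslip_id: str = "cs00",
    culture_id: str = "cult0",
    th_positive_fraction: float = 0.35,
    th_factor: float = TH_FACTOR_DEFAULT,
    slope_base: float = 0.8,
    gs_scale: float = 100.0,
    cell_radius_px: Tuple[int, int] = (5, 8),
    pixel_noise_sd: float = 3.0,
    noise_off: bool = False,
) -> tuple[np.ndarray, pd.DataFrame, GroundTruth]:
    """Generate one coverslip: image (3, H, W), annotated ROI table, ground truth.

    The ROI table carries signal disks for every cell (with ``th_status``,
    ``coverslip_id`` and ``culture_id`` annotations) plus four background
    disks. ``noise_off`` removes all stochastic intensity terms (cell spread,
    residuals, pixel noise) so measured glycogen equals ``slope_base`` x GS
    exactly.
    """
    if condition not in PRESET_NAMES:
        raise ValidationError(f"unknown condition {condition!r}; valid: {', '.join(PRESET_NAMES)}")
    if n_cells < 2:
        raise ValidationError("n_cells must be >= 2 (need one TH+ and one TH- cell)")
    h, w = frame_shape
    rng = np.random.default_rng(seed)

    r_lo, r_hi = cell_radius_px
    radii = rng.integers(r_lo, r_hi + 1, size=n_cells).astype(float)

    # place background disks first (corners), then cells by rejection sampling
    bg_radius = float(r_lo)
    margin = bg_radius + 2
    bg_centers = [
        (margin, margin),
        (w - margin, margin),
        (margin, h - margin),
        (w - margin, h - margin),
    ]
    centers: list[tuple[float, float]] = []
    occupied = [(x, y, bg_radius) for x, y in bg_centers]
    max_attempts = 200 * n_cells
    attempts = 0
    for r in radii:
        placed = False
        while attempts < max_attempts:
            attempts += 1
            x = rng.uniform(r + 1, w - r - 1)
            y = rng.uniform(r + 1, h - r - 1)
            if all((x - ox) ** 2 + (y - oy) ** 2 > (r + orad + 2) ** 2 for ox, oy, orad in occupied):
                centers.append((x, y))
                occupied.append((x, y, r))
                placed = True
                break
        if not placed:
            raise ValidationError(
                f"frame {frame_shape} too small to place {n_cells} non-overlapping cells"
            )

    th_status = np.array(["negative"] * n_cells, dtype=object)
    th_status[rng.random(n_cells) < th_positive_fraction] = "positive"
    th_status[0], th_status[1] = "positive", "negative"  # guarantee one of each

    if noise_off:
        coverslip_f = culture_f = 1.0
        cell_f = np.ones(n_cells)
        resid = np.ones(n_cells)
    else:
        # the culture gain is a property of the culture batch, not of this
        # image: derive it from culture_id so sister coverslips share it
        # (treated samples are normalized to controls of the same batch)
        culture_rng = np.random.default_rng(zlib.crc32(culture_id.encode()))
        culture_f = 10.0 ** culture_rng.normal(0.0, _SIGMA_LOG10_CULTURE)
        coverslip_f = 10.0 ** rng.normal(0.0, _SIGMA_LOG10_COVERSLIP)
        cell_f = 10.0 ** rng.normal(0.0, _SIGMA_LOG10_CELL, size=n_cells)
        resid = np.exp(rng.normal(0.0, _GLY_RESIDUAL_SD, size=n_cells))

    gs_true = gs_scale * culture_f * coverslip_f * cell_f
    th_scale = np.where(th_status == "positive", th_factor, 1.0)
    if condition == "da_sulpiride":
        th_scale = np.where(th_status == "positive", th_factor * SULPIRIDE_SCALE, 1.0)
    gly_true = slope_base * gs_true * th_scale       # noise-free glycogen signal
    gly_cell = gly_true * resid                      # realized per-cell mean intensity

    th_cell = np.where(
        th_status == "positive",
        150.0 * (1.0 if noise_off else 10.0 ** rng.normal(0.0, 0.15, size=n_cells)),
        8.0,
    )

    image = np.empty((3, h, w), dtype=np.float32)
    yy, xx = np.mgrid[0:h, 0:w]
    for c, name in enumerate(IF_CHANNELS):
        image[c] = _BACKGROUND[name]
    cell_values = {"th": th_cell, "glycogen": gly_cell, "gs": gs_true}
    for i, ((x, y), r) in enumerate(zip(centers, radii)):
        mask = (xx + 0.5 - x) ** 2 + (yy + 0.5 - y) ** 2 <= r**2
        for c, name in enumerate(IF_CHANNELS):
            image[c][mask] = _BACKGROUND[name] + cell_values[name][i]
    if not noise_off and pixel_noise_sd > 0:
        image += rng.normal(0.0, pixel_noise_sd, size=image.shape).astype(np.float32)

    rows = []
    for i, ((x, y), r) in enumerate(zip(centers, radii)):
        rows.append(
            dict(
                roi_id=f"{coverslip_id}_cell{i:03d}",
                center_x_px=x,
                center_y_px=y,
                radius_px=r,
                kind="signal",
                th_status=th_status[i],
                compartment="soma",
                coverslip_id=coverslip_id,
                culture_id=culture_id,
            )
        )
    for j, (x, y) in enumerate(bg_centers):
        rows.append(
            dict(
                roi_id=f"{coverslip_id}_bg{j}",
                center_x_px=x,
                center_y_px=y,
                radius_px=bg_radius,
                kind="background",
                th_status="",
                compartment="",
                coverslip_id=coverslip_id,
                culture_id=culture_id,
            )
        )
    rois = pd.DataFrame(rows)

    gt = GroundTruth(
        kind="if_image",
        condition=condition,
        seed_repr=repr(seed),
        extras={
            "cell_ids": [r["roi_id"] for r in rows if r["kind"] == "signal"],
            "th_status": list(th_status),
            "gs_true": gs_true,
            "gly_true": gly_true,
            "gly_cell": gly_cell,
            "th_scale": th_scale,
            "th_factor": th_factor if condition != "da_sulpiride" else th_factor * SULPIRIDE_SCALE,
            "slope_base": slope_base,
            "background": dict(_BACKGROUND),
        },
    )
    return image, rois, gt
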
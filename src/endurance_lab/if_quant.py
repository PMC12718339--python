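"""Immunofluorescence quantification with the study's normalization schemes.

Per-cell intensities are disk means, background subtracted, then normalized
to the mean of the corresponding culture per channel (so normalized values
of a culture average to 1 and every per-culture gain cancels). On top of the
records live three analyses: the glycogen-vs-GS linear relation with 0.5-
wide binned means, the per-coverslip TH+/TH- glycogen ratio, and the
percent change of a treated group relative to untreated controls.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ValidationError
from .extraction import disk_mask

__all__ = [
    "quantify_cells",
    "culture_normalize",
    "glycogen_gs_relation",
    "th_ratio",
    "treatment_effect",
    "GlycogenGsFit",
    "ThRatioResult",
    "TreatmentEffect",
]

ANNOTATION_COLUMNS = ["roi_id", "center_x_px", "center_y_px", "radius_px", "kind"]


def quantify_cells(
    image: np.ndarray,
    rois: pd.DataFrame,
    channels: Sequence[str] = ("th", "glycogen", "gs"),
    background: str = "rois",
) -> pd.DataFrame:
    """Per-cell mean intensity per channel, background subtracted.

    ``image`` is (n_channels, H, W) with pages in ``channels`` order. The
    ROI table needs the geometry columns plus ``kind`` and, for signal ROIs,
    ``th_status``/``compartment``/``coverslip_id``/``culture_id`` annotations.
    ``background='rois'`` subtracts the per-channel mean over background
    ROIs; ``'none'`` skips subtraction.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 3:
        raise ValidationError(f"image must be (channels, H, W); got {image.shape}")
    if image.shape[0] != len(channels):
        raise ValidationError(
            f"image has {image.shape[0]} channel pages but {len(channels)} channel names were given"
        )
    missing = [c for c in ANNOTATION_COLUMNS if c not in rois.columns]
    if missing:
        raise ValidationError(f"ROI table missing columns {missing}")
    cells = rois[rois["kind"] == "signal"]
    if cells.empty:
        raise ValidationError("ROI table contains no signal (cell) ROIs")
    for col in ("th_status",):
        if col not in rois.columns:
            raise ValidationError(f"cell ROIs must be annotated with {col!r}")
    if background not in ("rois", "none"):
        raise ValidationError("background must be 'rois' or 'none'")

    def mean_in(roi_row, page) -> float:
        mask = disk_mask(image.shape, roi_row.center_x_px, roi_row.center_y_px, roi_row.radius_px)
        return float(image[page][mask].mean())

    bg = np.zeros(len(channels))
    if background == "rois":
        bgs = rois[rois["kind"] == "background"]
        if bgs.empty:
            raise ValidationError("background='rois' but the table has no background ROIs")
        for c in range(len(channels)):
            bg[c] = np.mean([mean_in(r, c) for r in bgs.itertuples()])

    records = []
    for r in cells.itertuples():
        rec = {
            "cell_id": r.roi_id,
            "coverslip_id": getattr(r, "coverslip_id", ""),
            "culture_id": getattr(r, "culture_id", ""),
            "th_status": r.th_status,
            "compartment": getattr(r, "compartment", "soma"),
        }
        for c, name in enumerate(channels):
            raw = mean_in(r, c)
            rec[f"{name}_raw"] = raw
            rec[name] = raw - bg[c]
        records.append(rec)
    return pd.DataFrame(records)


def culture_normalize(records: pd.DataFrame, channels: Sequence[str] = ("th", "glycogen", "gs")) -> pd.DataFrame:
    """Divide each channel by the mean over its culture; adds ``<ch>_norm`` columns."""
    missing = [c for c in channels if c not in records.columns]
    if missing:
        raise ValidationError(f"records missing channels {missing}")
    if "culture_id" not in records.columns:
        raise ValidationError("records need a culture_id column for culture normalization")
    out = records.copy()
    for ch in channels:
        means = out.groupby("culture_id")[ch].transform("mean")
        if (means <= 0).any():
            raise ValidationError(f"non-positive culture mean for channel {ch!r}")
        out[f"{ch}_norm"] = out[ch] / means
    return out


@dataclass
class GlycogenGsFit:
    slope: float
    intercept: float
    r_value: float
    p_value: float
    n: int
    bins: pd.DataFrame  # bin_left, bin_right, n, mean, sem, underfilled


def glycogen_gs_relation(
    records: pd.DataFrame,
    gs_col: str = "gs_norm",
    gly_col: str = "glycogen_norm",
    bin_width: float = 0.5,
) -> GlycogenGsFit:
    """OLS of normalized glycogen on normalized GS plus binned means.

    Bins are ``bin_width`` wide on the GS axis, left-closed and anchored at
    0; bins with fewer than 2 members are flagged ``underfilled``.
    """
    df = records[[gs_col, gly_col]].dropna()
    if len(df) < 10:
        raise ValidationError(f"need >= 10 records with both channels, got {len(df)}")
    gs = df[gs_col].to_numpy(dtype=float)
    gly = df[gly_col].to_numpy(dtype=float)
    if np.std(gs) == 0:
        raise ValidationError("degenerate GS spread (sd = 0); regression undefined")
    fit = sps.linregress(gs, gly)

    idx = np.floor(gs / bin_width).astype(int)
    rows = []
    for b in range(idx.min(), idx.max() + 1):
        sel = gly[idx == b]
        if sel.size == 0:
            continue
        rows.append(
            dict(
                bin_left=b * bin_width,
                bin_right=(b + 1) * bin_width,
                n=int(sel.size),
                mean=float(sel.mean()),
                sem=float(sel.std(ddof=1) / np.sqrt(sel.size)) if sel.size > 1 else np.nan,
                underfilled=sel.size < 2,
            )
        )
    return GlycogenGsFit(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_value=float(fit.rvalue),
        p_value=float(fit.pvalue),
        n=len(df),
        bins=pd.DataFrame(rows),
    )


@dataclass
class ThRatioResult:
    per_coverslip: pd.DataFrame  # coverslip_id, n_positive, n_negative, ratio
    mean: float
    sem: float
    n_coverslips: int
    excluded: List[str] = field(default_factory=list)


def th_ratio(records: pd.DataFrame, value_col: str = "glycogen") -> ThRatioResult:
    """Per-coverslip ratio of mean glycogen in TH+ vs TH- cells, then the
    mean +/- SEM across coverslips. Coverslips missing one class are
    excluded with a warning and listed in the result."""
    for col in ("coverslip_id", "th_status", value_col):
        if col not in records.columns:
            raise ValidationError(f"records missing column {col!r}")
    rows, excluded = [], []
    for cs, g in records.groupby("coverslip_id"):
        pos = g.loc[g["th_status"] == "positive", value_col]
        neg = g.loc[g["th_status"] == "negative", value_col]
        if pos.empty or neg.empty:
            excluded.append(str(cs))
            continue
        rows.append(
            dict(
                coverslip_id=cs,
                n_positive=int(len(pos)),
                n_negative=int(len(neg)),
                ratio=float(pos.mean() / neg.mean()),
            )
        )
    if excluded:
        warnings.warn(
            f"excluded {len(excluded)} coverslip(s) missing a TH class: {excluded}", stacklevel=2
        )
    if not rows:
        raise ValidationError("no coverslip has both TH-positive and TH-negative cells")
    per = pd.DataFrame(rows)
    ratios = per["ratio"].to_numpy()
    sem = float(ratios.std(ddof=1) / np.sqrt(ratios.size)) if ratios.size > 1 else float("nan")
    return ThRatioResult(
        per_coverslip=per,
        mean=float(ratios.mean()),
        sem=sem,
        n_coverslips=int(ratios.size),
        excluded=excluded,
    )


@dataclass
class TreatmentEffect:
    percent_reduction: float  # positive = decrease vs control
    sem: float
    n_treated: int
    n_control: int
    treated_over_control: float


def treatment_effect(
    treated: pd.DataFrame | pd.Series | np.ndarray,
    control: pd.DataFrame | pd.Series | np.ndarray,
    value_col: str = "glycogen",
) -> TreatmentEffect:
    """Percent change of the treated group relative to control.

    percent_reduction = 100 * (1 - mean(treated)/mean(control)); a negative
    value reports an increase. The SEM is propagated from the treated values
    after normalizing them to the control mean (the controls define the unit).
    """
    tv = _values(treated, value_col)
    cv = _values(control, value_col)
    if tv.size == 0 or cv.size == 0:
        raise ValidationError("both treated and control groups must be non-empty")
    mc = float(cv.mean())
    if mc <= 0:
        raise ValidationError(f"control mean must be > 0, got {mc:.4g}")
    normalized = tv / mc
    sem = float(100.0 * normalized.std(ddof=1) / np.sqrt(normalized.size)) if normalized.size > 1 else float("nan")
    return TreatmentEffect(
        percent_reduction=float(100.0 * (1.0 - normalized.mean())),
        sem=sem,
        n_treated=int(tv.size),
        n_control=int(cv.size),
        treated_over_control=float(normalized.mean()),
    )


def _values(x, value_col: str) -> np.ndarray:
    if isinstance(x, pd.DataFrame):
        if value_col not in x.columns:
            raise ValidationError(f"records missing column {value_col!r}")
        return x[value_col].to_numpy(dtype=float)
    return np.asarray(x, dtype=float).ravel()
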
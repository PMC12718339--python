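"""ROI trace extraction from image stacks and responder selection.

A pixel belongs to a circular ROI when its center (at integer + 0.5, with
0-based image coordinates, x = column, y = row) lies within the ROI radius
of the ROI center. Background, when requested, is the frame-wise mean over
all background ROIs, subtracted from every signal trace.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, List, Optional

import numpy as np
import pandas as pd

from .errors import EmptySelectionError, RoiError, ValidationError
from .protocols import StimulusProtocol
from .traces import RoiTraceSet

__all__ = ["Roi", "RoiSet", "disk_mask", "extract_roi_traces", "select_responding_rois", "SelectionReport"]

ROI_COLUMNS = ["roi_id", "center_x_px", "center_y_px", "radius_px", "kind"]


@dataclass(frozen=True)
class Roi:
    roi_id: str
    center_x_px: float
    center_y_px: float
    radius_px: float
    kind: str = "signal"

    def __post_init__(self):
        if self.radius_px <= 0:
            raise RoiError(f"roi {self.roi_id!r}: radius must be > 0")
        if self.kind not in ("signal", "background"):
            raise RoiError(f"roi {self.roi_id!r}: kind must be 'signal' or 'background'")


class RoiSet:
    """An ordered collection of ROIs with unique ids."""

    def __init__(self, rois: Iterable[Roi]):
        self.rois: List[Roi] = list(rois)
        ids = [r.roi_id for r in self.rois]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise RoiError(f"duplicate roi_ids: {dupes}")

    def __len__(self):
        return len(self.rois)

    def __iter__(self):
        return iter(self.rois)

    @property
    def signal(self) -> List[Roi]:
        return [r for r in self.rois if r.kind == "signal"]

    @property
    def background(self) -> List[Roi]:
        return [r for r in self.rois if r.kind == "background"]

    def check_in_frame(self, shape) -> None:
        h, w = shape[-2], shape[-1]
        for r in self.rois:
            if (
                r.center_x_px - r.radius_px < 0
                or r.center_x_px + r.radius_px > w
                or r.center_y_px - r.radius_px < 0
                or r.center_y_px + r.radius_px > h
            ):
                raise RoiError(f"roi {r.roi_id!r} is not fully inside the {h}x{w} frame")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "RoiSet":
        missing = [c for c in ROI_COLUMNS if c not in df.columns and c != "kind"]
        if missing:
            raise RoiError(f"ROI table missing columns {missing}")
        kinds = df["kind"] if "kind" in df.columns else ["signal"] * len(df)
        return cls(
            Roi(str(row.roi_id), float(row.center_x_px), float(row.center_y_px), float(row.radius_px), str(k))
            for row, k in zip(df.itertuples(), kinds)
        )

    @classmethod
    def from_csv(cls, path) -> "RoiSet":
        return cls.from_frame(pd.read_csv(path))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(r) for r in self.rois])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def disk_mask(shape, center_x: float, center_y: float, radius: float) -> np.ndarray:
    """Boolean mask of pixels whose centers lie within ``radius`` of the center."""
    h, w = shape[-2], shape[-1]
    yy, xx = np.mgrid[0:h, 0:w]
    return (xx + 0.5 - center_x) ** 2 + (yy + 0.5 - center_y) ** 2 <= radius**2


def extract_roi_traces(
    stack: np.ndarray,
    rois: RoiSet,
    frame_interval: float = 0.5,
    time: Optional[np.ndarray] = None,
    channel: str = "F",
    background_policy: str = "mean",
) -> RoiTraceSet:
    """Mean-in-disk traces for every signal ROI, frame-wise background subtracted.

    ``background_policy``: "mean" subtracts the per-frame mean over all
    background ROIs (and requires at least one); "none" returns raw disk means.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3:
        raise ValidationError(f"stack must be (frames, H, W); got shape {stack.shape}")
    if stack.shape[0] == 0:
        raise ValidationError("empty stack: zero frames")
    if background_policy not in ("mean", "none"):
        raise ValidationError("background_policy must be 'mean' or 'none'")
    if not rois.signal:
        raise RoiError("need at least one signal ROI")
    if background_policy == "mean" and not rois.background:
        raise RoiError("background_policy 'mean' requires at least one background ROI (or pass 'none')")
    rois.check_in_frame(stack.shape)

    t = np.arange(stack.shape[0]) * frame_interval if time is None else np.asarray(time, dtype=float)
    flat = stack.reshape(stack.shape[0], -1)

    def disk_means(roi: Roi) -> np.ndarray:
        mask = disk_mask(stack.shape, roi.center_x_px, roi.center_y_px, roi.radius_px)
        idx = np.flatnonzero(mask.ravel())
        if idx.size == 0:
            raise RoiError(f"roi {roi.roi_id!r} covers no pixel centers")
        return flat[:, idx].mean(axis=1)

    if background_policy == "mean":
        bg = np.mean([disk_means(r) for r in rois.background], axis=0)
    else:
        bg = np.zeros(stack.shape[0])

    data = {(r.roi_id, channel): disk_means(r) - bg for r in rois.signal}
    return RoiTraceSet(
        t, data, provenance={"background_policy": background_policy, "n_background_rois": len(rois.background)}
    )


@dataclass
class SelectionReport:
    kept: List[str]
    dropped: List[str]
    k_sigma: float

    @property
    def n_kept(self) -> int:
        return len(self.kept)

    @property
    def n_dropped(self) -> int:
        return len(self.dropped)


def select_responding_rois(
    traces: RoiTraceSet,
    protocol: StimulusProtocol,
    k_sigma: float = 2.0,
    channel: Optional[str] = None,
) -> tuple[RoiTraceSet, SelectionReport]:
    """Keep ROIs whose mean rise during the first AP train exceeds
    ``k_sigma`` times the pre-stimulus baseline standard deviation."""
    if channel is None:
        if len(traces.channels) != 1:
            raise ValidationError(f"trace set has channels {traces.channels}; specify one")
        channel = traces.channels[0]
    a, b = protocol.first_train_window()
    t = traces.time
    if not (t[0] <= a and b <= t[-1] + 1e-9):
        raise ValidationError("protocol's first train lies outside the trace span")
    base_mask = t < a
    train_mask = (t >= a) & (t < b)
    if not base_mask.any() or not train_mask.any():
        raise ValidationError("baseline or train window contains no frames")

    kept, dropped = [], []
    for roi in traces.rois:
        if (roi, channel) not in traces:
            continue
        v = traces.values(roi, channel)
        baseline = v[base_mask]
        rise = v[train_mask].mean() - baseline.mean()
        if rise > k_sigma * baseline.std(ddof=0):
            kept.append(roi)
        else:
            dropped.append(roi)
    if not kept:
        raise EmptySelectionError(
            f"all {len(dropped)} ROIs rejected at k_sigma={k_sigma}; downstream analysis would run on nothing"
        )
    return traces.subset(kept), SelectionReport(kept, dropped, k_sigma)
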
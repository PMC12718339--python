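"""In-memory containers for fluorescence time series and their CSV schema.

The on-disk schema is a tidy CSV with columns ``time_s, roi_id, channel,
value`` shared by synthetic generators and the image-extraction stage, so
every downstream module is agnostic to where a trace came from.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, Optional, Tuple

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = ["FluorescenceTrace", "RoiTraceSet"]

TRACE_COLUMNS = ["time_s", "roi_id", "channel", "value"]


@dataclass
class FluorescenceTrace:
    """A single time-stamped intensity series."""

    time: np.ndarray
    values: np.ndarray
    channel: str = "F"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.time.ndim != 1 or self.time.shape != self.values.shape:
            raise ValidationError("time and values must be 1-D arrays of equal length")
        if self.time.size >= 2 and not np.all(np.diff(self.time) > 0):
            raise ValidationError("time axis must be strictly increasing")

    def __len__(self) -> int:
        return self.time.size

    @property
    def frame_interval(self) -> float:
        if len(self) < 2:
            raise ValidationError("need >= 2 samples to infer a frame interval")
        return float(np.median(np.diff(self.time)))

    def window(self, t0: float, t1: float) -> np.ndarray:
        """Values with t0 <= t < t1 (empty array if nothing falls inside)."""
        m = (self.time >= t0) & (self.time < t1)
        return self.values[m]

    def slice(self, t0: float, t1: float) -> "FluorescenceTrace":
        m = (self.time >= t0) & (self.time < t1)
        return FluorescenceTrace(self.time[m], self.values[m], self.channel, dict(self.meta))

    def copy_with(self, values: np.ndarray, **meta) -> "FluorescenceTrace":
        m = dict(self.meta)
        m.update(meta)
        return FluorescenceTrace(self.time.copy(), np.asarray(values, dtype=float), self.channel, m)


class RoiTraceSet:
    """Per-(roi_id, channel) intensity series on one shared time axis."""

    def __init__(
        self,
        time: np.ndarray,
        data: Dict[Tuple[str, str], np.ndarray],
        provenance: Optional[dict] = None,
    ):
        self.time = np.asarray(time, dtype=float)
        if self.time.ndim != 1:
            raise ValidationError("time axis must be 1-D")
        if self.time.size >= 2 and not np.all(np.diff(self.time) > 0):
            raise ValidationError("time axis must be strictly increasing")
        self._data: Dict[Tuple[str, str], np.ndarray] = {}
        for (roi, channel), v in data.items():
            v = np.asarray(v, dtype=float)
            if v.shape != self.time.shape:
                raise ValidationError(f"series ({roi}, {channel}) length {v.size} != time axis {self.time.size}")
            self._data[(str(roi), str(channel))] = v
        self.provenance = dict(provenance or {})

    # ---- access ---------------------------------------------------------

    @property
    def rois(self) -> list[str]:
        return sorted({r for r, _ in self._data})

    @property
    def channels(self) -> list[str]:
        return sorted({c for _, c in self._data})

    def __len__(self) -> int:
        return len(self._data)

    def __contains__(self, key) -> bool:
        return tuple(key) in self._data

    def trace(self, roi_id: str, channel: Optional[str] = None) -> FluorescenceTrace:
        if channel is None:
            channels = [c for r, c in self._data if r == str(roi_id)]
            if len(channels) != 1:
                raise ValidationError(f"roi {roi_id!r} has channels {channels}; specify one")
            channel = channels[0]
        key = (str(roi_id), str(channel))
        if key not in self._data:
            raise KeyError(f"no trace for roi={roi_id!r}, channel={channel!r}")
        return FluorescenceTrace(self.time, self._data[key], channel, {"roi_id": roi_id})

    def values(self, roi_id: str, channel: str) -> np.ndarray:
        return self._data[(str(roi_id), str(channel))]

    def roi_matrix(self, channel: str) -> tuple[list[str], np.ndarray]:
        """(roi_ids, array of shape (n_rois, n_frames)) for one channel."""
        rois = [r for r in self.rois if (r, channel) in self._data]
        if not rois:
            raise ValidationError(f"no ROIs carry channel {channel!r}")
        return rois, np.vstack([self._data[(r, channel)] for r in rois])

    def subset(self, roi_ids: Iterable[str]) -> "RoiTraceSet":
        keep = {str(r) for r in roi_ids}
        data = {k: v for k, v in self._data.items() if k[0] in keep}
        return RoiTraceSet(self.time, data, self.provenance)

    def with_channel(self, channel: str, data: Dict[str, np.ndarray]) -> "RoiTraceSet":
        merged = dict(self._data)
        for roi, v in data.items():
            merged[(str(roi), channel)] = np.asarray(v, dtype=float)
        return RoiTraceSet(self.time, merged, self.provenance)

    # ---- CSV schema -----------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (roi, channel), v in sorted(self._data.items()):
            rows.append(pd.DataFrame({"time_s": self.time, "roi_id": roi, "channel": channel, "value": v}))
        return pd.concat(rows, ignore_index=True)[TRACE_COLUMNS]

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, provenance: Optional[dict] = None) -> "RoiTraceSet":
        missing = [c for c in TRACE_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"trace table missing columns {missing}")
        time = np.sort(df["time_s"].unique())
        data = {}
        for (roi, channel), g in df.groupby(["roi_id", "channel"], sort=True):
            g = g.sort_values("time_s")
            if g["time_s"].size != time.size or not np.allclose(g["time_s"].to_numpy(), time):
                raise ValidationError(f"series ({roi}, {channel}) does not share the common time axis")
            data[(str(roi), str(channel))] = g["value"].to_numpy(dtype=float)
        return cls(time, data, provenance)

    @classmethod
    def from_csv(cls, path) -> "RoiTraceSet":
        return cls.from_frame(pd.read_csv(path), provenance={"source": str(path)})
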
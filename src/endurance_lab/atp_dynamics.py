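"""Ratiometric ATP analysis: sensor/reference ratio, neuron averaging, and
baseline / drop / recovery phase decomposition.

The intensiometric ATP sensor is co-expressed with a spectrally separate
reference fluorophore; their ratio cancels expression level and any
multiplicative factor shared by the two channels (illumination drifts,
bleaching). Per neuron, ROI ratios are averaged and normalized to the
pre-stimulation baseline (= 100%). The "drop" is the percentage lost at the
trace minimum within the stimulation window (+ a grace period), the
"recovery" the mean level over the final tail window.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np

from .errors import ValidationError
from .protocols import StimulusProtocol
from .traces import FluorescenceTrace, RoiTraceSet

__all__ = ["AtpPhases", "compute_ratio", "neuron_average_and_baseline", "atp_phases"]

DROP_GRACE_S = 10.0
RECOVERY_WINDOW_S = 60.0


@dataclass
class AtpPhases:
    baseline_percent: float
    drop_percent: float
    recovery_percent: float
    t_min: float
    windows: Dict[str, Tuple[float, float]] = field(default_factory=dict)


def compute_ratio(
    traces: RoiTraceSet,
    sensor_channel: str = "sensor",
    reference_channel: str = "reference",
    reference_floor: float = 0.0,
) -> RoiTraceSet:
    """Element-wise sensor / reference ratio per ROI.

    Frames where the reference falls at or below ``reference_floor`` are
    masked (NaN) and counted in the provenance; an ROI whose reference is
    fully masked raises. The floor should be set to ~3x the reference
    channel's background noise sd; the default 0 masks only non-positive
    frames.
    """
    rois = [r for r in traces.rois if (r, sensor_channel) in traces and (r, reference_channel) in traces]
    if not rois:
        raise ValidationError(
            f"no ROI carries both channels {sensor_channel!r} and {reference_channel!r}"
        )
    data = {}
    masked_counts = {}
    for roi in rois:
        sens = traces.values(roi, sensor_channel)
        ref = traces.values(roi, reference_channel).copy()
        bad = ref <= reference_floor
        if bad.all():
            raise ValidationError(f"roi {roi!r}: reference fully below the floor; ratio undefined")
        ref[bad] = np.nan
        data[(roi, "ratio")] = sens / ref
        masked_counts[roi] = int(bad.sum())
    prov = dict(traces.provenance)
    prov.update({"reference_floor": reference_floor, "masked_frames": masked_counts})
    return RoiTraceSet(traces.time, data, prov)


def neuron_average_and_baseline(
    ratios: RoiTraceSet,
    protocol: Optional[StimulusProtocol] = None,
    baseline_window: Optional[Tuple[float, float]] = None,
    channel: str = "ratio",
) -> FluorescenceTrace:
    """Average all ROI ratios per frame and normalize to the pre-stimulus
    baseline; output is percent of baseline (baseline mean = 100)."""
    if baseline_window is None:
        if protocol is None:
            raise ValidationError("provide a protocol or an explicit baseline_window")
        baseline_window = (float(ratios.time[0]), protocol.first_stimulus_start_s())
    _, mat = ratios.roi_matrix(channel)
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(mat, axis=0)
    t = ratios.time
    a, b = baseline_window
    base = mean[(t >= a) & (t < b)]
    base = base[np.isfinite(base)]
    if base.size == 0:
        raise ValidationError("baseline window contains no usable frames")
    return FluorescenceTrace(
        t,
        100.0 * mean / base.mean(),
        channel="atp_ratio_percent",
        meta={"n_rois": mat.shape[0], "baseline_window": baseline_window},
    )


def atp_phases(
    neuron_trace: FluorescenceTrace,
    protocol: StimulusProtocol,
    drop_grace_s: float = DROP_GRACE_S,
    recovery_window_s: float = RECOVERY_WINDOW_S,
    drop_mode: str = "min",
) -> AtpPhases:
    """Decompose a baseline-normalized neuron trace into phases.

    drop_percent = 100 - (trace minimum within [train start, train end +
    grace]) — or the value at train end with ``drop_mode='train_end'``.
    recovery_percent = mean over the final ``recovery_window_s`` seconds.
    """
    window = protocol.long_train_window()
    if window is None:
        if protocol.rounds == 0:
            raise ValidationError("protocol declares neither a long train nor rounds")
        window = (protocol.round_windows()[0][0], protocol.round_windows()[-1][1])
    a, b = window
    t = neuron_trace.time
    if a < t[0] or b > t[-1] + 1e-9:
        raise ValidationError("stimulation window lies outside the trace span")
    if drop_mode not in ("min", "train_end"):
        raise ValidationError("drop_mode must be 'min' or 'train_end'")

    m = (t >= a) & (t < b + drop_grace_s)
    if not m.any():
        raise ValidationError("drop window contains no frames")
    seg = neuron_trace.values[m]
    if drop_mode == "min":
        i_rel = int(np.nanargmin(seg))
    else:
        i_rel = int(np.flatnonzero(t[m] < b).max())
    t_min = float(t[m][i_rel])
    drop = 100.0 - float(seg[i_rel])

    r0 = t[-1] - recovery_window_s
    if r0 < b:
        raise ValidationError("recovery window overlaps the stimulation window")
    tail = neuron_trace.values[t >= r0]
    tail = tail[np.isfinite(tail)]
    if tail.size == 0:
        raise ValidationError("recovery window contains no usable frames")

    return AtpPhases(
        baseline_percent=100.0,
        drop_percent=max(drop, 0.0),
        recovery_percent=float(tail.mean()),
        t_min=t_min,
        windows={"stimulation": (a, b), "drop": (a, b + drop_grace_s), "recovery": (float(r0), float(t[-1]))},
    )
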
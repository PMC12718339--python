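"""Synthetic optical readouts: pHluorin traces and two-channel ATP sensor traces.

The pHluorin model: each stimulus round exocytoses a fixed fraction of the
not-yet-surfaced vesicle pool, spread over the train; retrieval is paused
during stimulation and afterwards proceeds as a first-order decay with rate
``capacity(ATP) / endocytosis_tau``, so un-retrieved signal from failed
rounds accumulates at the surface. An NH4Cl epoch unquenches the whole pool
(fluorescence = total). Bleaching is multiplicative exponential shared by
all channels; noise is additive Gaussian scaled to the first-round peak.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional, Union

import numpy as np

from ..errors import ValidationError
from ..params import SimulationParams
from ..protocols import StimulusProtocol
from ..traces import FluorescenceTrace, RoiTraceSet
from .bioenergetics import TerminalTrajectory, simulate_terminal_state

__all__ = ["GroundTruth", "simulate_ph_trace", "simulate_atp_ratio_traces"]

SeedLike = Union[int, np.random.SeedSequence, np.random.Generator]


@dataclass
class GroundTruth:
    """True parameters behind one synthetic artifact."""

    kind: str
    condition: str = ""
    seed_repr: str = ""
    true_tau: Optional[float] = None
    arrest_round: Optional[int] = None
    params: dict = field(default_factory=dict)
    extras: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as f:
            json.dump(asdict(self), f, indent=2, sort_keys=True, default=_jsonable)


def _jsonable(x):
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    raise TypeError(f"not JSON-serializable: {type(x)}")


def _check_span(state: TerminalTrajectory, protocol: StimulusProtocol) -> None:
    t = protocol.time_axis()
    if len(state) != t.size or not np.allclose(state.time, t):
        raise ValidationError("terminal-state sequence does not cover the protocol time axis")


def simulate_ph_trace(
    params: SimulationParams,
    protocol: StimulusProtocol,
    state: TerminalTrajectory,
    seed: SeedLike,
    capacity_override=None,
    forced_arrest_round: Optional[int] = None,
    condition: str = "",
) -> tuple[FluorescenceTrace, GroundTruth]:
    """Generate one pHluorin trace from a bioenergetic trajectory.

    ``capacity_override`` pins the endocytic capacity (scalar or per-frame
    array) instead of deriving it from ATP; ``forced_arrest_round`` pins
    capacity to 1 before the given 1-based round and 0 from its onset (used
    for pipeline parameter-recovery checks). Identical inputs and seed give
    bit-identical output.
    """
    _check_span(state, protocol)
    rng = np.random.default_rng(seed)
    t = protocol.time_axis()
    dt = protocol.frame_interval

    if forced_arrest_round is not None and capacity_override is not None:
        raise ValidationError("give either capacity_override or forced_arrest_round, not both")
    if forced_arrest_round is not None:
        if not 1 <= forced_arrest_round <= protocol.rounds:
            raise ValidationError(f"forced_arrest_round must be in [1, {protocol.rounds}]")
        t_arrest = protocol.round_windows()[forced_arrest_round - 1][0]
        cap = np.where(t < t_arrest, 1.0, 0.0)
    elif capacity_override is not None:
        cap = np.broadcast_to(np.asarray(capacity_override, dtype=float), t.shape).copy()
        if np.any(cap < 0):
            raise ValidationError("capacity must be non-negative")
    else:
        cap = params.endocytic_capacity(state.atp)

    trains = list(protocol.round_windows())
    if protocol.reference_window() is not None:
        trains.insert(0, protocol.reference_window())

    in_train = np.zeros(t.size, dtype=bool)
    train_id = np.full(t.size, -1, dtype=int)
    for k, (a, b) in enumerate(trains):
        m = (t >= a) & (t < b)
        in_train |= m
        train_id[m] = k

    s = 0.0
    surface = np.empty(t.size)
    release_per_frame = {}
    current_train = -1
    for i in range(t.size):
        if in_train[i]:
            k = train_id[i]
            if k != current_train:
                n_frames = int(np.sum(train_id == k))
                release_per_frame[k] = params.exo_pool_fraction_per_round * (1.0 - s) / n_frames
                current_train = k
            s += release_per_frame[k]
        else:
            current_train = -1
            s *= np.exp(-cap[i] * dt / params.endocytosis_tau)
        surface[i] = s

    f0 = params.surface_fraction_rest
    raw = f0 + (1.0 - f0) * surface
    if protocol.nh4cl_epoch is not None:
        a, b = protocol.nh4cl_epoch
        raw[(t >= a) & (t < b)] = 1.0

    raw = raw * np.exp(-params.bleach_rate * t)
    if params.noise_sd > 0:
        scale = params.noise_sd * (1.0 - f0) * params.exo_pool_fraction_per_round
        raw = raw + rng.normal(0.0, scale, size=raw.shape)

    trace = FluorescenceTrace(t, raw, channel="pHluorin", meta={"condition": condition})
    gt = GroundTruth(
        kind="ph_trace",
        condition=condition,
        seed_repr=repr(seed),
        true_tau=params.endocytosis_tau,
        arrest_round=forced_arrest_round,
        params=params.to_dict(),
        extras={
            "first_round_peak_fraction": params.exo_pool_fraction_per_round,
            "store_effective": state.meta.get("store_effective"),
        },
    )
    return trace, gt


def simulate_atp_ratio_traces(
    params: SimulationParams,
    protocol: StimulusProtocol,
    n_rois: int = 50,
    seed: SeedLike = 0,
    state: Optional[TerminalTrajectory] = None,
    condition: str = "",
) -> tuple[RoiTraceSet, GroundTruth]:
    """Generate paired sensor/reference ROI traces for the ATP paradigm.

    The sensor channel follows the saturating sensor response of the
    simulated ATP; the reference channel has a constant mean. Per-ROI
    brightness is log-normal; bleaching is shared by both channels (so it
    cancels in the ratio); noise is additive, independent per channel.
    The default ROI count matches practice (40-60 boutons per neuron).
    """
    if n_rois < 1:
        raise ValidationError("n_rois must be >= 1")
    ss = np.random.SeedSequence(seed) if isinstance(seed, int) else seed
    if isinstance(ss, np.random.Generator):
        rng_state = rng_opt = ss
    else:
        child_state, child_opt = ss.spawn(2)
        rng_state = np.random.default_rng(child_state)
        rng_opt = np.random.default_rng(child_opt)

    if state is None:
        state = simulate_terminal_state(params, protocol, rng_state)
    else:
        _check_span(state, protocol)

    t = protocol.time_axis()
    response = params.sensor_response(state.atp)  # noise-free, 1.0 at resting ATP
    bleach = np.exp(-params.bleach_rate * t)

    amp_sensor = 100.0 * np.exp(rng_opt.normal(0.0, 0.4, size=n_rois))
    amp_ref = 80.0 * np.exp(rng_opt.normal(0.0, 0.4, size=n_rois))

    data = {}
    for i in range(n_rois):
        roi = f"roi{i:03d}"
        sens = amp_sensor[i] * response * bleach
        ref = amp_ref[i] * np.ones_like(t) * bleach
        if params.noise_sd > 0:
            sens = sens + rng_opt.normal(0.0, params.noise_sd * amp_sensor[i], size=t.size)
            ref = ref + rng_opt.normal(0.0, params.noise_sd * amp_ref[i], size=t.size)
        data[(roi, "sensor")] = sens
        data[(roi, "reference")] = ref

    traces = RoiTraceSet(t, data, provenance={"generator": "simulate_atp_ratio_traces", "condition": condition})
    gt = GroundTruth(
        kind="atp_ratio_traces",
        condition=condition,
        seed_repr=repr(seed),
        params=params.to_dict(),
        extras={
            "atp": state.atp,
            "response_noise_free": response,
            "min_atp": float(state.atp.min()),
            "store_effective": state.meta.get("store_effective"),
        },
    )
    return traces, gt
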
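"""Stimulation protocols: timing of AP trains, glucose switches and NH4Cl epochs.

A protocol describes *when* things happen to the preparation, in seconds from
the start of the recording: an optional single reference round delivered in
5 mM glucose (used to fit the re-acidification time constant), a series of
identical stimulus rounds (the endurance assay: 50 APs at 10 Hz, one round
per minute), an optional single long train (the ATP paradigm: 600 APs at
10 Hz), the extracellular glucose timeline, and an optional NH4Cl
(total-pool unquenching) epoch at the end of the recording.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence, Tuple

import numpy as np
import yaml

from .errors import ProtocolError

__all__ = ["StimulusProtocol", "endurance_protocol", "atp_long_train_protocol"]


@dataclass(frozen=True)
class StimulusProtocol:
    """Timing description of one imaging experiment.

    Times are seconds from recording start. ``glucose_timeline`` is a list of
    ``(start_s, glucose_mM)`` pairs, piecewise constant, and must start at or
    before t = 0. ``rounds`` may be 0 only when a ``long_train`` is declared.
    """

    frame_interval: float = 0.5
    rounds: int = 1
    aps_per_round: int = 50
    ap_frequency: float = 10.0
    inter_round_interval: float = 60.0
    first_round_start_s: float = 120.0
    glucose_timeline: Tuple[Tuple[float, float], ...] = ((0.0, 0.0),)
    nh4cl_epoch: Optional[Tuple[float, float]] = None
    long_train: Optional[Tuple[int, float]] = None  # (n_aps, frequency_hz)
    long_train_start_s: Optional[float] = None
    reference_round_start_s: Optional[float] = None
    duration_s: Optional[float] = None

    def __post_init__(self):
        if self.frame_interval <= 0:
            raise ProtocolError("frame_interval must be > 0")
        if self.long_train is None and self.rounds < 1:
            raise ProtocolError("rounds must be >= 1 (unless a long_train is declared)")
        if self.rounds < 0:
            raise ProtocolError("rounds must be non-negative")
        if self.rounds > 0:
            if self.aps_per_round < 1:
                raise ProtocolError("aps_per_round must be >= 1")
            if self.ap_frequency <= 0:
                raise ProtocolError("ap_frequency must be > 0")
            if self.inter_round_interval <= 0:
                raise ProtocolError("inter_round_interval must be > 0")
            if self.train_duration_s > self.inter_round_interval:
                raise ProtocolError("stimulus rounds overlap: train longer than inter-round interval")
        if self.long_train is not None:
            n_aps, freq = self.long_train
            if n_aps < 1 or freq <= 0:
                raise ProtocolError("long_train must be (n_aps >= 1, frequency > 0)")
            if self.long_train_start_s is None:
                object.__setattr__(self, "long_train_start_s", 60.0)
            if self.long_train_start_s < 0:
                raise ProtocolError("long_train_start_s must be non-negative")
        if not self.glucose_timeline:
            raise ProtocolError("glucose_timeline must contain at least one entry")
        starts = [t for t, _ in self.glucose_timeline]
        if any(t < 0 for t in starts):
            raise ProtocolError("glucose_timeline times must be non-negative")
        if any(b <= a for a, b in zip(starts, starts[1:])):
            raise ProtocolError("glucose_timeline times must be strictly increasing")
        if starts[0] > 0:
            raise ProtocolError("glucose_timeline must define glucose from t = 0")
        if any(g < 0 for _, g in self.glucose_timeline):
            raise ProtocolError("glucose concentrations must be non-negative")
        if self.first_round_start_s < 0:
            raise ProtocolError("first_round_start_s must be non-negative")
        if self.reference_round_start_s is not None and self.reference_round_start_s < 0:
            raise ProtocolError("reference_round_start_s must be non-negative")
        if self.nh4cl_epoch is not None:
            a, b = self.nh4cl_epoch
            if not (0 <= a < b):
                raise ProtocolError("nh4cl_epoch must be an ordered (start, end) pair")
            if self.rounds > 0 and a < self.round_windows()[-1][1]:
                raise ProtocolError("nh4cl_epoch must begin after the last stimulus round")
        if self.duration_s is None:
            object.__setattr__(self, "duration_s", self._default_duration())
        if self.duration_s <= 0:
            raise ProtocolError("duration_s must be > 0")
        # every declared event must fit inside the recording
        for t in self._event_end_times():
            if t > self.duration_s + 1e-9:
                raise ProtocolError(f"protocol event ending at {t:.1f}s exceeds duration {self.duration_s:.1f}s")

    # ---- derived timing -------------------------------------------------

    @property
    def train_duration_s(self) -> float:
        return self.aps_per_round / self.ap_frequency

    @property
    def long_train_duration_s(self) -> Optional[float]:
        if self.long_train is None:
            return None
        n_aps, freq = self.long_train
        return n_aps / freq

    def round_windows(self) -> list[tuple[float, float]]:
        """(start, end) of each endurance stimulus round, in order."""
        return [
            (
                self.first_round_start_s + k * self.inter_round_interval,
                self.first_round_start_s + k * self.inter_round_interval + self.train_duration_s,
            )
            for k in range(self.rounds)
        ]

    def reference_window(self) -> Optional[tuple[float, float]]:
        if self.reference_round_start_s is None:
            return None
        return (self.reference_round_start_s, self.reference_round_start_s + self.train_duration_s)

    def long_train_window(self) -> Optional[tuple[float, float]]:
        if self.long_train is None:
            return None
        return (self.long_train_start_s, self.long_train_start_s + self.long_train_duration_s)

    def first_train_window(self) -> tuple[float, float]:
        """The earliest stimulus epoch (reference round if declared)."""
        candidates = []
        if self.reference_window() is not None:
            candidates.append(self.reference_window())
        if self.rounds > 0:
            candidates.append(self.round_windows()[0])
        if self.long_train_window() is not None:
            candidates.append(self.long_train_window())
        if not candidates:
            raise ProtocolError("protocol declares no stimulus at all")
        return min(candidates, key=lambda w: w[0])

    def first_stimulus_start_s(self) -> float:
        return self.first_train_window()[0]

    def _event_end_times(self):
        times = [w[1] for w in self.round_windows()]
        for w in (self.reference_window(), self.long_train_window()):
            if w is not None:
                times.append(w[1])
        if self.nh4cl_epoch is not None:
            times.append(self.nh4cl_epoch[1])
        return times

    def _default_duration(self) -> float:
        return max(self._event_end_times(), default=60.0) + 30.0

    # ---- sampled views --------------------------------------------------

    @property
    def n_frames(self) -> int:
        return int(np.floor(self.duration_s / self.frame_interval)) + 1

    def time_axis(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval

    def ap_rate(self, t: Optional[np.ndarray] = None) -> np.ndarray:
        """Instantaneous AP rate (Hz) at each frame time."""
        t = self.time_axis() if t is None else np.asarray(t, dtype=float)
        rate = np.zeros_like(t)
        windows = list(self.round_windows())
        if self.reference_window() is not None:
            windows.append(self.reference_window())
        for a, b in windows:
            rate[(t >= a) & (t < b)] = self.ap_frequency
        if self.long_train_window() is not None:
            a, b = self.long_train_window()
            rate[(t >= a) & (t < b)] = self.long_train[1]
        return rate

    def glucose(self, t: Optional[np.ndarray] = None) -> np.ndarray:
        """Extracellular glucose (mM) at each frame time."""
        t = self.time_axis() if t is None else np.asarray(t, dtype=float)
        starts = np.array([a for a, _ in self.glucose_timeline])
        levels = np.array([g for _, g in self.glucose_timeline])
        idx = np.clip(np.searchsorted(starts, t, side="right") - 1, 0, len(levels) - 1)
        return levels[idx]

    # ---- serialization --------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["glucose_timeline"] = [list(p) for p in self.glucose_timeline]
        if d["nh4cl_epoch"] is not None:
            d["nh4cl_epoch"] = list(d["nh4cl_epoch"])
        if d["long_train"] is not None:
            d["long_train"] = list(d["long_train"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "StimulusProtocol":
        d = dict(d)
        d["glucose_timeline"] = tuple(tuple(p) for p in d.get("glucose_timeline", [[0.0, 0.0]]))
        if d.get("nh4cl_epoch") is not None:
            d["nh4cl_epoch"] = tuple(d["nh4cl_epoch"])
        if d.get("long_train") is not None:
            lt = d["long_train"]
            d["long_train"] = (int(lt[0]), float(lt[1]))
        return cls(**d)

    def save_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load_yaml(cls, path) -> "StimulusProtocol":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def endurance_protocol(
    rounds: int = 30,
    glucose_mM: float = 0.0,
    frame_interval: float = 0.5,
    reference_glucose_mM: float = 5.0,
) -> StimulusProtocol:
    """The repeated-round endurance assay.

    One reference round (50 APs, 10 Hz) at t = 30 s in ``reference_glucose_mM``
    glucose (default 5 mM, where the decay time constant is fitted), a switch
    to ``glucose_mM`` at t = 80 s, then ``rounds`` identical rounds applied
    every minute from t = 120 s, and a 20 s NH4Cl unquenching epoch 40 s
    after the last round.
    """
    last_end = 120.0 + (rounds - 1) * 60.0 + 5.0
    nh4 = (last_end + 40.0, last_end + 60.0)
    return StimulusProtocol(
        frame_interval=frame_interval,
        rounds=rounds,
        aps_per_round=50,
        ap_frequency=10.0,
        inter_round_interval=60.0,
        first_round_start_s=120.0,
        reference_round_start_s=30.0,
        glucose_timeline=((0.0, reference_glucose_mM), (80.0, glucose_mM)),
        nh4cl_epoch=nh4,
        duration_s=nh4[1] + 5.0,
    )


def atp_long_train_protocol(
    glucose_mM: float = 0.0,
    frame_interval: float = 0.5,
) -> StimulusProtocol:
    """The single long-train ATP paradigm: 600 APs at 10 Hz from t = 60 s,
    recording to t = 300 s (the final minute is the recovery window)."""
    return StimulusProtocol(
        frame_interval=frame_interval,
        rounds=0,
        glucose_timeline=((0.0, glucose_mM),),
        long_train=(600, 10.0),
        long_train_start_s=60.0,
        duration_s=300.0,
    )
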
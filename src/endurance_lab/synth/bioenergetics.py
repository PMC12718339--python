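"""Terminal ATP/glycogen trajectory simulation.

A forward-Euler update at the imaging frame interval. ATP consumption is a
resting cost plus a per-action-potential cost; supply comes from glucose
uptake (proportional to extracellular glucose) and, when glucose supply
falls short of demand, from glycogenolysis. The glycogen flux is
demand-gated (the store is only drawn on to cover the deficit plus an
ATP-refilling drive), capped by GP activity with an activity-dependent
boost, and fades once the store is nearly empty. Both state variables are
bounded in [0, 1]; glycogen is strictly non-increasing (the model has no
synthesis flux).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np

from ..errors import ValidationError
from ..params import SimulationParams
from ..protocols import StimulusProtocol

__all__ = ["TerminalState", "TerminalTrajectory", "simulate_terminal_state"]

_AP_RATE_REF = 10.0  # Hz at which the activity signal saturates to 1


@dataclass(frozen=True)
class TerminalState:
    """Instantaneous bioenergetic state (ATP and glycogen relative units)."""

    time: float
    atp: float
    glycogen: float


class TerminalTrajectory(Sequence):
    """Sampled sequence of TerminalStates, exposed both as arrays and records."""

    def __init__(self, time: np.ndarray, atp: np.ndarray, glycogen: np.ndarray, meta: Optional[dict] = None):
        self.time = np.asarray(time, dtype=float)
        self.atp = np.asarray(atp, dtype=float)
        self.glycogen = np.asarray(glycogen, dtype=float)
        if not (self.time.shape == self.atp.shape == self.glycogen.shape):
            raise ValidationError("trajectory arrays must share one shape")
        self.meta = dict(meta or {})

    def __len__(self) -> int:
        return self.time.size

    def __getitem__(self, i):
        if isinstance(i, slice):
            return TerminalTrajectory(self.time[i], self.atp[i], self.glycogen[i], self.meta)
        return TerminalState(float(self.time[i]), float(self.atp[i]), float(self.glycogen[i]))


def simulate_terminal_state(
    params: SimulationParams,
    protocol: StimulusProtocol,
    seed: Union[int, np.random.SeedSequence, np.random.Generator],
) -> TerminalTrajectory:
    """Simulate the ATP/glycogen trajectory for one terminal.

    Deterministic given (params, protocol, seed); the only random elements
    are per-neuron log-normal jitters of the initial glycogen store
    (``store_jitter_sigma``, clipped so the store stays in [0, 1]), the GP
    flux cap (``gp_jitter_sigma``) and the per-AP cost (``cost_jitter_sigma``).
    """
    if not isinstance(params, SimulationParams):
        raise ValidationError("params must be a SimulationParams instance")
    rng = np.random.default_rng(seed)
    t = protocol.time_axis()
    dt = protocol.frame_interval
    ap_rate = protocol.ap_rate(t)
    glucose = protocol.glucose(t)

    def _jitter(sigma: float) -> float:
        # always consume one draw so trajectories with different sigma settings
        # stay stream-aligned for the same seed
        z = rng.normal(0.0, 1.0)
        return float(np.exp(sigma * z)) if sigma > 0 else 1.0

    jitter = _jitter(params.store_jitter_sigma)
    gp_jitter = _jitter(params.gp_jitter_sigma)
    cost_jitter = _jitter(params.cost_jitter_sigma)
    g0 = float(np.clip(params.glycogen_store_0 * params.d2r_tone * jitter, 0.0, 1.0))

    n = t.size
    atp = np.empty(n)
    gly = np.empty(n)
    a, g, ca = 1.0, g0, 0.0
    atp[0], gly[0] = a, g

    boost = params.activity_gp_boost - 1.0
    knee = max(params.glycogen_knee, 1e-12)
    gp_base = params.gp_activity * params.gp_max_flux * gp_jitter
    ap_cost = params.atp_cost_per_ap * cost_jitter
    fade_p = params.glycogen_fade_power
    for i in range(1, n):
        # activity signal: low-pass of the normalized AP rate
        ca += dt * (ap_rate[i - 1] / _AP_RATE_REF - ca) / params.ca_tau_s
        demand = params.atp_rest_cost + ap_cost * ap_rate[i - 1]
        glu_supply = params.glucose_uptake_gain * glucose[i - 1]
        want = demand + params.recovery_gain * (1.0 - a)
        flux_cap = gp_base * (1.0 + boost * ca) * min(g / knee, 1.0) ** fade_p
        gp_supply = min(max(want - glu_supply, 0.0), flux_cap)
        a = min(max(a + dt * (glu_supply + gp_supply - demand), 0.0), 1.0)
        g = max(g - dt * gp_supply / params.glycogen_capacity, 0.0)
        atp[i], gly[i] = a, g

    return TerminalTrajectory(
        t,
        atp,
        gly,
        meta={
            "store_effective": g0,
            "store_jitter": jitter,
            "gp_jitter": gp_jitter,
            "cost_jitter": cost_jitter,
            "min_atp": float(atp.min()),
        },
    )
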
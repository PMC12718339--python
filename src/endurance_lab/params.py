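"""Phenomenological nerve-terminal bioenergetics parameters and condition presets.

All quantities are dimensionless: ATP is expressed relative to its resting
level (1.0 = rest), the glycogen store is a filling fraction in [0, 1], and
costs/fluxes are per-second rates on the ATP scale. The presets encode the
experimental conditions of the assays: dopaminergic terminals in 0 or 5 mM
glucose, glycogen-phosphorylase inhibition (GPI, full block) or knockdown
(GP-KD, 50% loss), chronic D2-receptor antagonism (sulpiride, depleting the
store to ~55%), and glutamatergic (hippocampal) terminals with little
glycogen reliance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict, replace
from importlib import resources
from typing import Optional

import yaml

from .errors import ValidationError
from .protocols import StimulusProtocol, endurance_protocol, atp_long_train_protocol

__all__ = ["SimulationParams", "condition_presets", "PRESET_NAMES", "default_protocol"]

PRESET_NAMES = ("glut_0gluc", "da_0gluc", "da_gpi", "da_gpkd", "da_sulpiride", "da_5gluc")

_FRACTION_FIELDS = (
    "glycogen_store_0",
    "gp_activity",
    "d2r_tone",
    "exo_pool_fraction_per_round",
    "surface_fraction_rest",
)


@dataclass(frozen=True)
class SimulationParams:
    """Parameters of the terminal ATP/glycogen model and its optical readouts.

    The glycogen path supplies ATP through glycogen phosphorylase (GP): the
    flux cap is ``gp_activity * gp_max_flux``, boosted ``activity_gp_boost``-
    fold at full 10 Hz firing through a calcium-like low-pass of the AP rate
    (time constant ``ca_tau_s``), and fades linearly once the store falls
    below ``glycogen_knee``. One full store holds ``glycogen_capacity``
    ATP-units. Endocytic capacity is a Hill function of ATP (``atp_capacity_
    halfpoint``, ``hill_n``) normalized to 1 at resting ATP.
    """

    # reserves and fluxes
    glycogen_store_0: float = 0.5
    gp_activity: float = 1.0
    glucose_uptake_gain: float = 4e-4      # per mM per s
    atp_cost_per_ap: float = 8e-4          # per AP
    atp_rest_cost: float = 8e-4            # per s
    gp_max_flux: float = 1.4e-3            # per s, resting flux cap at full store
    activity_gp_boost: float = 4.0         # fold increase of the cap at 10 Hz firing
    ca_tau_s: float = 10.0                 # low-pass time constant of the activity signal
    glycogen_capacity: float = 4.1         # ATP-units held by a full store
    glycogen_knee: float = 0.18            # store level below which the flux cap fades
    glycogen_fade_power: float = 2.0       # sharpness of the below-knee flux fade
    recovery_gain: float = 0.05            # per s, demand for refilling the ATP deficit
    d2r_tone: float = 1.0                  # scales the initial store (D2 autoreceptor tone)
    store_jitter_sigma: float = 0.45       # log-normal sigma of per-neuron store variation
    gp_jitter_sigma: float = 0.15          # log-normal sigma of per-neuron GP flux variation
    cost_jitter_sigma: float = 0.10        # log-normal sigma of per-neuron AP-cost variation
    # vesicle recycling readout
    endocytosis_tau: float = 8.0           # s
    atp_capacity_halfpoint: float = 0.7
    hill_n: float = 8.0
    exo_pool_fraction_per_round: float = 0.15
    surface_fraction_rest: float = 0.15    # resting fluorescence as a fraction of total pool
    # ATP sensor readout
    atp_sensor_k: float = 3.0              # saturation constant of the sensor response
    # optical nuisance terms
    noise_sd: float = 0.05                 # additive noise, as a fraction of the signal scale
    bleach_rate: float = 2e-5              # per s, shared multiplicative bleaching
    # condition-level glucose (used when building a default protocol)
    glucose_mM: float = 0.0

    def __post_init__(self):
        for name, value in asdict(self).items():
            if not math.isfinite(value):
                raise ValidationError(f"{name} must be finite, got {value!r}")
            if value < 0:
                raise ValidationError(f"{name} must be non-negative, got {value!r}")
        for name in _FRACTION_FIELDS:
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1], got {v!r}")
        if self.endocytosis_tau <= 0:
            raise ValidationError("endocytosis_tau must be > 0")
        if self.hill_n <= 0 or self.atp_capacity_halfpoint <= 0:
            raise ValidationError("Hill parameters must be > 0")

    def endocytic_capacity(self, atp):
        """Hill map from relative ATP to endocytic capacity, normalized to 1 at ATP = 1."""
        import numpy as np

        a = np.asarray(atp, dtype=float)
        h, n = self.atp_capacity_halfpoint, self.hill_n
        f = (a / h) ** n
        f = f / (1.0 + f)
        f1 = (1.0 / h) ** n
        return f / (f1 / (1.0 + f1))

    def sensor_response(self, atp):
        """Saturating (invertible) map from relative ATP to sensor signal; 1 at ATP = 1."""
        import numpy as np

        a = np.asarray(atp, dtype=float)
        k = self.atp_sensor_k
        return a * (1.0 + k) / (a + k)

    def replace(self, **changes) -> "SimulationParams":
        return replace(self, **changes)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationParams":
        return cls(**d)


def _load_preset_file(name: str) -> dict:
    ref = resources.files("endurance_lab.data").joinpath(f"presets/{name}.yaml")
    return yaml.safe_load(ref.read_text())


def condition_presets(name: str) -> SimulationParams:
    """Return the parameter set for a named experimental condition.

    Presets differ from the dopaminergic 0-glucose baseline only in
    interpretable fields: ``gp_activity`` (GPI sets it to 0, GP-KD halves
    it), ``d2r_tone`` (sulpiride scales the store to 0.546, the observed
    45.4% glycogen loss), ``glycogen_store_0``/``gp_activity`` (glutamatergic:
    small store, weak GP path) and ``glucose_mM``.
    """
    if name not in PRESET_NAMES:
        raise ValidationError(
            f"unknown condition preset {name!r}; valid presets: {', '.join(PRESET_NAMES)}"
        )
    d = _load_preset_file(name)
    d.pop("condition", None)
    return SimulationParams.from_dict(d)


def default_protocol(
    params_or_name,
    paradigm: str = "endurance",
    rounds: int = 30,
    frame_interval: float = 0.5,
) -> StimulusProtocol:
    """Build the standard protocol for a condition (its glucose level applied)."""
    params = condition_presets(params_or_name) if isinstance(params_or_name, str) else params_or_name
    if paradigm == "endurance":
        return endurance_protocol(rounds=rounds, glucose_mM=params.glucose_mM, frame_interval=frame_interval)
    if paradigm == "atp":
        return atp_long_train_protocol(glucose_mM=params.glucose_mM, frame_interval=frame_interval)
    raise ValidationError(f"unknown paradigm {paradigm!r}; choose 'endurance' or 'atp'")
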
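"""End-to-end orchestration: simulate -> analyze -> compare, from one config.

The config (dict or YAML file) declares named two-or-more-arm comparisons,
each arm a condition preset with a number of synthetic neurons. Endurance
comparisons run the full pHluorin chain (bioenergetic simulation, trace
generation, pool normalization, tau fit, EB series, rounds-to-block, with
censored neurons contributing max_rounds); ATP comparisons run the
ratiometric chain to per-neuron drop percentages. Arms are compared with
the Wilcoxon–Mann–Whitney test. The report is a plain JSON-serializable
dict; the same config and seed always produce a byte-identical report.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import yaml

from .errors import ValidationError
from .params import PRESET_NAMES, condition_presets, default_protocol
from .atp_dynamics import atp_phases, compute_ratio, neuron_average_and_baseline
from .ph_recycling import analyze_endurance_trace
from .stats import format_mean_sem, mann_whitney_u, summarize_group
from .synth import simulate_atp_ratio_traces, simulate_ph_trace, simulate_terminal_state

__all__ = ["run_pipeline", "load_config"]

_ANALYSES = ("endurance", "atp")


def load_config(config: Union[dict, str, Path]) -> dict:
    if isinstance(config, (str, Path)):
        return yaml.safe_load(Path(config).read_text())
    return dict(config)


def _validate_config(cfg: dict) -> None:
    comparisons = cfg.get("comparisons")
    if not comparisons:
        raise ValidationError("config declares no comparisons")
    for comp in comparisons:
        if "name" not in comp:
            raise ValidationError("every comparison needs a name")
        analysis = comp.get("analysis", "endurance")
        if analysis not in _ANALYSES:
            raise ValidationError(f"comparison {comp['name']!r}: unknown analysis {analysis!r}")
        arms = comp.get("arms", [])
        if len(arms) != 2:
            raise ValidationError(f"comparison {comp['name']!r}: exactly two arms required")
        for arm in arms:
            preset = arm.get("preset")
            if preset not in PRESET_NAMES:
                raise ValidationError(
                    f"comparison {comp['name']!r}: unknown preset {preset!r}; valid: {', '.join(PRESET_NAMES)}"
                )
            if int(arm.get("n_neurons", 0)) < 1:
                raise ValidationError(f"comparison {comp['name']!r}: each arm needs n_neurons >= 1")


def _endurance_arm(preset: str, n_neurons: int, seeds, rounds: int, eb_threshold: float) -> dict:
    params = condition_presets(preset)
    protocol = default_protocol(params, "endurance", rounds=rounds)
    values, censored = [], []
    for child in seeds:
        state = simulate_terminal_state(params, protocol, np.random.default_rng(child))
        trace, _ = simulate_ph_trace(params, protocol, state, np.random.default_rng(child.spawn(1)[0]), condition=preset)
        res = analyze_endurance_trace(trace, protocol, eb_threshold=eb_threshold).endurance
        values.append(res.rounds_to_block)
        censored.append(res.censored)
    return {
        "preset": preset,
        "n_neurons": n_neurons,
        "values": values,
        "n_censored": int(sum(censored)),
        "metric": "rounds_to_block",
    }


def _atp_arm(preset: str, n_neurons: int, seeds) -> dict:
    params = condition_presets(preset)
    protocol = default_protocol(params, "atp")
    values = []
    for child in seeds:
        traces, _ = simulate_atp_ratio_traces(params, protocol, seed=child, condition=preset)
        neuron = neuron_average_and_baseline(compute_ratio(traces), protocol)
        values.append(atp_phases(neuron, protocol).drop_percent)
    return {
        "preset": preset,
        "n_neurons": n_neurons,
        "values": values,
        "n_censored": 0,
        "metric": "atp_drop_percent",
    }


def run_pipeline(
    config: Union[dict, str, Path],
    seed: int,
    out_dir: Optional[Union[str, Path]] = None,
) -> dict:
    """Execute every comparison in the config; return (and optionally write)
    the report. All randomness derives from ``seed``."""
    cfg = load_config(config)
    _validate_config(cfg)  # abort before any compute

    root_ss = np.random.SeedSequence(seed)
    report = {"seed": int(seed), "comparisons": [], "config": cfg}
    tidy_rows = []
    for comp_idx, comp in enumerate(cfg["comparisons"]):
        analysis = comp.get("analysis", "endurance")
        rounds = int(comp.get("rounds", 30))
        eb_threshold = float(comp.get("eb_threshold", 50.0))
        alternative = comp.get("alternative", "two-sided")
        comp_ss = np.random.SeedSequence(entropy=root_ss.entropy, spawn_key=(comp_idx,))
        arm_results = []
        for arm_idx, arm in enumerate(comp["arms"]):
            n = int(arm["n_neurons"])
            arm_ss = np.random.SeedSequence(entropy=root_ss.entropy, spawn_key=(comp_idx, arm_idx))
            seeds = arm_ss.spawn(n)
            if analysis == "endurance":
                res = _endurance_arm(arm["preset"], n, seeds, rounds, eb_threshold)
            else:
                res = _atp_arm(arm["preset"], n, seeds)
            res["label"] = arm.get("label", arm["preset"])
            summ = summarize_group(res["values"])
            res["mean"] = summ.mean
            res["sem"] = summ.sem
            res["formatted"] = format_mean_sem(summ)
            arm_results.append(res)
            for i, v in enumerate(res["values"]):
                tidy_rows.append(
                    dict(comparison=comp["name"], arm=res["label"], preset=res["preset"],
                         neuron=i, metric=res["metric"], value=v)
                )
        test = mann_whitney_u(
            arm_results[0]["values"],
            arm_results[1]["values"],
            alternative=alternative,
            labels=(arm_results[0]["label"], arm_results[1]["label"]),
        )
        report["comparisons"].append(
            {
                "name": comp["name"],
                "analysis": analysis,
                "parameters": {"rounds": rounds, "eb_threshold": eb_threshold, "alternative": alternative},
                "arms": arm_results,
                "test": test.to_dict(),
            }
        )

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
        pd.DataFrame(tidy_rows).to_csv(out / "values.csv", index=False)
    return report
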
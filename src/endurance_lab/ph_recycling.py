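"""Synaptic endurance analysis on pHluorin traces.

The assay: repeated 50-AP rounds, one per minute. Each round's response is
segmented, the re-acidification time constant tau is fitted once per neuron
on a reference round recorded in 5 mM glucose, and the endocytic block (EB)
of every round is the percentage of that round's exocytic amplitude still
present 3*tau after the peak — ~5% (e^-3) for a perfect single-exponential
retrieval, 100% for complete arrest. Endurance is the 1-based index of the
first round whose EB exceeds the threshold (default 50%), right-censored at
``max_rounds`` when no round crosses it.

EB is computed from each round's own peak and immediately-preceding
baseline, which makes it invariant to gain and offset of the raw trace and
robust to pool rundown; using the NH4Cl-normalized or peak-normalized trace
therefore yields the same EB.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
from scipy.optimize import curve_fit

from .errors import CalibrationError, FitError, ProtocolError, ValidationError
from .protocols import StimulusProtocol
from .traces import FluorescenceTrace

__all__ = [
    "RoundResponse",
    "EnduranceResult",
    "TauFit",
    "normalize_to_total_pool",
    "normalize_to_peak",
    "segment_rounds",
    "fit_decay_tau",
    "compute_eb",
    "endurance_rounds",
    "analyze_endurance_trace",
    "EnduranceAnalysis",
]

GRACE_S = 2.0               # post-train window still eligible for the peak
BASELINE_WINDOW_S = 5.0     # quiet seconds averaged before each round
PROBE_HALFWIDTH_FRAMES = 2  # EB probe is a mean over +/- this many frames
MIN_FIT_POINTS = 5


@dataclass
class RoundResponse:
    """Segmented response of one stimulus round."""

    round_index: int            # 1-based
    t_stim_start: float
    t_stim_end: float
    peak_value: float
    t_peak: float
    baseline_pre: float
    tau: Optional[float] = None
    eb_percent: Optional[float] = None

    @property
    def amplitude(self) -> float:
        return self.peak_value - self.baseline_pre


@dataclass
class EnduranceResult:
    rounds_to_block: int
    censored: bool
    max_rounds: int
    eb_series: List[float]
    threshold: float = 50.0


@dataclass
class TauFit:
    tau: float
    amplitude: float
    offset: float
    resid_norm: float
    converged: bool
    n_points: int


def normalize_to_total_pool(
    trace: FluorescenceTrace,
    protocol: StimulusProtocol,
    plateau_trim: float = 0.25,
) -> FluorescenceTrace:
    """Express a trace as percent of total sensor pool.

    Output = 100 * (F - F0) / (F_NH4Cl - F0), where F0 is the mean over the
    pre-stimulus window and F_NH4Cl is the median of the NH4Cl epoch after
    discarding its first ``plateau_trim`` fraction (solution wash-in).
    """
    if protocol.nh4cl_epoch is None:
        raise ProtocolError("protocol declares no NH4Cl epoch; cannot normalize to total pool")
    a, b = protocol.nh4cl_epoch
    if b > trace.time[-1] + 1e-9:
        raise ValidationError("NH4Cl epoch lies outside the trace span")
    t_first = protocol.first_stimulus_start_s()
    baseline = trace.window(trace.time[0], t_first)
    if baseline.size == 0:
        raise ValidationError("no pre-stimulus frames available for F0")
    f0 = float(baseline.mean())
    plateau = trace.window(a + plateau_trim * (b - a), b)
    if plateau.size == 0:
        raise ValidationError("NH4Cl epoch contains no usable frames")
    f_nh4 = float(np.median(plateau))
    if f_nh4 <= f0:
        raise CalibrationError(
            f"total-pool calibration failed: NH4Cl plateau ({f_nh4:.4g}) <= baseline F0 ({f0:.4g})"
        )
    values = 100.0 * (trace.values - f0) / (f_nh4 - f0)
    return trace.copy_with(values, normalization="total_pool_percent", f0=f0, f_nh4cl=f_nh4)


def normalize_to_peak(
    trace: FluorescenceTrace,
    t_stim_start: float,
    t_stim_end: float,
    baseline_window_s: float = BASELINE_WINDOW_S,
    grace_s: float = GRACE_S,
) -> FluorescenceTrace:
    """Normalize a single-train segment so baseline -> 0 and the in-train peak -> 1."""
    window = trace.window(t_stim_start, t_stim_end + grace_s)
    if window.size == 0:
        raise ValidationError("segment does not contain the stimulus window")
    baseline = trace.window(t_stim_start - baseline_window_s, t_stim_start)
    if baseline.size == 0:
        baseline = trace.values[trace.time < t_stim_start]
    if baseline.size == 0:
        raise ValidationError("no pre-stimulus frames for the baseline")
    b = float(baseline.mean())
    peak = float(window.max())
    if peak <= b:
        raise ValidationError(f"non-responding segment: peak ({peak:.4g}) <= baseline ({b:.4g})")
    return trace.copy_with((trace.values - b) / (peak - b), normalization="peak")


def segment_rounds(
    trace: FluorescenceTrace,
    protocol: StimulusProtocol,
    grace_s: float = GRACE_S,
    baseline_window_s: float = BASELINE_WINDOW_S,
) -> List[RoundResponse]:
    """One RoundResponse per declared stimulus round.

    Peak = maximum within [stim start, stim end + grace]; baseline_pre =
    mean over the final quiet ``baseline_window_s`` seconds before the round.
    """
    windows = protocol.round_windows()
    if not windows:
        raise ProtocolError("protocol declares no stimulus rounds")
    if windows[-1][1] > trace.time[-1] + 1e-9:
        raise ValidationError("protocol rounds extend beyond the trace span")
    t = trace.time
    out = []
    for k, (a, b) in enumerate(windows, start=1):
        m = (t >= a) & (t < b + grace_s)
        if not m.any():
            raise ValidationError(f"round {k} window contains no frames")
        i_peak = np.flatnonzero(m)[np.argmax(trace.values[m])]
        base = trace.window(a - baseline_window_s, a)
        if base.size == 0:
            base = trace.values[t < a]
        if base.size == 0:
            raise ValidationError(f"round {k}: no pre-round frames for the baseline")
        out.append(
            RoundResponse(
                round_index=k,
                t_stim_start=a,
                t_stim_end=b,
                peak_value=float(trace.values[i_peak]),
                t_peak=float(t[i_peak]),
                baseline_pre=float(base.mean()),
            )
        )
    return out


def _exp_decay(t, amplitude, tau, offset):
    return amplitude * np.exp(-t / tau) + offset


def fit_decay_tau(
    trace: FluorescenceTrace,
    t_peak: float,
    fit_end_s: Optional[float] = None,
    min_points: int = MIN_FIT_POINTS,
) -> TauFit:
    """Least-squares single-exponential fit of the post-peak decay.

    Fits F(t) = A exp(-(t - t_peak)/tau) + C on [t_peak, fit_end_s) and
    returns tau with diagnostics. Raises FitError on flat segments,
    non-convergence, or tau pinned at a bound.
    """
    end = trace.time[-1] + trace.frame_interval if fit_end_s is None else fit_end_s
    m = (trace.time >= t_peak) & (trace.time < end)
    t = trace.time[m] - t_peak
    y = trace.values[m]
    if t.size < min_points:
        raise FitError(f"too few post-peak samples for a decay fit ({t.size} < {min_points})")
    span = float(y.max() - y.min())
    if span <= 0 or span < 1e-12 * max(1.0, abs(float(y.max()))):
        raise FitError("flat segment: no decay to fit", {"span": span})
    tau_hi = 50.0 * (t[-1] - t[0] + 1e-9)
    p0 = (y[0] - y[-1], max((t[-1] - t[0]) / 3.0, 1e-3), y[-1])
    try:
        popt, _ = curve_fit(
            _exp_decay,
            t,
            y,
            p0=p0,
            bounds=([-np.inf, 1e-4, -np.inf], [np.inf, tau_hi, np.inf]),
            maxfev=5000,
        )
    except (RuntimeError, ValueError) as exc:
        raise FitError(f"decay fit did not converge: {exc}", {"n_points": t.size}) from exc
    amplitude, tau, offset = (float(v) for v in popt)
    resid = y - _exp_decay(t, *popt)
    resid_norm = float(np.sqrt(np.mean(resid**2)))
    if tau >= 0.99 * tau_hi or tau <= 1.5e-4:
        raise FitError(
            f"fitted tau {tau:.4g}s pinned at a bound",
            {"tau": tau, "bound": tau_hi, "resid_norm": resid_norm},
        )
    return TauFit(tau=tau, amplitude=amplitude, offset=offset, resid_norm=resid_norm, converged=True, n_points=t.size)


def compute_eb(
    trace: FluorescenceTrace,
    rnd: RoundResponse,
    tau_ref: float,
    probe_halfwidth_frames: int = PROBE_HALFWIDTH_FRAMES,
    clamp: bool = True,
) -> float:
    """Endocytic block (%) of one round: signal remaining at t_peak + 3*tau_ref.

    EB = 100 * (F(probe) - baseline_pre) / (peak - baseline_pre), with the
    probe read as a mean over +/- ``probe_halfwidth_frames`` frames. Values
    above 100 (post-stimulus rise) are clamped to 100 with a warning;
    values below 0 are clamped to 0.
    """
    if tau_ref <= 0:
        raise ValidationError("tau_ref must be > 0")
    t_probe = rnd.t_peak + 3.0 * tau_ref
    if t_probe > trace.time[-1] + 1e-9:
        raise ValidationError(
            f"EB probe time {t_probe:.1f}s lies beyond the trace end ({trace.time[-1]:.1f}s)"
        )
    i = int(np.argmin(np.abs(trace.time - t_probe)))
    lo = max(i - probe_halfwidth_frames, 0)
    hi = min(i + probe_halfwidth_frames + 1, len(trace))
    probe = float(trace.values[lo:hi].mean())
    amp = rnd.amplitude
    if amp <= 0:
        raise ValidationError(f"round {rnd.round_index}: non-positive exocytic amplitude")
    eb = 100.0 * (probe - rnd.baseline_pre) / amp
    if clamp:
        if eb > 100.0:
            warnings.warn(
                f"round {rnd.round_index}: EB {eb:.1f}% > 100% (post-stimulus rise); clamped",
                stacklevel=2,
            )
            eb = 100.0
        eb = max(eb, 0.0)
    return eb


def endurance_rounds(
    eb_series: Sequence[float],
    threshold: float = 50.0,
    max_rounds: int = 30,
) -> EnduranceResult:
    """Rounds-to-block with right censoring.

    rounds_to_block is the 1-based index of the first EB strictly exceeding
    ``threshold``; if none does, the neuron is censored and contributes
    ``max_rounds``.
    """
    eb = list(float(e) for e in eb_series)
    if not eb:
        raise ValidationError("eb_series is empty")
    if len(eb) > max_rounds:
        raise ValidationError(f"eb_series length {len(eb)} exceeds max_rounds {max_rounds}")
    bad = [e for e in eb if not 0.0 <= e <= 100.0]
    if bad:
        raise ValidationError(f"EB values outside [0, 100] after clamping: {bad[:3]}")
    for k, e in enumerate(eb, start=1):
        if e > threshold:
            return EnduranceResult(k, censored=False, max_rounds=max_rounds, eb_series=eb, threshold=threshold)
    return EnduranceResult(max_rounds, censored=True, max_rounds=max_rounds, eb_series=eb, threshold=threshold)


@dataclass
class EnduranceAnalysis:
    """Per-neuron result bundle of the full endurance analysis."""

    tau_ref: TauFit
    rounds: List[RoundResponse]
    endurance: EnduranceResult
    normalized: FluorescenceTrace


def analyze_endurance_trace(
    trace: FluorescenceTrace,
    protocol: StimulusProtocol,
    eb_threshold: float = 50.0,
    max_rounds: Optional[int] = None,
    grace_s: float = GRACE_S,
) -> EnduranceAnalysis:
    """Full per-neuron pipeline: pool normalization (when an NH4Cl epoch is
    declared), tau_ref fit on the reference round, per-round EB, endurance."""
    norm = normalize_to_total_pool(trace, protocol) if protocol.nh4cl_epoch is not None else trace

    ref = protocol.reference_window()
    if ref is not None:
        a, b = ref
        fit_end = protocol.round_windows()[0][0] - BASELINE_WINDOW_S if protocol.rounds else None
    else:
        a, b = protocol.round_windows()[0]
        fit_end = a + protocol.inter_round_interval - BASELINE_WINDOW_S
    seg = norm.slice(max(a - BASELINE_WINDOW_S, norm.time[0]), fit_end if fit_end is not None else norm.time[-1])
    win = (norm.time >= a) & (norm.time < b + grace_s)
    if not win.any():
        raise ValidationError("reference train window contains no frames")
    i_peak = np.flatnonzero(win)[np.argmax(norm.values[win])]
    tau_fit = fit_decay_tau(norm, float(norm.time[i_peak]), fit_end_s=fit_end)

    rounds = segment_rounds(norm, protocol, grace_s=grace_s)
    eb_series = []
    for rnd in rounds:
        rnd.tau = tau_fit.tau
        rnd.eb_percent = compute_eb(norm, rnd, tau_fit.tau)
        eb_series.append(rnd.eb_percent)
    max_r = protocol.rounds if max_rounds is None else max_rounds
    result = endurance_rounds(eb_series, threshold=eb_threshold, max_rounds=max_r)
    return EnduranceAnalysis(tau_ref=tau_fit, rounds=rounds, endurance=result, normalized=norm)
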
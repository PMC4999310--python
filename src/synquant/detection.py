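"""Evoked-EPSC detection, kinetics and charge measurement.

Detection follows the threshold-crossing scheme used for stimulus-locked
events: the baseline is the mean of a pre-stimulus window, the detection
threshold is k times the baseline noise SD (k in [2, 4]), the deflection
must reach threshold within the onset time limit (2 ms) after the stimulus
and peak within the peak time limit (3 ms) after crossing threshold;
otherwise the trial is a failure. Event onset is defined by back-projecting
the 10-90% rise slope line to the baseline level — the trace-based analogue
of drawing a tangent through the rising phase. All level crossings are
linearly interpolated between samples.
"""

from __future__ import annotations

import numpy as np

from synquant.types import EPSCEvent, EPSCTrace

__all__ = [
    "estimate_noise_sd",
    "detect_epsc",
    "measure_kinetics",
    "integrate_charge",
    "epoch_stability",
    "analyze_trace",
]

MIN_BASELINE_SAMPLES = 50


def _baseline_slice(trace: EPSCTrace, window_ms: tuple[float, float]) -> slice:
    lo, hi = window_ms
    if hi > trace.stimulus_time_ms:
        raise ValueError("baseline window must precede the stimulus")
    i0 = int(np.searchsorted(trace.time_ms, lo, side="left"))
    i1 = int(np.searchsorted(trace.time_ms, hi, side="right"))
    if i0 >= len(trace.time_ms) or i1 <= i0:
        raise ValueError("baseline window lies outside the trace")
    return slice(i0, i1)


def estimate_noise_sd(
    trace: EPSCTrace, baseline_window_ms: tuple[float, float] | None = None
) -> float:
    """SD of the baseline current after subtracting the window mean.

    The window must precede the stimulus and contain at least 50 samples.
    Defaults to everything before the stimulus.
    """
    if baseline_window_ms is None:
        baseline_window_ms = (trace.time_ms[0], trace.stimulus_time_ms)
    sl = _baseline_slice(trace, baseline_window_ms)
    seg = trace.current_pa[sl]
    if len(seg) < MIN_BASELINE_SAMPLES:
        raise ValueError(
            f"baseline window holds {len(seg)} samples; "
            f">= {MIN_BASELINE_SAMPLES} required"
        )
    return float(np.std(seg - np.mean(seg), ddof=1))


def _interp_crossing(t0, t1, y0, y1, level):
    """Time at which the line through (t0,y0),(t1,y1) reaches level."""
    if y1 == y0:
        return t0
    return t0 + (level - y0) * (t1 - t0) / (y1 - y0)


def _rise_times(t, deflection, i_peak, amplitude, i_start):
    """Interpolated 10% and 90% crossing times on the rising phase."""
    lo, hi = 0.1 * amplitude, 0.9 * amplitude
    t10 = t90 = None
    for j in range(i_peak, i_start, -1):
        if t90 is None and deflection[j - 1] < hi <= deflection[j]:
            t90 = _interp_crossing(t[j - 1], t[j], deflection[j - 1],
                                   deflection[j], hi)
        if deflection[j - 1] < lo <= deflection[j]:
            t10 = _interp_crossing(t[j - 1], t[j], deflection[j - 1],
                                   deflection[j], lo)
            break
    return t10, t90


def detect_epsc(
    trace: EPSCTrace,
    k_threshold: float = 3.0,
    onset_limit_ms: float = 2.0,
    peak_limit_ms: float = 3.0,
    baseline_window_ms: tuple[float, float] | None = None,
) -> EPSCEvent:
    """Detect the first evoked EPSC after the stimulus, or return a failure.

    The first excursion beyond ``k_threshold`` x noise SD below baseline is
    searched within ``onset_limit_ms`` after the stimulus; the peak must
    follow within ``peak_limit_ms`` of the threshold crossing. Events
    violating either limit — and trials with no crossing at all — are
    returned as failure events.
    """
    if not 2.0 <= k_threshold <= 4.0:
        raise ValueError(f"k_threshold must be in [2, 4], got {k_threshold}")
    if baseline_window_ms is None:
        baseline_window_ms = (trace.time_ms[0], trace.stimulus_time_ms)
    sl = _baseline_slice(trace, baseline_window_ms)
    baseline = float(np.mean(trace.current_pa[sl]))
    noise_sd = estimate_noise_sd(trace, baseline_window_ms)

    t = trace.time_ms
    deflection = baseline - trace.current_pa  # positive for inward EPSCs
    threshold = k_threshold * noise_sd

    i_stim = int(np.searchsorted(t, trace.stimulus_time_ms, side="left"))
    i_limit = int(np.searchsorted(
        t, trace.stimulus_time_ms + onset_limit_ms, side="right"))
    above = np.flatnonzero(deflection[i_stim:i_limit] > threshold)
    if len(above) == 0:
        return EPSCEvent(is_failure=True)
    i_thr = i_stim + int(above[0])
    t_thr = t[i_thr]

    # peak: largest deflection within the peak window after the crossing
    i_peak_limit = int(np.searchsorted(t, t_thr + peak_limit_ms, side="right"))
    i_peak = i_thr + int(np.argmax(deflection[i_thr:i_peak_limit]))
    # reject if the deflection is still growing at the window edge
    if i_peak == i_peak_limit - 1 and i_peak_limit < len(t) \
            and deflection[i_peak_limit] > deflection[i_peak]:
        return EPSCEvent(is_failure=True)
    amplitude = float(deflection[i_peak])

    t10, t90 = _rise_times(t, deflection, i_peak, amplitude, i_stim)
    if t10 is None or t90 is None or t90 <= t10:
        onset = t_thr  # degenerate rise; fall back to the crossing time
    else:
        # back-project the 10-90% slope line to the baseline level
        onset = t10 - 0.125 * (t90 - t10)
    onset = max(onset, trace.stimulus_time_ms)

    return EPSCEvent(
        is_failure=False,
        onset_ms=float(onset),
        peak_ms=float(t[i_peak]),
        amplitude_pa=amplitude,
    )


def measure_kinetics(trace: EPSCTrace, event: EPSCEvent,
                     baseline_window_ms: tuple[float, float] | None = None
                     ) -> EPSCEvent:
    """Complete latency, 10-90% rise and 37%-decay times of a detected event.

    - latency: event onset minus stimulus time;
    - rise_10_90: interval between the interpolated 10% and 90% amplitude
      crossings on the rising phase;
    - decay_37: interval from the peak until the current magnitude first
      relaxes to 37% of the peak (interpolated); if the trace ends first the
      event is flagged right-censored and decay is reported missing.
    """
    if event.is_failure:
        raise ValueError("cannot measure kinetics of a failure event")
    if baseline_window_ms is None:
        baseline_window_ms = (trace.time_ms[0], trace.stimulus_time_ms)
    sl = _baseline_slice(trace, baseline_window_ms)
    baseline = float(np.mean(trace.current_pa[sl]))
    t = trace.time_ms
    deflection = baseline - trace.current_pa
    i_peak = int(np.searchsorted(t, event.peak_ms, side="left"))
    amplitude = float(event.amplitude_pa)
    i_stim = int(np.searchsorted(t, trace.stimulus_time_ms, side="left"))

    t10, t90 = _rise_times(t, deflection, i_peak, amplitude, i_stim)
    rise = (t90 - t10) if (t10 is not None and t90 is not None) else None

    level = 0.37 * amplitude
    decay = None
    censored = True
    for j in range(i_peak + 1, len(t)):
        if deflection[j] <= level:
            t_cross = _interp_crossing(t[j - 1], t[j], deflection[j - 1],
                                       deflection[j], level)
            decay = t_cross - t[i_peak]
            censored = False
            break

    event.latency_ms = float(event.onset_ms - trace.stimulus_time_ms)
    event.rise_10_90_ms = float(rise) if rise is not None else None
    event.decay_37_ms = float(decay) if decay is not None else None
    event.decay_censored = censored
    return event


def integrate_charge(
    trace: EPSCTrace,
    event: EPSCEvent,
    max_window_ms: float = 50.0,
    baseline_window_ms: tuple[float, float] | None = None,
) -> float:
    """Trapezoidal charge of a detected event, in fC (1 pA*ms = 1 fC).

    Integrates the baseline-subtracted current magnitude from the event
    onset until the current first returns within one noise SD of baseline
    after the peak, or ``max_window_ms`` after onset, whichever comes first.
    """
    if event.is_failure:
        raise ValueError("cannot integrate the charge of a failure event")
    if baseline_window_ms is None:
        baseline_window_ms = (trace.time_ms[0], trace.stimulus_time_ms)
    sl = _baseline_slice(trace, baseline_window_ms)
    baseline = float(np.mean(trace.current_pa[sl]))
    noise_sd = estimate_noise_sd(trace, baseline_window_ms)

    t = trace.time_ms
    deflection = baseline - trace.current_pa
    i_on = int(np.searchsorted(t, event.onset_ms, side="left"))
    i_end = int(np.searchsorted(t, event.onset_ms + max_window_ms,
                                side="right"))
    if noise_sd > 0 and event.peak_ms is not None:
        i_peak = int(np.searchsorted(t, event.peak_ms, side="left"))
        back = np.flatnonzero(deflection[i_peak:i_end] <= noise_sd)
        if len(back):
            i_end = i_peak + int(back[0]) + 1
    seg = np.clip(deflection[i_on:i_end], 0.0, None)
    return float(np.trapezoid(seg, t[i_on:i_end]))


def epoch_stability(
    charges_fc: np.ndarray, trial_times_s: np.ndarray,
    max_slope: float = 0.05,
) -> tuple[float, bool]:
    """Normalized drift slope of an epoch and its stability verdict.

    Fits an ordinary least-squares line of charge / (epoch mean charge)
    against time / (epoch duration); the epoch is stable iff the absolute
    slope is strictly below ``max_slope`` (< 5% drift per epoch).
    """
    charges = np.asarray(charges_fc, dtype=float)
    times = np.asarray(trial_times_s, dtype=float)
    if len(charges) < 10:
        raise ValueError("epoch stability needs >= 10 trials")
    mean = charges.mean()
    if mean == 0:
        raise ValueError("epoch mean charge is zero")
    duration = times[-1] - times[0]
    if duration <= 0:
        raise ValueError("epoch duration must be positive")
    x = (times - times[0]) / duration
    y = charges / mean
    slope = float(np.polyfit(x, y, 1)[0])
    # strict inequality: a slope at the boundary (within float rounding)
    # fails the screen
    at_boundary = np.isclose(abs(slope), max_slope, rtol=1e-9, atol=1e-12)
    return slope, bool(abs(slope) < max_slope and not at_boundary)


def analyze_trace(
    trace: EPSCTrace,
    k_threshold: float = 3.0,
    onset_limit_ms: float = 2.0,
    peak_limit_ms: float = 3.0,
    max_window_ms: float = 50.0,
) -> EPSCEvent:
    """Detect, measure and integrate one trace in a single call."""
    event = detect_epsc(trace, k_threshold, onset_limit_ms, peak_limit_ms)
    if event.is_failure:
        return event
    event = measure_kinetics(trace, event)
    event.charge_fc = integrate_charge(trace, event, max_window_ms)
    return event
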
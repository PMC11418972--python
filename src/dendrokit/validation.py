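"""Semi-automated electrophysiological validation protocols.

Every protocol is a pure function of voltage traces plus the stimulus
metadata the user supplies: input resistance and sag ratio from step
responses, membrane time constant from a double-exponential fit, spike
metrics via peak detection, f–I curve and rheobase from repeated step
simulations, voltage attenuation profiles, and dendritic input-integration
nonlinearity (expected vs. actual EPSP amplitudes).

Protocols that need repeated simulations (`f_i_curve`,
`dendritic_nonlinearity`) take a ``simulate`` callable so they stay
independent of how the model is built and run.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit
from scipy.signal import find_peaks

STEADY_SLOPE_TOL = 1e-3  # mV/ms; above this the final window is not steady


@dataclass
class SpikeMetrics:
    peak_times: np.ndarray   # ms
    peak_values: np.ndarray  # mV
    amplitudes: np.ndarray   # mV, peak minus preceding local minimum
    half_widths: np.ndarray  # ms at half amplitude
    rate: float              # Hz over the analysis window
    isis: np.ndarray         # ms

    @property
    def n_spikes(self) -> int:
        return len(self.peak_times)


@dataclass
class PassiveReadouts:
    Rin: float | None = None          # MΩ
    tau_m: float | None = None        # ms
    attenuation: list = field(default_factory=list)  # (distance µm, ratio)
    sag_ratio: float | None = None
    steady_state_Rin: float | None = None


@dataclass
class CurveResult:
    amplitudes: np.ndarray | None = None  # nA (f–I) or weights (nonlinearity)
    rates: np.ndarray | None = None       # Hz
    rheobase: float | None = None         # nA
    expected: np.ndarray | None = None    # mV
    actual: np.ndarray | None = None      # mV
    waveforms: list = field(default_factory=list)


def _window_mean(t, v, t0, t1):
    # half-open [t0, t1): the sample at a step edge belongs to the next epoch
    m = (t >= t0) & (t < t1)
    if not m.any():
        raise ValueError(f"empty analysis window [{t0}, {t1}) ms")
    return float(np.mean(v[m])), m


def input_resistance(t, v, i_ext: float, delay: float, duration: float,
                     window_fraction: float = 0.1) -> float:
    """Rin = (V_offset − V_onset)/I_ext in MΩ (mV / nA = MΩ).

    V_onset averages the last ``window_fraction`` of the pre-stimulus epoch,
    V_offset the last fraction of the stimulus epoch.  Warns when the final
    window has not reached steady state.
    """
    import warnings
    if i_ext == 0:
        raise ValueError("input resistance undefined for I_ext = 0")
    t = np.asarray(t, dtype=float)
    v = np.asarray(v, dtype=float)
    v_on, _ = _window_mean(t, v, delay * (1 - window_fraction), delay)
    t_end = delay + duration
    v_off, m = _window_mean(t, v, t_end - window_fraction * duration, t_end)
    tw, vw = t[m], v[m]
    if len(tw) > 2:
        slope = np.polyfit(tw, vw, 1)[0]
        if abs(slope) > STEADY_SLOPE_TOL:
            warnings.warn(f"no steady state: |dV/dt| = {abs(slope):.2g} mV/ms "
                          "over the final window", stacklevel=2)
    return (v_off - v_on) / i_ext


def membrane_time_constant(t, v, delay: float, fit_duration: float = None) -> float:
    """Slowest component of a double-exponential fit to the onset transient.

    Fits V(t) = V∞ + A1·exp(−t/τ1) + A2·exp(−t/τ2) on the stretch after the
    stimulus onset and returns max(τ1, τ2) in ms.  Intended for a
    hyperpolarizing step with h-current blocked.
    """
    t = np.asarray(t, dtype=float)
    v = np.asarray(v, dtype=float)
    m = t >= delay
    if fit_duration is not None:
        m &= t <= delay + fit_duration
    tt, vv = t[m] - delay, v[m]
    if len(tt) < 8 or np.ptp(vv) < 1e-9:
        raise ValueError("trace is flat after onset; cannot fit a time constant")
    dv = vv[-1] - vv[0]
    span = max(tt[-1] / 5.0, 1e-3)

    def dexp(x, vinf, a1, tau1, a2, tau2):
        return vinf + a1 * np.exp(-x / tau1) + a2 * np.exp(-x / tau2)

    p0 = [vv[-1], -0.7 * dv, span, -0.3 * dv, span / 10.0]
    try:
        p, _ = curve_fit(dexp, tt, vv, p0=p0,
                         bounds=([-200, -200, 1e-4, -200, 1e-4],
                                 [100, 200, 1e4, 200, 1e4]), maxfev=20000)
    except RuntimeError as exc:
        resid = float(np.sqrt(np.mean((dexp(tt, *p0) - vv) ** 2)))
        raise RuntimeError(f"double-exponential fit failed ({exc}); "
                           f"initial-guess RMS residual {resid:.3g} mV") from None
    return float(max(p[2], p[4]))


def detect_spikes(t, v, min_height: float = 0.0, min_distance: float = 1.0,
                  window: tuple | None = None) -> SpikeMetrics:
    """Peak detection with amplitude and interpolated half-width per spike.

    Amplitude is measured from the preceding local minimum to the peak;
    half-width is the time between the half-amplitude crossings around the
    peak, linearly interpolated.  Peaks closer than ``min_distance`` ms keep
    only the higher one.
    """
    t = np.asarray(t, dtype=float)
    v = np.asarray(v, dtype=float)
    dt = float(np.median(np.diff(t))) if len(t) > 1 else 1.0
    dist = max(1, int(round(min_distance / dt)))
    peaks, _ = find_peaks(v, height=min_height, distance=dist)
    times, vals, amps, widths = [], [], [], []
    prev_peak = 0
    for p in peaks:
        base_lo = v[prev_peak:p + 1].min() if p > prev_peak else v[p]
        amp = v[p] - base_lo
        half = v[p] - amp / 2.0
        i = p
        while i > 0 and v[i - 1] > half:
            i -= 1
        t_left = t[i] if i == 0 else np.interp(half, [v[i - 1], v[i]], [t[i - 1], t[i]])
        j = p
        while j < len(v) - 1 and v[j + 1] > half:
            j += 1
        t_right = t[j] if j == len(v) - 1 else \
            np.interp(half, [v[j + 1], v[j]], [t[j + 1], t[j]])
        # parabolic refinement of the peak time (sub-sample precision)
        if 0 < p < len(v) - 1:
            denom = v[p - 1] - 2.0 * v[p] + v[p + 1]
            shift = 0.5 * (v[p - 1] - v[p + 1]) / denom if denom != 0 else 0.0
            times.append(t[p] + np.clip(shift, -0.5, 0.5) * dt)
        else:
            times.append(t[p])
        vals.append(v[p])
        amps.append(amp)
        widths.append(t_right - t_left)
        prev_peak = p
    times = np.asarray(times)
    if window is None:
        window = (t[0], t[-1]) if len(t) else (0.0, 1.0)
    in_win = (times >= window[0]) & (times < window[1])
    dur_s = (window[1] - window[0]) / 1000.0
    rate = float(in_win.sum() / dur_s) if dur_s > 0 else 0.0
    return SpikeMetrics(peak_times=times, peak_values=np.asarray(vals),
                        amplitudes=np.asarray(amps), half_widths=np.asarray(widths),
                        rate=rate, isis=np.diff(times))


def f_i_curve(simulate, start: float, stop: float, step: float,
              delay: float, duration: float, min_height: float = 0.0,
              refine_rheobase: bool = True) -> CurveResult:
    """Firing rate vs injected step amplitude, plus the rheobase.

    ``simulate(amplitude_nA) -> (t, v)`` runs one trial.  Spikes are counted
    within the stimulus window only.  Rheobase is the smallest amplitude
    with >= 1 spike, refined by bisection to step/8; None when nothing
    spikes.
    """
    if step <= 0:
        raise ValueError("step must be > 0")
    amps = np.arange(start, stop + step / 2.0, step)
    rates = []
    first_spiking = None
    for a in amps:
        t, v = simulate(a)
        sm = detect_spikes(t, v, min_height=min_height,
                           window=(delay, delay + duration))
        rates.append(sm.rate)
        if first_spiking is None and sm.rate > 0:
            first_spiking = a
    rheo = first_spiking
    if rheo is not None and refine_rheobase and rheo > start:
        lo, hi = rheo - step, rheo
        while hi - lo > step / 8.0:
            mid = (lo + hi) / 2.0
            t, v = simulate(mid)
            sm = detect_spikes(t, v, min_height=min_height,
                               window=(delay, delay + duration))
            if sm.n_spikes >= 1:
                hi = mid
            else:
                lo = mid
        rheo = hi
    return CurveResult(amplitudes=amps, rates=np.asarray(rates), rheobase=rheo)


def attenuation_profile(t, v_stim, probes: list, delay: float, duration: float,
                        window_fraction: float = 0.1) -> list:
    """Steady-state ΔV_seg/ΔV_stim at each probe vs its path distance.

    ``probes`` is a list of ``(distance_um, v_trace)``; the stimulus-site
    trace ``v_stim`` defines the denominator.  Ratios use the same windows
    as :func:`input_resistance`.
    """
    t = np.asarray(t, dtype=float)
    t_end = delay + duration

    def delta(v):
        v = np.asarray(v, dtype=float)
        v_on, _ = _window_mean(t, v, delay * (1 - window_fraction), delay)
        v_off, _ = _window_mean(t, v, t_end - window_fraction * duration, t_end)
        return v_off - v_on

    d_stim = delta(v_stim)
    if abs(d_stim) < 1e-12:
        raise ValueError("no voltage change at the stimulation site")
    return [(float(d), delta(v) / d_stim) for d, v in probes]


def dendritic_nonlinearity(simulate, weights, delay: float = 0.0,
                           baseline_window: float | None = None) -> CurveResult:
    """Expected vs actual EPSP peak for increasing synaptic weight.

    ``simulate(weight) -> (t, v)`` activates the synapse(s) scaled by an
    integer weight.  The unitary response is weight 1; expected(k) is
    k times the unitary peak; actual(k) is measured.  Raises when the
    unitary EPSP is below the noise floor.
    """
    weights = np.asarray(list(weights))
    actual, wave = [], []
    t_ref = None
    for k in weights:
        t, v = simulate(k)
        t = np.asarray(t, dtype=float)
        v = np.asarray(v, dtype=float)
        m = t >= delay
        base = float(v[m][0])
        actual.append(float(np.max(v[m]) - base))
        wave.append(v)
        t_ref = t
    actual = np.asarray(actual)
    unit = actual[np.argmin(np.abs(weights - 1))] if (weights == 1).any() else actual[0] / weights[0]
    if unit <= 1e-9:
        raise ValueError("unitary EPSP below noise floor")
    expected = weights * unit
    return CurveResult(amplitudes=weights.astype(float), expected=expected,
                       actual=actual, waveforms=[(t_ref, w) for w in wave])


def sag_ratio(t, v, delay: float, duration: float,
              window_fraction: float = 0.1) -> float:
    """Sag ratio a/b with a = V_offset − V_min and b = V_onset − V_min.

    V_onset is the pre-step baseline, V_min the minimum during the step,
    V_offset the end-of-step voltage.  Raises when the step does not
    hyperpolarize (b <= 0).
    """
    t = np.asarray(t, dtype=float)
    v = np.asarray(v, dtype=float)
    v_on, _ = _window_mean(t, v, delay * (1 - window_fraction), delay)
    t_end = delay + duration
    v_off, _ = _window_mean(t, v, t_end - window_fraction * duration, t_end)
    m = (t >= delay) & (t <= t_end)
    v_min = float(np.min(v[m]))
    b = v_on - v_min
    if b <= 0:
        raise ValueError("no hyperpolarization during the step (b <= 0)")
    a = v_off - v_min
    return a / b
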
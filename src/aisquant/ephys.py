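"""Excitability feature extraction from patch-clamp sweep recordings.

Implements the standard somatic current-clamp analysis chain for cortical
pyramidal neurons: action-potential (AP) detection, voltage threshold (the
point where dV/dt first exceeds 50 V/s), amplitude and half-width, the
phase-plane decomposition into axonal (first) and somatic (second) dV/dt
peaks, rheobase from 20 ms step families, I-f curve slope analysis from
500 ms step families, passive properties (RMP, input resistance, series
resistance with the 30 MOhm exclusion rule), and spontaneous postsynaptic
current (PSC) detection by scaled-template matching.

Conventions: voltages in mV, currents in pA, resistances in MOhm, rates of
rise in V/s (numerically equal to mV/ms), times in seconds on a uniform
grid (50 kHz by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal, stats

__all__ = [
    "Sweep", "SweepSet", "APFeatures", "IFCurve", "PassiveProperties",
    "PSCSummary", "detect_aps", "voltage_threshold",
    "ap_amplitude_halfwidth", "phase_plane", "current_threshold",
    "if_curve", "passive_properties", "series_resistance", "detect_pscs",
    "extract_ap_features", "DVDT_THRESHOLD_VPS", "RS_EXCLUSION_MOHM",
]

#: dV/dt criterion defining the AP voltage threshold (V/s)
DVDT_THRESHOLD_VPS = 50.0
#: voltage an AP peak must exceed to count as a spike (mV)
AP_PEAK_FLOOR_MV = -10.0
#: recordings with series resistance above this are excluded (MOhm)
RS_EXCLUSION_MOHM = 30.0
#: minimum phase-plane peak prominence to resolve two components (V/s)
PHASE_PROMINENCE_VPS = 10.0


@dataclass
class Sweep:
    """One stimulus-step recording sharing the set's time base."""

    signal: np.ndarray          # mV (current clamp) or pA (voltage clamp)
    step_pA: float
    step_onset_s: float
    step_duration_s: float

    def __post_init__(self):
        self.signal = np.asarray(self.signal, dtype=float)


@dataclass
class SweepSet:
    """A family of step recordings on a common uniform time grid."""

    time_s: np.ndarray
    sweeps: list
    clamp_mode: str = "current"
    ljp_corrected: bool = False

    def __post_init__(self):
        self.time_s = np.asarray(self.time_s, dtype=float)
        dt = np.diff(self.time_s)
        if len(dt) and np.ptp(dt) > 1e-9 * dt.mean():
            raise ValueError("time base must be uniform")
        for sw in self.sweeps:
            if len(sw.signal) != len(self.time_s):
                raise ValueError("all sweeps must share the time base")
            if sw.step_onset_s < self.time_s[0] or \
                    sw.step_onset_s + sw.step_duration_s > self.time_s[-1] + 1e-12:
                raise ValueError("step window outside the sweep")
        if self.clamp_mode not in ("current", "voltage"):
            raise ValueError("clamp_mode must be 'current' or 'voltage'")

    @property
    def sample_rate_Hz(self) -> float:
        return 1.0 / (self.time_s[1] - self.time_s[0])

    @property
    def dt_s(self) -> float:
        return float(self.time_s[1] - self.time_s[0])

    def step_amplitudes(self) -> np.ndarray:
        return np.array([sw.step_pA for sw in self.sweeps])


@dataclass
class APFeatures:
    v_threshold_mV: float
    amplitude_mV: float
    half_width_ms: float
    peak_mV: float
    phase_peak1_Vps: float = np.nan
    phase_peak2_Vps: float = np.nan
    i_threshold_pA: float = np.nan
    phase_resolved: bool = True


@dataclass
class IFCurve:
    currents_pA: np.ndarray
    frequencies_Hz: np.ndarray
    f_prime_max_HzperpA: float
    i_at_f_prime_max_pA: float


@dataclass
class PassiveProperties:
    rmp_mV: float
    r_n_MOhm: float
    r_s_MOhm: float = np.nan
    r_s_excluded: bool = False


@dataclass
class PSCSummary:
    events: pd.DataFrame           # columns: time_s, amplitude_pA
    mean_amplitude_pA: float
    frequency_Hz: float


def _dvdt_Vps(time_s: np.ndarray, v_mV: np.ndarray) -> np.ndarray:
    """Centered finite-difference dV/dt in V/s (== mV/ms), one-sided at ends."""
    return np.gradient(v_mV, time_s) / 1000.0


def detect_aps(time_s, v_mV, peak_floor_mV=AP_PEAK_FLOOR_MV,
               dvdt_floor_Vps=DVDT_THRESHOLD_VPS, lookback_ms=2.0,
               refractory_ms=1.0):
    """Detect AP peak times in a current-clamp trace.

    A peak qualifies if the voltage exceeds ``peak_floor_mV`` and dV/dt
    exceeded ``dvdt_floor_Vps`` within the preceding ``lookback_ms``.
    Peaks closer than ``refractory_ms`` are merged (highest wins).
    Returns an array of peak times (possibly empty).
    """
    time_s = np.asarray(time_s, float)
    v = np.asarray(v_mV, float)
    dt = time_s[1] - time_s[0]
    dist = max(1, int(round(refractory_ms * 1e-3 / dt)))
    peaks, _ = signal.find_peaks(v, height=peak_floor_mV, distance=dist)
    if len(peaks) == 0:
        return np.empty(0)
    dvdt = _dvdt_Vps(time_s, v)
    nb = max(1, int(round(lookback_ms * 1e-3 / dt)))
    keep = [p for p in peaks if dvdt[max(0, p - nb):p + 1].max() >= dvdt_floor_Vps]
    return time_s[np.array(keep, dtype=int)] if keep else np.empty(0)


def voltage_threshold(time_s, v_mV, ap_peak_time_s,
                      dvdt_criterion_Vps=DVDT_THRESHOLD_VPS,
                      search_window_ms=5.0):
    """AP voltage threshold: first pre-peak sample where dV/dt >= criterion.

    Scans backward from the peak through the contiguous run of samples
    whose centered-difference dV/dt stays at or above the criterion and
    returns the voltage at the run's first sample.  Raises if dV/dt never
    reaches the criterion before the peak.
    """
    time_s = np.asarray(time_s, float)
    v = np.asarray(v_mV, float)
    dt = time_s[1] - time_s[0]
    ipk = int(np.argmin(np.abs(time_s - ap_peak_time_s)))
    i0 = max(0, ipk - int(round(search_window_ms * 1e-3 / dt)))
    dvdt = _dvdt_Vps(time_s, v)
    seg = dvdt[i0:ipk + 1]
    # tiny tolerance so an exact-criterion slope break is not lost to
    # floating-point rounding of the centered difference
    above = seg >= dvdt_criterion_Vps - 1e-6
    if not above.any():
        raise ValueError(
            f"dV/dt never reached {dvdt_criterion_Vps} V/s before the peak")
    # walk back from the peak to the start of the final suprathreshold run
    j = len(above) - 1
    while j > 0 and not above[j]:
        j -= 1
    while j > 0 and above[j - 1]:
        j -= 1
    return float(v[i0 + j])


def _interp_crossing(t0, t1, v0, v1, level):
    return t0 + (level - v0) / (v1 - v0) * (t1 - t0)


def ap_amplitude_halfwidth(time_s, v_mV, ap_peak_time_s, v_threshold_mV,
                           next_peak_time_s=None):
    """Amplitude (threshold to peak) and half-width of one AP.

    Half-width is the time between the rising and falling crossings of the
    mid voltage ``(threshold + peak) / 2``, with linear interpolation
    between samples.  Raises if the falling phase never re-crosses the mid
    voltage before the next AP, or if the AP is degenerate (peak <=
    threshold).
    """
    time_s = np.asarray(time_s, float)
    v = np.asarray(v_mV, float)
    ipk = int(np.argmin(np.abs(time_s - ap_peak_time_s)))
    peak = float(v[ipk])
    if peak <= v_threshold_mV:
        raise ValueError("degenerate AP: peak does not exceed threshold")
    amplitude = peak - v_threshold_mV
    v_mid = 0.5 * (v_threshold_mV + peak)

    i = ipk
    while i > 0 and v[i - 1] >= v_mid:
        i -= 1
    if i == 0:
        raise ValueError("rising phase never below mid voltage in trace")
    t_rise = _interp_crossing(time_s[i - 1], time_s[i], v[i - 1], v[i], v_mid)

    stop = len(v) - 1
    if next_peak_time_s is not None:
        stop = int(np.argmin(np.abs(time_s - next_peak_time_s)))
    j = ipk
    while j < stop and v[j + 1] > v_mid:
        j += 1
    if j >= stop:
        raise ValueError("falling phase never re-crosses the mid voltage")
    t_fall = _interp_crossing(time_s[j], time_s[j + 1], v[j], v[j + 1], v_mid)
    return amplitude, (t_fall - t_rise) * 1e3


def phase_plane(time_s, v_mV, ap_peak_time_s, window_before_ms=2.0,
                prominence_Vps=PHASE_PROMINENCE_VPS):
    """Rising-phase dV/dt peaks of one AP (axonal then somatic component).

    Returns ``(peak1_Vps, peak2_Vps, curve, resolved)`` where ``curve`` is
    a ``(v_mV, dvdt_Vps)`` tuple over the AP window.  With a single
    resolvable maximum both peaks are set to it and ``resolved`` is False;
    a monotone (e.g. triangular) upstroke reports its constant slope.
    """
    time_s = np.asarray(time_s, float)
    v = np.asarray(v_mV, float)
    dt = time_s[1] - time_s[0]
    ipk = int(np.argmin(np.abs(time_s - ap_peak_time_s)))
    i0 = max(0, ipk - int(round(window_before_ms * 1e-3 / dt)))
    if ipk - i0 < 3:
        raise ValueError("no AP window before the peak")
    dvdt = _dvdt_Vps(time_s, v)
    rise = dvdt[i0:ipk + 1]
    pk, _ = signal.find_peaks(rise, prominence=prominence_Vps)
    curve = (v[i0:ipk + 1].copy(), rise.copy())
    if len(pk) >= 2:
        return float(rise[pk[0]]), float(rise[pk[1]]), curve, True
    val = float(rise[pk[0]]) if len(pk) == 1 else float(rise.max())
    return val, val, curve, False


def extract_ap_features(sweepset: SweepSet, sweep_index=None) -> APFeatures:
    """Full waveform feature set from the first AP of a spiking sweep.

    If ``sweep_index`` is None the first sweep containing an AP is used
    (for a short-step family this is the rheobase sweep).
    """
    if sweep_index is None:
        for i, sw in enumerate(sweepset.sweeps):
            if len(detect_aps(sweepset.time_s, sw.signal)):
                sweep_index = i
                break
        else:
            raise ValueError("no sweep contains an AP")
    sw = sweepset.sweeps[sweep_index]
    peaks = detect_aps(sweepset.time_s, sw.signal)
    if len(peaks) == 0:
        raise ValueError("selected sweep contains no AP")
    t_pk = peaks[0]
    nxt = peaks[1] if len(peaks) > 1 else None
    v_thr = voltage_threshold(sweepset.time_s, sw.signal, t_pk)
    amp, hw = ap_amplitude_halfwidth(sweepset.time_s, sw.signal, t_pk, v_thr,
                                     next_peak_time_s=nxt)
    p1, p2, _, resolved = phase_plane(sweepset.time_s, sw.signal, t_pk)
    return APFeatures(v_threshold_mV=v_thr, amplitude_mV=amp,
                      half_width_ms=hw, peak_mV=v_thr + amp,
                      phase_peak1_Vps=p1, phase_peak2_Vps=p2,
                      phase_resolved=resolved)


def current_threshold(sweepset: SweepSet) -> float:
    """Rheobase from a short-step family: smallest step that reliably spikes.

    "Reliably" is operationalized as monotone persistence: the returned
    amplitude I* spikes and every recorded sweep with a larger amplitude
    also spikes.  Raises when no sweep spikes or when spiking is
    non-monotone with no qualifying step.
    """
    amps = sweepset.step_amplitudes()
    if np.any(np.diff(amps) <= 0):
        raise ValueError("step amplitudes must be strictly increasing")
    spiking = np.array([len(detect_aps(sweepset.time_s, sw.signal)) > 0
                        for sw in sweepset.sweeps])
    if not spiking.any():
        raise ValueError("no sweep elicited an AP; current threshold undefined")
    # smallest index from which spiking persists through the last sweep
    idx = np.flatnonzero(~spiking)
    first_persistent = 0 if len(idx) == 0 else idx[-1] + 1
    if first_persistent >= len(amps):
        raise ValueError(
            "non-monotone spiking: no step spikes reliably "
            f"(spiking pattern {spiking.astype(int).tolist()})")
    return float(amps[first_persistent])


def if_curve(sweepset: SweepSet) -> IFCurve:
    """Firing frequency vs injected current from a long-step family.

    Frequency is spike count over the step duration; the curve's slope is
    the centered discrete derivative at interior points, and the summary
    statistics are its maximum and the current at which it occurs (first
    occurrence on ties).
    """
    amps = sweepset.step_amplitudes()
    if len(amps) < 3:
        raise ValueError("I-f analysis needs at least 3 steps")
    freqs = np.empty(len(amps))
    for k, sw in enumerate(sweepset.sweeps):
        n = len(detect_aps(sweepset.time_s, sw.signal))
        freqs[k] = n / sw.step_duration_s
    fp = (freqs[2:] - freqs[:-2]) / (amps[2:] - amps[:-2])
    kmax = int(np.argmax(fp))
    return IFCurve(currents_pA=amps, frequencies_Hz=freqs,
                   f_prime_max_HzperpA=float(fp[kmax]),
                   i_at_f_prime_max_pA=float(amps[kmax + 1]))


def series_resistance(step_mV, current_trace_pA, baseline_n=None):
    """Series resistance from the capacitive transient of a voltage step.

    ``R_s = |step| / |peak transient current|`` where the peak is measured
    relative to the pre-step baseline (mean of the first ``baseline_n``
    samples, default 10% of the trace).
    """
    i = np.asarray(current_trace_pA, float)
    if baseline_n is None:
        baseline_n = max(1, len(i) // 10)
    base = i[:baseline_n].mean()
    peak = np.abs(i - base).max()
    if peak <= 0:
        raise ValueError("no capacitive transient in the current trace")
    # mV / pA = GOhm -> MOhm
    return abs(step_mV) / peak * 1000.0


def passive_properties(sweepset: SweepSet, break_in_trace_mV=None,
                       rs_step_mV=None, rs_current_trace_pA=None,
                       baseline_ms=50.0) -> PassiveProperties:
    """RMP, input resistance and (optionally) series resistance.

    * RMP: mean of the break-in trace at I = 0 if given, else the mean
      pre-step baseline across sweeps (holding current is zero).
    * R_N: least-squares slope of the steady-state V-I relation, using the
      mean of the last 20% of each step window; sweeps containing an AP
      are excluded (< 3 remaining raises).
    * R_s: from a -10 mV voltage-clamp step transient when provided;
      values above 30 MOhm only set the exclusion flag.
    """
    t = sweepset.time_s
    dt = sweepset.dt_s
    vs, cs, baselines = [], [], []
    for sw in sweepset.sweeps:
        i_on = int(round((sw.step_onset_s - t[0]) / dt))
        i_off = int(round((sw.step_onset_s + sw.step_duration_s - t[0]) / dt))
        nb = int(round(baseline_ms * 1e-3 / dt))
        baselines.append(sw.signal[max(0, i_on - nb):i_on].mean())
        if len(detect_aps(t, sw.signal)):
            continue  # suprathreshold sweep: excluded from the V-I fit
        n_ss = max(1, int(0.2 * (i_off - i_on)))
        vs.append(sw.signal[i_off - n_ss:i_off].mean())
        cs.append(sw.step_pA)
    if len(vs) < 3:
        raise ValueError("fewer than 3 AP-free subthreshold steps")
    slope = stats.linregress(cs, vs).slope  # mV/pA = GOhm
    r_n = slope * 1000.0
    if r_n <= 0:
        raise ValueError("non-positive input resistance fit")
    rmp = float(np.mean(break_in_trace_mV)) if break_in_trace_mV is not None \
        else float(np.mean(baselines))
    r_s = np.nan
    excluded = False
    if rs_step_mV is not None and rs_current_trace_pA is not None:
        r_s = series_resistance(rs_step_mV, rs_current_trace_pA)
        excluded = r_s > RS_EXCLUSION_MOHM
    return PassiveProperties(rmp_mV=rmp, r_n_MOhm=float(r_n),
                             r_s_MOhm=float(r_s), r_s_excluded=excluded)


def _biexp_template(rise_ms, decay_ms, dt_s, n=None):
    """Unit-peak biexponential kernel (negative-going, inward current)."""
    if n is None:
        n = int(round((rise_ms + 5 * decay_ms) * 1e-3 / dt_s))
    tt = np.arange(n) * dt_s * 1e3  # ms
    w = np.exp(-tt / decay_ms) - np.exp(-tt / rise_ms)
    return -w / w.max()


def detect_pscs(time_s, current_pA, duration_s=None, rise_ms=0.5,
                decay_ms=5.0, criterion=3.0) -> PSCSummary:
    """Spontaneous PSC detection by scaled-template (Clements-Bekkers) matching.

    A unit-peak biexponential template is fit (scale + offset, least
    squares) at every lag of the trace; the detection criterion is the
    fitted scale divided by its standard error, thresholded at
    ``criterion``.  Events closer than one rise time are merged (largest
    criterion wins).  Amplitudes are the fitted peak magnitudes (positive,
    for inward/negative-going events); frequency is count over the
    recording duration.
    """
    time_s = np.asarray(time_s, float)
    x = np.asarray(current_pA, float)
    if duration_s is None:
        duration_s = time_s[-1] - time_s[0] + (time_s[1] - time_s[0])
    if duration_s <= 0:
        raise ValueError("recording duration must be positive")
    dt = time_s[1] - time_s[0]
    w = _biexp_template(rise_ms, decay_ms, dt)
    L = len(w)
    if L >= len(x):
        raise ValueError("trace shorter than the detection template")
    sw, sww = w.sum(), (w * w).sum()
    ssw = sww - sw * sw / L
    ones = np.ones(L)
    # sliding sums via correlation (valid lags)
    sx = np.correlate(x, ones, mode="valid")
    sxx = np.correlate(x * x, ones, mode="valid")
    swx = signal.fftconvolve(x, w[::-1], mode="valid")
    scale = (swx - sw * sx / L) / ssw
    sse = np.maximum(sxx - sx * sx / L - scale * scale * ssw, 0.0)
    # Clements-Bekkers criterion: fitted scale over the residual SD, i.e.
    # an SNR-like measure (not a t statistic).  The floor keeps noiseless
    # traces from flagging machine-epsilon event tails.
    floor = 1e-3 * np.abs(x - np.median(x)).max()
    se = np.sqrt(sse / (L - 1) + floor * floor)
    dc = scale / se
    # one candidate per contiguous suprathreshold region of the criterion
    above = dc >= criterion
    edges = np.diff(above.astype(np.int8))
    starts = np.flatnonzero(edges == 1) + 1
    ends = np.flatnonzero(edges == -1) + 1
    if above[0]:
        starts = np.concatenate([[0], starts])
    if above[-1]:
        ends = np.concatenate([ends, [len(above)]])
    cands = [s + int(np.argmax(dc[s:e])) for s, e in zip(starts, ends)]
    min_sep = max(1, int(round(rise_ms * 1e-3 / dt)))
    locs = []
    for c in cands:  # merge candidates closer than one rise time
        if locs and c - locs[-1] < min_sep:
            if dc[c] > dc[locs[-1]]:
                locs[-1] = c
        else:
            locs.append(c)
    locs = np.array(locs, dtype=int)
    events = pd.DataFrame({
        "time_s": time_s[locs],
        "amplitude_pA": np.abs(scale[locs]),
    })
    mean_amp = float(events.amplitude_pA.mean()) if len(events) else np.nan
    return PSCSummary(events=events, mean_amplitude_pA=mean_amp,
                      frequency_Hz=len(events) / duration_s)
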
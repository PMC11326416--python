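"""Intrinsic electrophysiological feature extraction.

Extracts the 18 intrinsic features from a cell's current-step family:

* passive: resting membrane potential, sag (-60 pA step), input resistance
  and membrane time constant (-20 pA step);
* the rheobase sweep and first-spike latency;
* first-spike shape at rheobase: threshold (dV/dt crossing of 10 mV/ms),
  amplitude, width at half maximum, maximum upstroke and downstroke;
* afterhyperpolarization amplitude, latency and half-width;
* rate statistics: per-step rate = 2 x spike count (500-ms step), f-I slope
  over the initial linear section, maximum rate over 0-200 pA, adaptation
  index and CV of interspike intervals on the maximal step.

Conventions the definitions leave open are fixed here: steady state is the
mean of the final 100 ms of a step and baseline the mean of the 100 ms
before onset; dV/dt uses centered finite differences with linear
interpolation back to the exact criterion crossing; a threshold crossing is
accepted only if followed within 10 ms by a peak at least 2 mV above the
threshold voltage, with a 2-ms refractory lockout; the membrane time
constant is a least-squares single-exponential fit to the -20 pA onset
relaxation; the AHP search window is 100 ms after the first spike's
threshold crossing, truncated at the next spike's threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit
from scipy.stats import linregress

from .features import EPHYS_FEATURES, FeatureVector
from .sweeps import InvalidSweepError, StepFamily, Sweep

SLOPE_CRITERION = 10.0      # mV/ms, dV/dt at spike threshold
PEAK_SEARCH_MS = 10.0       # a crossing must peak within this window
MIN_PEAK_HEIGHT_MV = 2.0    # ... at least this far above threshold
REFRACTORY_MS = 2.0
STEADY_STATE_MS = 100.0
AHP_WINDOW_MS = 100.0
AHP_MIN_WINDOW_MS = 5.0


@dataclass
class SpikeEvent:
    """One detected action potential."""

    threshold_time: float     # s
    threshold_voltage: float  # mV
    peak_time: float          # s
    peak_voltage: float       # mV
    max_dvdt: float           # mV/ms, threshold -> peak
    min_dvdt: float           # mV/ms, repolarization


@dataclass
class QCRecord:
    """Whole-cell recording quality-control measurements."""

    access_resistance_initial: float  # MOhm
    access_resistance_final: float    # MOhm
    offset_current_initial: float     # pA
    offset_current_final: float       # pA
    resting_potential: float          # mV


def dvdt(sweep: Sweep) -> np.ndarray:
    """Membrane-potential time derivative in mV/ms (centered differences)."""
    return np.gradient(sweep.voltage, sweep.dt * 1e3)


def _interp_crossing(t0: float, t1: float, y0: float, y1: float, level: float) -> float:
    if y1 == y0:
        return t0
    return t0 + (level - y0) / (y1 - y0) * (t1 - t0)


def detect_spikes(sweep: Sweep, slope_criterion: float = SLOPE_CRITERION) -> list[SpikeEvent]:
    """Detect action potentials as upward dV/dt crossings of the criterion.

    The threshold is the (interpolated) point where dV/dt first reaches
    ``slope_criterion``; the crossing is accepted only if a local voltage
    maximum at least 2 mV above the threshold voltage follows within 10 ms.
    Returns one event per depolarization transient, ordered in time.
    """
    if slope_criterion <= 0:
        raise ValueError("slope_criterion must be positive")
    v = sweep.voltage
    d = dvdt(sweep)
    dt = sweep.dt
    crossing_idx = np.nonzero((d[:-1] < slope_criterion) & (d[1:] >= slope_criterion))[0] + 1

    events: list[SpikeEvent] = []
    peak_span = max(1, int(round(PEAK_SEARCH_MS * 1e-3 / dt)))
    for i in crossing_idx:
        t_star = _interp_crossing((i - 1) * dt, i * dt, d[i - 1], d[i], slope_criterion)
        v_star = float(np.interp(t_star, [(i - 1) * dt, i * dt], [v[i - 1], v[i]]))
        if events and (t_star - events[-1].threshold_time) < REFRACTORY_MS * 1e-3:
            continue
        hi = min(v.size, i + peak_span + 1)
        seg = v[i:hi]
        if seg.size < 3:
            continue
        # first local maximum at least 2 mV above the threshold voltage
        # (a global max could belong to the next spike in a dense train)
        interior = (
            (seg[1:-1] >= seg[2:])
            & (seg[1:-1] >= seg[:-2])
            & (seg[1:-1] >= v_star + MIN_PEAK_HEIGHT_MV)
        )
        cand = np.nonzero(interior)[0]
        if cand.size == 0:
            continue
        pk = int(cand[0]) + i + 1
        # sub-sample peak refinement (3-point parabola)
        peak_time, peak_v = pk * dt, float(v[pk])
        if 0 < pk < v.size - 1:
            denom = v[pk - 1] - 2 * v[pk] + v[pk + 1]
            if denom < 0:
                delta = 0.5 * (v[pk - 1] - v[pk + 1]) / denom
                if abs(delta) <= 1.0:
                    peak_time = (pk + delta) * dt
                    peak_v = float(v[pk] - 0.25 * (v[pk - 1] - v[pk + 1]) * delta)
        if events and pk * dt <= events[-1].peak_time:
            continue  # same transient
        # repolarization window: peak -> +10 ms
        hi_rep = min(v.size, pk + peak_span + 1)
        max_up = float(np.max(d[i:pk + 1])) if pk >= i else float(d[i])
        min_down = float(np.min(d[pk:hi_rep])) if hi_rep > pk else 0.0
        events.append(
            SpikeEvent(t_star, v_star, peak_time, peak_v, max_up, min_down)
        )
    return events


def spikes_in_step(sweep: Sweep, events: list[SpikeEvent] | None = None) -> list[SpikeEvent]:
    """Events whose threshold crossing falls inside the step window."""
    if events is None:
        events = detect_spikes(sweep)
    return [
        e for e in events
        if sweep.step_onset <= e.threshold_time < sweep.step_offset
    ]


def _baseline(sweep: Sweep) -> float:
    t0 = max(0.0, sweep.step_onset - STEADY_STATE_MS * 1e-3)
    return float(np.mean(sweep.window(t0, sweep.step_onset)))


def _steady_state(sweep: Sweep) -> float:
    return float(np.mean(sweep.window(sweep.step_offset - STEADY_STATE_MS * 1e-3,
                                      sweep.step_offset)))


def passive_features(family: StepFamily) -> FeatureVector:
    """RMP, sag, input resistance and membrane time constant."""
    out = FeatureVector(registry=EPHYS_FEATURES)

    if family.zero_current_sweep is not None:
        out.set("rmp", float(np.mean(family.zero_current_sweep.voltage)))
    else:
        out.set_missing("rmp", "no zero-current sweep")

    s60 = family.sweep_at(-60.0)
    if detect_spikes(s60):
        out.set_missing("sag", "spike detected during hyperpolarizing step")
    else:
        steady = _steady_state(s60)
        vmin = float(np.min(s60.window(s60.step_onset, s60.step_offset)))
        out.set("sag", max(steady - vmin, 0.0))

    s20 = family.sweep_at(-20.0)
    if detect_spikes(s20):
        out.set_missing("input_resistance", "spike detected during hyperpolarizing step")
        out.set_missing("tau", "spike detected during hyperpolarizing step")
        return out
    base = _baseline(s20)
    steady = _steady_state(s20)
    dv = steady - base
    # |dV| mV / 20 pA  ->  MOhm
    out.set("input_resistance", abs(dv) / 20.0 * 1e3)

    t0 = s20.step_onset + 1e-3
    i0 = int(np.ceil(t0 / s20.dt))
    i1 = int(s20.step_offset / s20.dt)
    t = (np.arange(i0, i1) * s20.dt - s20.step_onset) * 1e3  # ms
    y = s20.voltage[i0:i1]

    def relax(tt, tau, v_ss, v0):
        return v_ss + (v0 - v_ss) * np.exp(-tt / tau)

    try:
        p0 = (20.0, steady, base)
        popt, _ = curve_fit(relax, t, y, p0=p0, maxfev=5000)
        tau = float(popt[0])
        if tau <= 0 or not math.isfinite(tau):
            raise RuntimeError
        out.set("tau", tau)
    except Exception:
        out.set_missing("tau", "exponential fit failed")
    return out


def rheobase_sweep(family: StepFamily) -> tuple[Sweep | None, list[SpikeEvent]]:
    """Smallest positive step with >=1 spike inside the step window.

    Sweeps with spikes before step onset are excluded from the search.
    """
    for s in family.positive_sweeps():
        events = detect_spikes(s)
        if any(e.threshold_time < s.step_onset for e in events):
            continue  # flagged: spontaneous activity before the step
        in_step = spikes_in_step(s, events)
        if in_step:
            return s, in_step
    return None, []


def rheobase_and_latency(family: StepFamily) -> FeatureVector:
    out = FeatureVector(registry=EPHYS_FEATURES)
    sweep, events = rheobase_sweep(family)
    if sweep is None:
        out.set_missing("rheobase", "no spikes")
        out.set_missing("spike_latency", "no spikes")
        return out
    out.set("rheobase", sweep.step_amplitude)
    out.set("spike_latency", (events[0].threshold_time - sweep.step_onset) * 1e3)
    return out


def _refine_peak(v: np.ndarray, dt: float, pk: int, halfwin: int = 4) -> tuple[float, float]:
    """Sub-sample spike-tip estimate via local cubic-spline upsampling."""
    from scipy.interpolate import CubicSpline

    lo, hi = max(0, pk - halfwin), min(v.size, pk + halfwin + 1)
    if hi - lo < 4:
        return pk * dt, float(v[pk])
    x = np.arange(lo, hi) * dt
    cs = CubicSpline(x, v[lo:hi])
    xx = np.linspace(x[0], x[-1], (hi - lo - 1) * 50 + 1)
    yy = cs(xx)
    j = int(np.argmax(yy))
    return float(xx[j]), float(yy[j])


def spike_shape_features(family: StepFamily) -> FeatureVector:
    """Threshold, amplitude, half-width, upstroke and downstroke of the
    first spike on the rheobase sweep."""
    out = FeatureVector(registry=EPHYS_FEATURES)
    names = ("spike_threshold", "spike_amplitude", "spike_width", "upstroke", "downstroke")
    sweep, events = rheobase_sweep(family)
    if sweep is None:
        for n in names:
            out.set_missing(n, "no rheobase")
        return out
    e = events[0]
    _, peak_v = _refine_peak(sweep.voltage, sweep.dt, int(round(e.peak_time / sweep.dt)))
    amp = peak_v - e.threshold_voltage
    out.set("spike_threshold", e.threshold_voltage)
    out.set("spike_amplitude", amp)
    out.set("upstroke", e.max_dvdt)
    out.set("downstroke", e.min_dvdt)

    half = e.threshold_voltage + amp / 2.0
    v = sweep.voltage
    dt = sweep.dt
    i_thr = int(e.threshold_time / dt)
    i_pk = int(round(e.peak_time / dt))
    t_rise = t_fall = None
    for i in range(max(i_thr, 1), i_pk + 1):
        if v[i - 1] < half <= v[i]:
            t_rise = _interp_crossing((i - 1) * dt, i * dt, v[i - 1], v[i], half)
            break
    for i in range(i_pk + 1, v.size):
        if v[i - 1] >= half > v[i]:
            t_fall = _interp_crossing((i - 1) * dt, i * dt, v[i - 1], v[i], half)
            break
    if t_rise is None or t_fall is None:
        out.set_missing("spike_width", "half-maximum crossings not found")
    else:
        out.set("spike_width", (t_fall - t_rise) * 1e3)
    return out


def ahp_features(family: StepFamily) -> FeatureVector:
    """AHP amplitude, latency and half-width after the first rheobase spike.

    The trough is searched within 100 ms of the threshold crossing (truncated
    at the next spike's threshold); the half-width is measured between the
    interpolated crossings of the half-amplitude level below threshold, the
    recovery crossing being allowed to fall beyond the 100-ms window.
    """
    out = FeatureVector(registry=EPHYS_FEATURES)
    names = ("ahp_amplitude", "ahp_latency", "ahp_width")
    sweep, events = rheobase_sweep(family)
    if sweep is None:
        for n in names:
            out.set_missing(n, "no rheobase")
        return out
    e = events[0]
    dt = sweep.dt
    t_end = e.threshold_time + AHP_WINDOW_MS * 1e-3
    if len(events) > 1:
        t_end = min(t_end, events[1].threshold_time)
    t_end = min(t_end, sweep.voltage.size * dt)
    if (t_end - e.peak_time) < AHP_MIN_WINDOW_MS * 1e-3:
        for n in names:
            out.set_missing(n, "AHP window shorter than 5 ms")
        return out

    i0 = int(round(e.peak_time / dt))
    i1 = int(t_end / dt)
    seg = sweep.voltage[i0:i1]
    i_min = int(np.argmin(seg)) + i0
    vmin = float(sweep.voltage[i_min])
    amp = max(e.threshold_voltage - vmin, 0.0)
    out.set("ahp_amplitude", amp)
    out.set("ahp_latency", (i_min * dt - e.threshold_time) * 1e3)
    if amp <= 0:
        out.set_missing("ahp_width", "no hyperpolarization below threshold")
        return out

    half = e.threshold_voltage - amp / 2.0
    v = sweep.voltage
    t_fall = t_rise = None
    for i in range(i0 + 1, i_min + 1):
        if v[i - 1] > half >= v[i]:
            t_fall = _interp_crossing((i - 1) * dt, i * dt, v[i - 1], v[i], half)
            break
    i_stop = int(events[1].threshold_time / dt) if len(events) > 1 else v.size
    for i in range(i_min + 1, i_stop):
        if v[i - 1] < half <= v[i]:
            t_rise = _interp_crossing((i - 1) * dt, i * dt, v[i - 1], v[i], half)
            break
    if t_fall is None or t_rise is None:
        out.set_missing("ahp_width", "half-amplitude crossings not found")
    else:
        out.set("ahp_width", (t_rise - t_fall) * 1e3)
    return out


def step_rate(sweep: Sweep) -> float:
    """Per-step firing rate in Hz: spikes during the 500-ms step times 2."""
    return 2.0 * len(spikes_in_step(sweep))


def rate_features(family: StepFamily) -> FeatureVector:
    """f-I slope, maximum rate, adaptation index and CV of ISIs."""
    out = FeatureVector(registry=EPHYS_FEATURES)
    pos = [s for s in family.sweeps if 0 <= s.step_amplitude <= 200]
    rates = {s.step_amplitude: step_rate(s) for s in pos}
    out.set("max_rate", max(rates.values()) if rates else 0.0)

    sweep, _ = rheobase_sweep(family)
    if sweep is None:
        out.set_missing("fi_slope", "no spikes")
        out.set_missing("adaptation_index", "no spikes")
        out.set_missing("cv_isi", "no spikes")
        return out

    # initial linear section: first three positive-rate levels from rheobase
    amps = sorted(a for a, r in rates.items() if a >= sweep.step_amplitude and r > 0)
    amps = amps[:3]
    if len(amps) < 2:
        out.set_missing("fi_slope", "fewer than 2 points on the f-I curve")
    else:
        out.set("fi_slope", float(linregress(amps, [rates[a] for a in amps]).slope))

    top = family.sweeps[-1]
    ev = spikes_in_step(top)
    mid = top.step_onset + top.step_duration / 2.0
    n1 = sum(1 for e in ev if e.threshold_time < mid)
    n2 = len(ev) - n1
    if n1 == 0:
        out.set_missing("adaptation_index", "no spikes in first half of maximal step")
    else:
        out.set("adaptation_index", n2 / n1)
    if len(ev) < 3:
        out.set_missing("cv_isi", "fewer than 3 spikes on maximal step")
    else:
        isi = np.diff([e.threshold_time for e in ev])
        out.set("cv_isi", float(np.std(isi, ddof=1) / np.mean(isi)))
    return out


def extract_features(family: StepFamily) -> FeatureVector:
    """All 18 intrinsic features; per-feature missing markers propagate."""
    out = FeatureVector(registry=EPHYS_FEATURES)
    for part in (
        passive_features(family),
        rheobase_and_latency(family),
        spike_shape_features(family),
        ahp_features(family),
        rate_features(family),
    ):
        for name, value in part.values.items():
            if name in part.reasons:
                out.set_missing(name, part.reasons[name])
            elif not math.isnan(value):
                out.set(name, value)
    return out


def phase_curve(sweep: Sweep) -> tuple[np.ndarray, np.ndarray]:
    """(V, dV/dt) samples over the whole sweep."""
    return sweep.voltage.copy(), dvdt(sweep)


def phase_plane(family: StepFamily) -> tuple[np.ndarray, np.ndarray]:
    """Phase-plane curve (V vs dV/dt) over the first spike cycle at rheobase.

    Empty arrays when no rheobase sweep exists.
    """
    sweep, events = rheobase_sweep(family)
    if sweep is None:
        return np.empty(0), np.empty(0)
    e = events[0]
    dt = sweep.dt
    t0 = max(0.0, e.threshold_time - 2e-3)
    t1 = e.peak_time + PEAK_SEARCH_MS * 1e-3
    if len(events) > 1:
        t1 = min(t1, events[1].threshold_time)
    i0, i1 = int(t0 / dt), min(sweep.voltage.size, int(t1 / dt))
    v, d = phase_curve(sweep)
    return v[i0:i1], d[i0:i1]


def qc_check(qc: QCRecord) -> tuple[bool, list[str]]:
    """Recording QC: access resistance < 25 MOhm and stable within 20%,
    offset-current drift within 10% and magnitude < 100 pA, resting
    potential <= -40 mV.  Returns (passed, violated criteria)."""
    reasons: list[str] = []
    ra0, ra1 = qc.access_resistance_initial, qc.access_resistance_final
    if ra0 >= 25 or ra1 >= 25:
        reasons.append("access resistance >= 25 MOhm")
    if ra0 > 0 and abs(ra1 - ra0) / ra0 >= 0.20:
        reasons.append("access resistance drift >= 20%")
    i0, i1 = qc.offset_current_initial, qc.offset_current_final
    ref = max(abs(i0), 1e-9)
    if abs(i1 - i0) / ref >= 0.10:
        reasons.append("offset current drift >= 10%")
    if abs(i0) >= 100 or abs(i1) >= 100:
        reasons.append("offset current magnitude >= 100 pA")
    if qc.resting_potential > -40:
        reasons.append("resting potential > -40 mV")
    return (not reasons), reasons
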
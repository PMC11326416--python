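"""Ground-truth voltage-trace generators.

Two tiers:

* :func:`compose_trace_family` builds a step family from analytic segments
  (exponential passive relaxations, a sag rebound, stereotyped spline-like
  spikes, shaped afterhyperpolarizations) so that every programmed feature
  value is known exactly and can be checked against the extractor.
* :func:`simulate_adex` integrates the two-variable adaptive exponential
  integrate-and-fire model over the same protocol for mechanistically
  generated (but only approximately calibrated) cohorts.

Spike construction.  The depolarizing flank is specified by its slope
profile: the slope starts exactly at the detection criterion (10 mV/ms) at
the programmed threshold voltage, rises smoothly (quarter-sine) to the peak
upstroke, and returns smoothly to zero at the spike tip; the repolarizing
flank is a half-sine slope profile reaching the peak downstroke.  Threshold,
amplitude and width-at-half-maximum are embedded exactly; because the width
and both slope extrema cannot all be chosen independently for a fixed
amplitude, the two slope extrema are rescaled jointly (preserving their
ratio) until the half-width matches, and the realized values are recorded
as ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.stats import linregress

from .features import EPHYS_FEATURES, FeatureVector
from .sweeps import (
    BASELINE_MV,
    PROTOCOL_AMPLITUDES,
    STEP_DURATION_S,
    StepFamily,
    Sweep,
)

SLOPE_AT_THRESHOLD = 10.0   # mV/ms, matches the detection criterion
PRE_MS = 0.3                # constant-acceleration window around threshold
PRE_GAIN = 20.0             # slope acceleration (mV/ms per ms) in that window
PRE_SLOPE_HI = SLOPE_AT_THRESHOLD + PRE_GAIN * PRE_MS
PRE_SLOPE_LO = SLOPE_AT_THRESHOLD - PRE_GAIN * PRE_MS
PRE_AREA_ABOVE = SLOPE_AT_THRESHOLD * PRE_MS + 0.5 * PRE_GAIN * PRE_MS**2
PRE_AREA_BELOW = SLOPE_AT_THRESHOLD * PRE_MS - 0.5 * PRE_GAIN * PRE_MS**2
LEAD_GAP = 6.0              # mV climbed by the prepotential ramp
LEADIN_MS = LEAD_GAP * math.pi / (2.0 * PRE_SLOPE_LO)
LEADIN_DEPTH = PRE_AREA_BELOW + LEAD_GAP  # mV below threshold at ramp start
SAG_BUMP_CENTER_S = 0.35    # within-step position of the sag trough
SAG_BUMP_SIGMA_S = 0.02
MIN_ISI_MARGIN_MS = 2.0


class SpecError(ValueError):
    """An infeasible trace specification."""


@dataclass
class StepProtocol:
    amplitudes: tuple[float, ...] = PROTOCOL_AMPLITUDES
    step_onset: float = 0.15
    step_duration: float = STEP_DURATION_S
    post: float = 0.2
    baseline: float = BASELINE_MV

    @property
    def total(self) -> float:
        return self.step_onset + self.step_duration + self.post


# ---------------------------------------------------------------------------
# stereotyped spike shape
# ---------------------------------------------------------------------------

@dataclass
class SpikeShape:
    """Analytic spike waveform with exact threshold/amplitude/half-width.

    Around the threshold crossing the slope grows linearly in time
    (constant acceleration over +/- ``PRE_MS``), so finite-difference
    detection with linear interpolation recovers the programmed threshold
    point essentially exactly.  ``upstroke``/``downstroke`` are the realized
    slope extrema after the joint rescaling that enforces the half-width.
    """

    threshold: float
    amplitude: float
    width_ms: float
    upstroke: float      # realized, mV/ms
    downstroke: float    # realized, mV/ms (negative)
    rise_ms: float       # threshold -> peak
    fall_ms: float       # peak -> threshold level

    @classmethod
    def solve(
        cls,
        threshold: float,
        amplitude: float,
        width_ms: float,
        upstroke_target: float,
        downstroke_target: float,
    ) -> "SpikeShape":
        if amplitude <= PRE_AREA_ABOVE + 5.0 or width_ms <= 0:
            raise SpecError("spike amplitude too small or width non-positive")
        if upstroke_target <= SLOPE_AT_THRESHOLD or downstroke_target >= 0:
            raise SpecError("upstroke must exceed 10 mV/ms and downstroke be negative")
        u0, d0 = upstroke_target, abs(downstroke_target)

        def realized_width(lam: float) -> float:
            u, d = lam * u0, lam * d0
            t_half = _rise_half_time(amplitude, u)
            t_rise = _rise_duration(amplitude, u)
            t_fall = math.pi * amplitude / (2.0 * d)
            return (t_rise - t_half) + t_fall / 2.0

        lam_lo = (PRE_SLOPE_HI + 3.0) / u0
        lam_hi = max(1.0, lam_lo * 2)
        while realized_width(lam_hi) > width_ms and lam_hi < 1e4:
            lam_hi *= 2.0
        if realized_width(lam_lo) < width_ms:
            raise SpecError(
                f"half-width {width_ms:g} ms unattainable for amplitude "
                f"{amplitude:g} mV with the given slope ratio"
            )
        lam = brentq(lambda L: realized_width(L) - width_ms, lam_lo, lam_hi,
                     xtol=1e-10)
        u, d = lam * u0, lam * d0
        return cls(
            threshold=threshold,
            amplitude=amplitude,
            width_ms=width_ms,
            upstroke=u,
            downstroke=-d,
            rise_ms=_rise_duration(amplitude, u),
            fall_ms=math.pi * amplitude / (2.0 * d),
        )

    @property
    def pre_ms(self) -> float:
        return PRE_MS

    @property
    def duration_ms(self) -> float:
        return self.rise_ms + self.fall_ms

    def voltage(self, t_ms: np.ndarray) -> np.ndarray:
        """Absolute voltage at times (ms) relative to the threshold
        crossing, valid on [-PRE_MS, rise+fall]; clipped outside."""
        t = np.clip(np.asarray(t_ms, float), -PRE_MS, self.duration_ms)
        v = np.empty_like(t)
        s_crit = SLOPE_AT_THRESHOLD
        u = self.upstroke
        h = (self.rise_ms - PRE_MS) / 2.0
        t1 = PRE_MS + h   # end of the slope ramp to the upstroke

        lin = t <= PRE_MS
        v[lin] = self.threshold + s_crit * t[lin] + 0.5 * PRE_GAIN * t[lin] ** 2
        v_lin_end = self.threshold + PRE_AREA_ABOVE

        ramp = (t > PRE_MS) & (t <= t1)
        tt = t[ramp] - PRE_MS
        v[ramp] = (
            v_lin_end
            + PRE_SLOPE_HI * tt
            + 0.5 * (u - PRE_SLOPE_HI) * (tt - (h / math.pi) * np.sin(math.pi * tt / h))
        )
        v_ramp_end = v_lin_end + h * (u + PRE_SLOPE_HI) / 2.0

        decay = (t > t1) & (t <= self.rise_ms)
        tt = t[decay] - t1
        v[decay] = v_ramp_end + u * (2 * h / math.pi) * np.sin(math.pi * tt / (2 * h))

        falling = t > self.rise_ms
        tt = t[falling] - self.rise_ms
        tf = self.fall_ms
        d = -self.downstroke
        v[falling] = (
            self.threshold + self.amplitude
            - d * (tf / math.pi) * (1 - np.cos(math.pi * tt / tf))
        )
        return v


def _rise_duration(amplitude: float, upstroke: float) -> float:
    # beyond the constant-acceleration window: a half-cosine slope ramp to
    # the upstroke and a quarter-cosine decay to zero, equal durations h
    h = (amplitude - PRE_AREA_ABOVE) / (
        (upstroke + PRE_SLOPE_HI) / 2.0 + 2.0 * upstroke / math.pi
    )
    if h <= 0:
        raise SpecError("amplitude too small for the spike shape")
    return PRE_MS + 2.0 * h


def _rise_half_time(amplitude: float, upstroke: float) -> float:
    """Time (ms from threshold) at which the rising flank crosses
    threshold + amplitude/2."""
    t_rise = _rise_duration(amplitude, upstroke)
    h = (t_rise - PRE_MS) / 2.0
    half = amplitude / 2.0
    if half <= PRE_AREA_ABOVE:  # cannot happen for amplitude > 2*PRE_AREA_ABOVE
        return brentq(
            lambda t: SLOPE_AT_THRESHOLD * t + 0.5 * PRE_GAIN * t * t - half,
            0.0, PRE_MS, xtol=1e-12,
        )
    v_mid = PRE_AREA_ABOVE + h * (upstroke + PRE_SLOPE_HI) / 2.0
    if half <= v_mid:
        f = lambda t: (
            PRE_AREA_ABOVE
            + PRE_SLOPE_HI * t
            + 0.5 * (upstroke - PRE_SLOPE_HI) * (t - (h / math.pi) * math.sin(math.pi * t / h))
            - half
        )
        return PRE_MS + brentq(f, 0.0, h, xtol=1e-12)
    # quarter-cosine decay phase
    arg = (half - v_mid) * math.pi / (2 * h * upstroke)
    arg = min(max(arg, -1.0), 1.0)
    return PRE_MS + h + (2 * h / math.pi) * math.asin(arg)


# ---------------------------------------------------------------------------
# trace specification
# ---------------------------------------------------------------------------

@dataclass
class TraceSpec:
    """Exact per-cell ground truth for a composed step family.

    ``spike_times`` maps step amplitude (pA) to threshold-crossing times in
    seconds *relative to step onset*.
    """

    rmp: float = -55.0
    sag: float = 3.0
    input_resistance: float = 300.0   # MOhm
    tau: float = 25.0                 # ms
    spike_threshold: float = -35.0
    spike_amplitude: float = 60.0
    spike_width: float = 1.2          # ms
    upstroke: float = 200.0           # target, mV/ms
    downstroke: float = -90.0         # target, mV/ms
    ahp_amplitude: float = 20.0       # mV
    ahp_latency: float = 50.0         # ms
    ahp_width: float = 120.0          # ms
    spike_times: dict[float, np.ndarray] = field(default_factory=dict)
    protocol: StepProtocol = field(default_factory=StepProtocol)

    def validate(self, shape: SpikeShape) -> None:
        p = self.protocol
        min_gap = max(self.spike_width + MIN_ISI_MARGIN_MS,
                      shape.duration_ms + PRE_MS + LEADIN_MS + 3.0) * 1e-3
        for amp, times in self.spike_times.items():
            times = np.asarray(times, float)
            if times.size == 0:
                continue
            if np.any(times < 1e-2) or np.any(times > p.step_duration - 2e-3):
                raise SpecError(f"{amp} pA: spike times outside the step window")
            if np.any(np.diff(times) < min_gap):
                raise SpecError(f"{amp} pA: spikes closer than width + 2 ms")
        if self.tau <= 0 or self.input_resistance <= 0:
            raise SpecError("tau and input resistance must be positive")
        if self.ahp_amplitude < 0 or self.ahp_latency <= 0 or self.ahp_width <= 0:
            raise SpecError("AHP parameters must be non-negative")


@dataclass
class AhpShape:
    """Full afterhyperpolarization: half-cosine descent to the trough at the
    programmed latency, then a half-cosine recovery whose duration is chosen
    so the half-amplitude level is recrossed exactly one half-width after it
    was first crossed."""

    depth: float
    descent_ms: float      # spike end -> trough
    recovery_ms: float
    recovery_level: float  # relative to threshold (negative)

    @classmethod
    def solve(cls, spike: SpikeShape, depth: float, latency_ms: float,
              width_ms: float) -> "AhpShape":
        t_d = latency_ms - spike.duration_ms
        if t_d <= 1.0:
            raise SpecError("AHP latency must exceed the spike duration")
        s_star = width_ms - t_d / 2.0
        if s_star <= 0.5:
            raise SpecError("AHP width too small for the programmed latency")
        d_rec = min(5.0, depth / 4.0)
        frac = (depth / 2.0) / (depth - d_rec)
        t_rec = s_star * math.pi / math.acos(1.0 - 2.0 * frac)
        return cls(depth=depth, descent_ms=t_d, recovery_ms=t_rec,
                   recovery_level=-d_rec)

    @property
    def duration_ms(self) -> float:
        return self.descent_ms + self.recovery_ms

    def voltage(self, t_ms: np.ndarray, threshold: float) -> np.ndarray:
        """Voltage at times (ms) after the spike end; holds the recovery
        level afterwards."""
        t = np.asarray(t_ms, float)
        v = np.full_like(t, threshold + self.recovery_level)
        desc = t <= self.descent_ms
        v[desc] = threshold - self.depth * (1 - np.cos(math.pi * t[desc] / self.descent_ms)) / 2.0
        rec = (t > self.descent_ms) & (t <= self.duration_ms)
        tt = t[rec] - self.descent_ms
        trough = threshold - self.depth
        v[rec] = trough + (threshold + self.recovery_level - trough) * (
            1 - np.cos(math.pi * tt / self.recovery_ms)
        ) / 2.0
        return v


def _passive_deflection(t: np.ndarray, onset: float, offset: float,
                        dv_ss: float, tau_s: float) -> np.ndarray:
    """Exponential step response (deflection from baseline) with relaxation
    back after the step."""
    out = np.zeros_like(t)
    during = (t >= onset) & (t < offset)
    out[during] = dv_ss * (1 - np.exp(-(t[during] - onset) / tau_s))
    after = t >= offset
    v_off = dv_ss * (1 - math.exp(-(offset - onset) / tau_s))
    out[after] = v_off * np.exp(-(t[after] - offset) / tau_s)
    return out


def _compose_subthreshold(spec: TraceSpec, amp: float, t: np.ndarray) -> np.ndarray:
    p = spec.protocol
    tau_s = spec.tau * 1e-3
    dv = amp * spec.input_resistance * 1e-3  # pA * MOhm -> mV
    if amp > 0:
        dv = min(dv, (spec.spike_threshold - 12.0) - p.baseline)
    v = p.baseline + _passive_deflection(t, p.step_onset, p.step_onset + p.step_duration,
                                         dv, tau_s)
    if amp == -60.0 and spec.sag > 0:
        center = p.step_onset + SAG_BUMP_CENTER_S
        bump = spec.sag * np.exp(-((t - center) ** 2) / (2 * SAG_BUMP_SIGMA_S**2))
        during = (t >= p.step_onset) & (t < p.step_onset + p.step_duration)
        v[during] -= bump[during]
    return v


def _compose_spiking(spec: TraceSpec, shape: SpikeShape, ahp: AhpShape,
                     times_s: np.ndarray, t: np.ndarray) -> np.ndarray:
    p = spec.protocol
    theta = spec.spike_threshold
    lead_level = theta - LEADIN_DEPTH
    flank_below = theta - PRE_AREA_BELOW  # spike segment start voltage
    onset = p.step_onset
    offset = onset + p.step_duration
    t_ms = t * 1e3
    v = np.full_like(t, p.baseline)

    spike_abs = times_s + onset  # absolute threshold times, s

    # onset ramp (half-cosine, C1 at both ends) landing exactly on the
    # lead-in start level when the first lead-in begins
    delta0 = lead_level - p.baseline
    t1_start = spike_abs[0] - (PRE_MS + LEADIN_MS) * 1e-3
    t_on = (t1_start - onset) * 1e3  # ms
    if t_on <= 0 or abs(delta0) * math.pi / (2.0 * t_on) >= 9.0:
        raise SpecError(
            "first spike too early: onset ramp would approach the slope criterion"
        )
    seg = (t >= onset) & (t < t1_start)
    v[seg] = p.baseline + delta0 * (
        1 - np.cos(math.pi * (t_ms[seg] - onset * 1e3) / t_on)
    ) / 2.0

    for k, t_thr in enumerate(spike_abs):
        thr_ms = t_thr * 1e3
        flank_ms = thr_ms - PRE_MS
        # lead-in: quarter-sine slope profile ending exactly at the flank's
        # initial slope (the constant-acceleration window takes over there)
        gap_mv = flank_below - lead_level
        t_lead = LEADIN_MS
        seg = (t_ms >= flank_ms - t_lead) & (t_ms < flank_ms)
        tt = t_ms[seg] - (flank_ms - t_lead)
        v[seg] = lead_level + gap_mv * (1 - np.cos(math.pi * tt / (2 * t_lead)))
        # the spike proper (constant-acceleration window + flanks)
        spike_end_ms = thr_ms + shape.duration_ms
        seg = (t_ms >= flank_ms) & (t_ms < spike_end_ms)
        v[seg] = shape.voltage(t_ms[seg] - thr_ms)

        last = k == len(spike_abs) - 1
        if last:
            seg = (t_ms >= spike_end_ms) & (t < offset)
            v[seg] = ahp.voltage(t_ms[seg] - spike_end_ms, theta)
        else:
            # inter-spike trough and recovery back to the lead-in level
            next_flank = spike_abs[k + 1] * 1e3 - PRE_MS
            gap_total = next_flank - LEADIN_MS - spike_end_ms
            depth = max(min(ahp.depth, 12.0), LEADIN_DEPTH + 1.0)
            d1, d2 = 0.4 * gap_total, 0.6 * gap_total
            seg = (t_ms >= spike_end_ms) & (t_ms < spike_end_ms + d1)
            tt = t_ms[seg] - spike_end_ms
            v[seg] = theta - depth * (1 - np.cos(math.pi * tt / d1)) / 2.0
            seg = (t_ms >= spike_end_ms + d1) & (t_ms < next_flank - LEADIN_MS)
            tt = t_ms[seg] - spike_end_ms - d1
            trough = theta - depth
            v[seg] = trough + (lead_level - trough) * (1 - np.cos(math.pi * tt / d2)) / 2.0

    # step offset: relax back to baseline from wherever the trace is
    i_off = int(np.searchsorted(t, offset))
    if i_off < t.size:
        v_off = v[i_off - 1] if i_off > 0 else p.baseline
        seg = t >= offset
        v[seg] = p.baseline + (v_off - p.baseline) * np.exp(
            -(t[seg] - offset) / (spec.tau * 1e-3)
        )
    return v


def ground_truth_vector(spec: TraceSpec, shape: SpikeShape) -> FeatureVector:
    """The 18 feature values a composed family encodes (realized values for
    the rate-derived features, programmed values elsewhere)."""
    gt = FeatureVector(registry=EPHYS_FEATURES)
    gt.set("rmp", spec.rmp)
    gt.set("sag", spec.sag)
    gt.set("input_resistance", spec.input_resistance)
    gt.set("tau", spec.tau)

    counts = {
        amp: len(np.asarray(ts)) for amp, ts in spec.spike_times.items()
    }
    spiking = sorted(a for a, c in counts.items() if c > 0 and a > 0)
    rates = {a: 2.0 * counts.get(a, 0) for a in spec.protocol.amplitudes
             if 0 <= a <= 200}
    gt.set("max_rate", max(rates.values()) if rates else 0.0)
    if not spiking:
        for n in ("rheobase", "spike_latency", "spike_threshold", "spike_amplitude",
                  "spike_width", "upstroke", "downstroke", "ahp_amplitude",
                  "ahp_latency", "ahp_width", "fi_slope", "adaptation_index",
                  "cv_isi"):
            gt.set_missing(n, "no spikes")
        return gt

    rheo = spiking[0]
    gt.set("rheobase", rheo)
    gt.set("spike_latency", float(np.asarray(spec.spike_times[rheo])[0]) * 1e3)
    gt.set("spike_threshold", shape.threshold)
    gt.set("spike_amplitude", shape.amplitude)
    gt.set("spike_width", shape.width_ms)
    gt.set("upstroke", shape.upstroke)
    gt.set("downstroke", shape.downstroke)
    gt.set("ahp_amplitude", spec.ahp_amplitude)
    gt.set("ahp_latency", spec.ahp_latency)
    gt.set("ahp_width", spec.ahp_width)

    fi_amps = sorted(a for a in rates if a >= rheo and rates[a] > 0)[:3]
    if len(fi_amps) >= 2:
        gt.set("fi_slope", float(linregress(fi_amps, [rates[a] for a in fi_amps]).slope))
    else:
        gt.set_missing("fi_slope", "fewer than 2 points on the f-I curve")

    top = max(a for a in spec.protocol.amplitudes)
    times = np.asarray(spec.spike_times.get(top, ()), float)
    half = spec.protocol.step_duration / 2.0
    n1 = int(np.sum(times < half))
    n2 = times.size - n1
    if n1 == 0:
        gt.set_missing("adaptation_index", "no spikes in first half of maximal step")
    else:
        gt.set("adaptation_index", n2 / n1)
    if times.size < 3:
        gt.set_missing("cv_isi", "fewer than 3 spikes on maximal step")
    else:
        isi = np.diff(times)
        gt.set("cv_isi", float(np.std(isi, ddof=1) / np.mean(isi)))
    return gt


def compose_trace_family(
    spec: TraceSpec, dt: float = 2.5e-5, cell_id: str = "composed"
) -> tuple[StepFamily, FeatureVector]:
    """Build the full step family for a :class:`TraceSpec`.

    Returns the family and its ground-truth feature vector.
    """
    shape = SpikeShape.solve(
        spec.spike_threshold, spec.spike_amplitude, spec.spike_width,
        spec.upstroke, spec.downstroke,
    )
    spec.validate(shape)
    ahp = AhpShape.solve(shape, max(spec.ahp_amplitude, 0.5),
                         spec.ahp_latency, spec.ahp_width)
    p = spec.protocol
    t = np.arange(0.0, p.total, dt)
    sweeps = []
    for amp in p.amplitudes:
        times = np.asarray(spec.spike_times.get(amp, ()), float)
        if times.size == 0:
            v = _compose_subthreshold(spec, amp, t)
        else:
            v = _compose_spiking(spec, shape, ahp, times, t)
        sweeps.append(Sweep(dt, v, amp, p.step_onset, p.step_duration, p.baseline))
    rest = Sweep(dt, np.full_like(t, spec.rmp), 0.0, p.step_onset,
                 p.step_duration, p.baseline)
    family = StepFamily(cell_id, sweeps, rest)
    return family, ground_truth_vector(spec, shape)


# ---------------------------------------------------------------------------
# adaptive exponential integrate-and-fire generator
# ---------------------------------------------------------------------------

@dataclass
class AdExParams:
    """Two-variable adaptive exponential integrate-and-fire parameters."""

    capacitance: float = 100.0        # pF
    g_leak: float = 5.0               # nS
    e_leak: float = -65.0             # mV
    delta_t: float = 2.0              # mV, threshold slope factor
    v_t: float = -45.0                # mV, spike-initiation voltage
    a: float = 2.0                    # nS, subthreshold adaptation coupling
    b: float = 30.0                   # pA, spike-triggered adaptation
    tau_w: float = 150.0              # ms
    v_reset: float = -55.0            # mV
    v_cut: float = 0.0                # mV, numerical spike cutoff
    v_spike_draw: float = 30.0        # mV, drawn spike tip for the trace

    def __post_init__(self) -> None:
        if min(self.capacitance, self.g_leak, self.tau_w, self.delta_t) <= 0:
            raise ValueError("capacitance, conductances and time constants must be positive")


def holding_current(params: AdExParams, v_hold: float = BASELINE_MV) -> float:
    """Constant current (pA) that makes ``v_hold`` a pre-step fixed point."""
    p = params
    w_ss = p.a * (v_hold - p.e_leak)
    exp_term = p.g_leak * p.delta_t * math.exp((v_hold - p.v_t) / p.delta_t)
    return p.g_leak * (v_hold - p.e_leak) - exp_term + w_ss


def simulate_adex(
    params: AdExParams,
    protocol: StepProtocol | None = None,
    dt: float = 5e-5,
    cell_id: str = "adex",
) -> StepFamily:
    """Forward-Euler integration of the AdEx model over the step protocol,
    all sweeps integrated in lockstep.  Raises on numerical divergence."""
    p = params
    proto = protocol or StepProtocol()
    amps = np.asarray(proto.amplitudes, float)
    n_steps = int(round(proto.total / dt))
    i_hold = holding_current(p, proto.baseline)

    v = np.full(amps.size, proto.baseline)
    w = np.full(amps.size, p.a * (proto.baseline - p.e_leak))
    out = np.empty((n_steps, amps.size))
    dt_ms = dt * 1e3
    onset, offset = proto.step_onset, proto.step_onset + proto.step_duration
    exp_cap = 30.0 / p.delta_t  # caps the exponential argument
    for i in range(n_steps):
        t_now = i * dt
        i_inj = i_hold + amps * ((onset <= t_now) & (t_now < offset))
        arg = np.minimum((v - p.v_t) / p.delta_t, exp_cap)
        dv = (
            -p.g_leak * (v - p.e_leak)
            + p.g_leak * p.delta_t * np.exp(arg)
            - w
            + i_inj
        ) / p.capacitance  # pA/pF = mV/ms
        dw = (p.a * (v - p.e_leak) - w) / p.tau_w
        v = v + dv * dt_ms
        w = w + dw * dt_ms
        fired = v >= p.v_cut
        if np.any(fired):
            out[i, :] = np.where(fired, p.v_spike_draw, v)
            v = np.where(fired, p.v_reset, v)
            w = np.where(fired, w + p.b, w)
        else:
            out[i, :] = v
        if not np.all(np.isfinite(v)):
            bad = amps[~np.isfinite(v)][0]
            raise FloatingPointError(f"AdEx integration diverged at {bad:g} pA")

    sweeps = [
        Sweep(dt, out[:, j], float(amps[j]), proto.step_onset,
              proto.step_duration, proto.baseline)
        for j in range(amps.size)
    ]
    rest_v = np.full(n_steps, p.e_leak)
    rest = Sweep(dt, rest_v, 0.0, proto.step_onset, proto.step_duration, proto.baseline)
    return StepFamily(cell_id, sweeps, rest)
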
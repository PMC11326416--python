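"""Intrinsic-feature extraction: spike detection, passive properties, spike
shape, AHP, rate statistics and recording QC."""

import math

import numpy as np
import pytest

from morphoelec.ephys import (
    QCRecord,
    ahp_features,
    detect_spikes,
    dvdt,
    extract_features,
    passive_features,
    phase_curve,
    phase_plane,
    qc_check,
    rate_features,
    rheobase_and_latency,
    spike_shape_features,
    step_rate,
)
from morphoelec.features import EPHYS_FEATURES
from morphoelec.sweeps import InvalidSweepError, StepFamily, Sweep
from morphoelec.synth_traces import TraceSpec, compose_trace_family


def flat_sweep(amp=0.0, level=-65.0, dt=1e-4, total=0.85):
    v = np.full(int(total / dt), level)
    return Sweep(dt, v, amp, 0.15)


class TestDetectSpikes:
    def test_constant_trace_yields_no_events(self):
        assert detect_spikes(flat_sweep(100.0)) == []

    def test_single_composed_spike_threshold_voltage(self):
        # slope passes smoothly through 10 mV/ms at the programmed -33 mV
        spec = TraceSpec(spike_threshold=-33.0, spike_times={70.0: np.array([0.1])})
        fam, _ = compose_trace_family(spec)
        events = detect_spikes(fam.sweep_at(70.0))
        assert len(events) == 1
        assert events[0].threshold_voltage == pytest.approx(-33.0, abs=0.5)

    def test_regular_train_has_equal_intervals(self):
        times = 0.03 + 0.04 * np.arange(10)
        spec = TraceSpec(spike_times={200.0: times})
        fam, _ = compose_trace_family(spec)
        events = detect_spikes(fam.sweep_at(200.0))
        assert len(events) == 10
        isi = np.diff([e.threshold_time for e in events])
        assert np.allclose(isi, 0.04, atol=1e-4)

    def test_events_are_time_ordered_with_peak_after_threshold(self, composed_cell):
        _, fam, _ = composed_cell
        events = detect_spikes(fam.sweep_at(200.0))
        t = [e.threshold_time for e in events]
        assert t == sorted(t)
        for e in events:
            assert e.peak_time >= e.threshold_time
            assert e.peak_voltage > e.threshold_voltage
            assert e.max_dvdt >= 10.0

    def test_nonfinite_trace_rejected(self):
        v = np.full(9000, -65.0)
        v[100] = np.nan
        with pytest.raises(InvalidSweepError):
            Sweep(1e-4, v, 10.0, 0.15)

    def test_slope_criterion_must_be_positive(self):
        with pytest.raises(ValueError):
            detect_spikes(flat_sweep(), slope_criterion=0.0)


class TestPassiveFeatures:
    def test_input_resistance_from_ohms_law(self):
        # R = 500 MOhm: a -20 pA step must deflect by -10 mV
        spec = TraceSpec(input_resistance=500.0, sag=0.0, spike_times={})
        fam, _ = compose_trace_family(spec)
        out = passive_features(fam)
        assert out["input_resistance"] == pytest.approx(500.0, rel=0.02)

    def test_pure_exponential_relaxation_has_zero_sag(self):
        spec = TraceSpec(sag=0.0, spike_times={})
        fam, _ = compose_trace_family(spec)
        assert passive_features(fam)["sag"] == pytest.approx(0.0, abs=0.1)

    def test_membrane_time_constant_recovered(self):
        spec = TraceSpec(tau=34.6, spike_times={})
        fam, _ = compose_trace_family(spec)
        assert passive_features(fam)["tau"] == pytest.approx(34.6, rel=0.05)

    def test_rmp_missing_without_rest_sweep(self, passive_cell):
        _, fam, _ = passive_cell
        bare = StepFamily(fam.cell_id, list(fam.sweeps), None)
        out = passive_features(bare)
        assert out.is_missing("rmp")
        assert "zero-current" in out.reasons["rmp"]


class TestRheobaseAndShape:
    def test_rheobase_by_brute_force_scan(self, composed_cell):
        spec, fam, _ = composed_cell
        out = rheobase_and_latency(fam)
        # oracle: smallest positive amplitude with a programmed spike
        expected = min(a for a, t in spec.spike_times.items() if len(t) and a > 0)
        assert out["rheobase"] == expected

    def test_latency_matches_programmed_onset_delay(self, composed_cell):
        spec, fam, _ = composed_cell
        out = rheobase_and_latency(fam)
        assert out["spike_latency"] == pytest.approx(120.0, abs=0.2)

    def test_silent_cell_has_missing_rheobase(self, passive_cell):
        _, fam, _ = passive_cell
        out = rheobase_and_latency(fam)
        assert out.is_missing("rheobase") and out.is_missing("spike_latency")
        assert out.reasons["rheobase"] == "no spikes"

    def test_amplitude_is_peak_minus_threshold(self, composed_cell):
        _, fam, truth = composed_cell
        out = spike_shape_features(fam)
        assert out["spike_amplitude"] == pytest.approx(60.0, abs=0.5)
        assert out["spike_threshold"] == pytest.approx(-33.0, abs=0.5)

    def test_half_width_recovered(self, composed_cell):
        _, fam, _ = composed_cell
        out = spike_shape_features(fam)
        assert out["spike_width"] == pytest.approx(1.2, abs=0.05)

    def test_slope_extrema_match_realized_shape(self, composed_cell):
        _, fam, truth = composed_cell
        out = spike_shape_features(fam)
        assert out["upstroke"] == pytest.approx(truth["upstroke"], rel=0.10)
        assert out["downstroke"] == pytest.approx(truth["downstroke"], rel=0.10)


class TestAhpFeatures:
    def test_programmed_trough_depth_and_latency(self):
        spec = TraceSpec(ahp_amplitude=20.0, ahp_latency=40.0, ahp_width=60.0,
                         spike_times={70.0: np.array([0.1])})
        fam, _ = compose_trace_family(spec)
        out = ahp_features(fam)
        assert out["ahp_amplitude"] == pytest.approx(20.0, abs=0.5)
        assert out["ahp_latency"] == pytest.approx(40.0, abs=0.5)

    def test_long_half_width_measured_beyond_search_window(self):
        # half-amplitude crossings may fall outside the 100-ms trough window
        spec = TraceSpec(ahp_amplitude=25.0, ahp_latency=60.0, ahp_width=177.9,
                         spike_times={70.0: np.array([0.05])})
        fam, _ = compose_trace_family(spec)
        out = ahp_features(fam)
        assert out["ahp_width"] == pytest.approx(177.9, rel=0.05)

    def test_no_rheobase_marks_all_missing(self, passive_cell):
        _, fam, _ = passive_cell
        out = ahp_features(fam)
        for name in ("ahp_amplitude", "ahp_latency", "ahp_width"):
            assert out.is_missing(name)


class TestRateFeatures:
    def test_single_spike_rate_is_two_hertz(self):
        spec = TraceSpec(spike_times={70.0: np.array([0.1]),
                                      200.0: np.array([0.1])})
        fam, _ = compose_trace_family(spec)
        assert step_rate(fam.sweep_at(70.0)) == 2.0

    def test_regular_train_gives_unit_adaptation_and_zero_cv(self):
        times = np.arange(10) * 0.05 + 0.015
        spec = TraceSpec(spike_times={70.0: np.array([0.1]), 200.0: times})
        fam, _ = compose_trace_family(spec)
        out = rate_features(fam)
        assert out["adaptation_index"] == 1.0
        assert out["cv_isi"] == pytest.approx(0.0, abs=1e-6)

    def test_fi_slope_exact_on_linear_section(self):
        # rates (2, 4, 6) Hz at (70, 80, 90) pA -> slope 0.2 Hz/pA
        spec = TraceSpec(spike_times={
            70.0: np.array([0.05]),
            80.0: np.array([0.05, 0.25]),
            90.0: np.array([0.05, 0.2, 0.35]),
            200.0: np.array([0.05, 0.2, 0.35]),
        })
        fam, _ = compose_trace_family(spec)
        assert rate_features(fam)["fi_slope"] == pytest.approx(0.2, abs=1e-9)

    def test_silent_cell_zero_max_rate_others_missing(self, passive_cell):
        _, fam, _ = passive_cell
        out = rate_features(fam)
        assert out["max_rate"] == 0.0
        for name in ("fi_slope", "adaptation_index", "cv_isi"):
            assert out.is_missing(name)

    def test_adding_second_half_spike_increases_adaptation(self):
        base = {70.0: np.array([0.1]), 200.0: np.array([0.05, 0.15, 0.30])}
        more = {70.0: np.array([0.1]), 200.0: np.array([0.05, 0.15, 0.30, 0.42])}
        a0 = rate_features(compose_trace_family(TraceSpec(spike_times=base))[0])
        a1 = rate_features(compose_trace_family(TraceSpec(spike_times=more))[0])
        assert a1["adaptation_index"] > a0["adaptation_index"]


class TestExtractFeatures:
    def test_full_cell_recovers_all_eighteen(self, composed_cell):
        _, fam, truth = composed_cell
        vec = extract_features(fam)
        assert set(vec.values) == set(EPHYS_FEATURES)
        for name in EPHYS_FEATURES:
            assert not vec.is_missing(name), name

    def test_deterministic_on_repeat(self, composed_cell):
        _, fam, _ = composed_cell
        v1, v2 = extract_features(fam), extract_features(fam)
        assert v1.values == v2.values

    def test_sweep_storage_order_is_irrelevant(self, composed_cell):
        _, fam, _ = composed_cell
        shuffled = StepFamily(fam.cell_id, list(reversed(fam.sweeps)),
                              fam.zero_current_sweep)
        assert extract_features(shuffled).values == extract_features(fam).values

    def test_sampling_rate_robustness(self):
        """Halving dt changes every recovered feature by < 2%."""
        spec = TraceSpec(spike_times={70.0: np.array([0.12]),
                                      200.0: np.array([0.03, 0.15, 0.3, 0.42])})
        v1 = extract_features(compose_trace_family(spec, dt=2.5e-5)[0])
        v2 = extract_features(compose_trace_family(spec, dt=1.25e-5)[0])
        for name in EPHYS_FEATURES:
            a, b = v1[name], v2[name]
            assert math.isfinite(a) == math.isfinite(b)
            if math.isfinite(a):
                assert abs(a - b) <= 0.02 * max(abs(a), abs(b), 1e-9) + 1e-9, name


class TestPhasePlane:
    def test_extrema_match_spike_shape_features(self, composed_cell):
        _, fam, _ = composed_cell
        v, d = phase_plane(fam)
        shape = spike_shape_features(fam)
        assert d.max() == pytest.approx(shape["upstroke"], rel=1e-6)
        assert d.min() == pytest.approx(shape["downstroke"], rel=1e-6)

    def test_constant_trace_has_zero_ordinates(self):
        _, d = phase_curve(flat_sweep())
        assert np.allclose(d, 0.0)

    def test_linear_ramp_has_constant_unit_slope(self):
        dt = 1e-4
        v = -70.0 + np.arange(9000) * dt * 1e3  # 1 mV/ms
        _, d = phase_curve(Sweep(dt, v, 10.0, 0.15))
        assert np.allclose(d, 1.0, atol=1e-9)

    def test_missing_rheobase_gives_empty_curve(self, passive_cell):
        _, fam, _ = passive_cell
        v, d = phase_plane(fam)
        assert v.size == 0 and d.size == 0


class TestQcCheck:
    def test_compliant_recording_passes(self):
        ok, reasons = qc_check(QCRecord(20.0, 22.0, -50.0, -52.0, -55.0))
        assert ok and reasons == []

    def test_access_resistance_violations_both_listed(self):
        ok, reasons = qc_check(QCRecord(20.0, 26.0, -50.0, -52.0, -55.0))
        assert not ok
        assert any("25 MOhm" in r for r in reasons)
        assert any("drift" in r for r in reasons)

    def test_depolarized_resting_potential_fails(self):
        ok, reasons = qc_check(QCRecord(20.0, 21.0, -50.0, -51.0, -38.0))
        assert not ok
        assert any("resting potential" in r for r in reasons)

    def test_offset_magnitude_bound(self):
        ok, reasons = qc_check(QCRecord(20.0, 21.0, -120.0, -125.0, -55.0))
        assert not ok
        assert any("magnitude" in r for r in reasons)
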
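"""Shared fixtures: composed ground-truth cells and small cohorts.

Expensive generated objects are session-scoped so the suite builds each
synthetic dataset once.
"""

from __future__ import annotations

import numpy as np
import pytest

from morphoelec.synth_cohorts import load_calibration, sample_ephys_cohort
from morphoelec.synth_traces import StepProtocol, TraceSpec, compose_trace_family


@pytest.fixture(scope="session")
def profiles():
    return load_calibration()


@pytest.fixture(scope="session")
def composed_cell():
    """One composed cell with a rheobase spike at +70 pA and a 5-spike
    maximal step; returns (spec, family, ground_truth)."""
    spec = TraceSpec(
        rmp=-55.0,
        sag=3.0,
        input_resistance=500.0,
        tau=20.0,
        spike_threshold=-33.0,
        spike_amplitude=60.0,
        spike_width=1.2,
        upstroke=200.0,
        downstroke=-90.0,
        ahp_amplitude=20.0,
        ahp_latency=40.0,
        ahp_width=120.0,
        spike_times={
            70.0: np.array([0.12]),
            200.0: np.array([0.02, 0.10, 0.20, 0.31, 0.42]),
        },
    )
    family, truth = compose_trace_family(spec, cell_id="composed-ref")
    return spec, family, truth


@pytest.fixture(scope="session")
def passive_cell():
    """A silent cell (no spikes anywhere up to +200 pA)."""
    spec = TraceSpec(rmp=-60.0, sag=2.0, input_resistance=300.0, tau=25.0,
                     spike_times={})
    family, truth = compose_trace_family(spec, cell_id="silent-ref")
    return spec, family, truth


@pytest.fixture(scope="session")
def small_cohort(profiles):
    """Ten composed mouse cholinergic-like cells with ground truth."""
    fams, truth = sample_ephys_cohort(profiles["mouse-chol"], n=10, seed=42)
    return fams, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
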
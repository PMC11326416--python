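"""Current-clamp sweep containers and the columnar sweep-file format.

A recording for one cell is a *step family*: an ordered set of sweeps under
the standard protocol (500-ms rectangular steps, -60 to +200 pA in 10-pA
increments, from a -65 mV holding potential), plus an optional zero-current
sweep used for the resting membrane potential.

The on-disk format is plain UTF-8 text, one file per cell::

    # cell_id: m-chol-001
    # dt_s: 0.0001
    # step_onset_s: 0.15
    # step_duration_s: 0.5
    # baseline_mV: -65.0
    t_s	I_-60pA	I_-20pA	...	I_200pA	I_0pA_rest
    0.0000	-65.000	...

Columns are tab-separated; a voltage column ``I_<amp>pA`` holds one sweep,
and ``I_0pA_rest`` is the zero-current sweep.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

PROTOCOL_AMPLITUDES: tuple[int, ...] = tuple(range(-60, 201, 10))
STEP_DURATION_S = 0.5
BASELINE_MV = -65.0

REST_COLUMN = "I_0pA_rest"
_SWEEP_COL_RE = re.compile(r"^I_(-?\d+(?:\.\d+)?)pA$")


class InvalidSweepError(ValueError):
    """Raised for non-uniform, non-finite or structurally invalid sweep data."""


@dataclass
class Sweep:
    """One voltage trace under a rectangular current step.

    Parameters
    ----------
    dt : float
        Sampling interval in seconds (uniform).
    voltage : ndarray
        Membrane potential in mV.
    step_amplitude : float
        Injected current in pA (0 for the rest sweep).
    step_onset, step_duration : float
        Step timing in seconds.
    baseline_target : float
        Holding potential in mV (protocol: -65).
    """

    dt: float
    voltage: np.ndarray
    step_amplitude: float
    step_onset: float
    step_duration: float = STEP_DURATION_S
    baseline_target: float = BASELINE_MV

    def __post_init__(self) -> None:
        self.voltage = np.asarray(self.voltage, dtype=float)
        if self.dt <= 0:
            raise InvalidSweepError("dt must be positive")
        if self.voltage.ndim != 1:
            raise InvalidSweepError("voltage must be one-dimensional")
        if not np.all(np.isfinite(self.voltage)):
            raise InvalidSweepError("voltage contains non-finite samples")
        needed = (self.step_onset + self.step_duration) / self.dt
        if self.voltage.size < needed:
            raise InvalidSweepError(
                f"trace too short: {self.voltage.size} samples < {needed:.0f}"
            )

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.voltage.size) * self.dt

    @property
    def step_offset(self) -> float:
        return self.step_onset + self.step_duration

    def window(self, t0: float, t1: float) -> np.ndarray:
        """Samples with t0 <= t < t1."""
        i0 = max(0, int(np.ceil(t0 / self.dt - 1e-9)))
        i1 = min(self.voltage.size, int(np.ceil(t1 / self.dt - 1e-9)))
        return self.voltage[i0:i1]


@dataclass
class StepFamily:
    """Ordered sweeps for one cell; the unit of electrophysiological analysis."""

    cell_id: str
    sweeps: list[Sweep] = field(default_factory=list)
    zero_current_sweep: Sweep | None = None

    def __post_init__(self) -> None:
        self.sweeps = sorted(self.sweeps, key=lambda s: s.step_amplitude)
        amps = [s.step_amplitude for s in self.sweeps]
        if len(set(amps)) != len(amps):
            raise InvalidSweepError(f"{self.cell_id}: duplicate step amplitudes")
        for required in (-60.0, -20.0):
            if required not in amps:
                raise InvalidSweepError(
                    f"{self.cell_id}: protocol requires a {required:g} pA sweep"
                )
        if not any(a > 0 for a in amps):
            raise InvalidSweepError(f"{self.cell_id}: no positive current step")

    @property
    def amplitudes(self) -> np.ndarray:
        return np.array([s.step_amplitude for s in self.sweeps])

    def sweep_at(self, amplitude: float) -> Sweep:
        for s in self.sweeps:
            if s.step_amplitude == amplitude:
                return s
        raise KeyError(f"no sweep at {amplitude} pA")

    def positive_sweeps(self) -> list[Sweep]:
        return [s for s in self.sweeps if s.step_amplitude > 0]


def write_sweep_file(family: StepFamily, path: str | Path) -> None:
    """Serialize a step family to the columnar sweep format."""
    ref = family.sweeps[0]
    n = min(s.voltage.size for s in family.sweeps)
    cols: list[tuple[str, np.ndarray]] = []
    for s in family.sweeps:
        if abs(s.dt - ref.dt) > 1e-12:
            raise InvalidSweepError("all sweeps in a file must share dt")
        amp = s.step_amplitude
        label = f"I_{amp:g}pA"
        cols.append((label, s.voltage[:n]))
    if family.zero_current_sweep is not None:
        cols.append((REST_COLUMN, family.zero_current_sweep.voltage[:n]))

    buf = io.StringIO()
    buf.write(f"# cell_id: {family.cell_id}\n")
    buf.write(f"# dt_s: {ref.dt:.9g}\n")
    buf.write(f"# step_onset_s: {ref.step_onset:.9g}\n")
    buf.write(f"# step_duration_s: {ref.step_duration:.9g}\n")
    buf.write(f"# baseline_mV: {ref.baseline_target:.9g}\n")
    buf.write("\t".join(["t_s"] + [c[0] for c in cols]) + "\n")
    t = np.arange(n) * ref.dt
    mat = np.column_stack([t] + [c[1] for c in cols])
    np.savetxt(buf, mat, fmt="%.6g", delimiter="\t")
    Path(path).write_text(buf.getvalue())


def read_sweep_file(path: str | Path) -> StepFamily:
    """Parse a columnar sweep file back into a :class:`StepFamily`."""
    text = Path(path).read_text()
    header: dict[str, str] = {}
    lines = text.splitlines()
    i = 0
    while i < len(lines) and lines[i].startswith("#"):
        key, _, value = lines[i][1:].partition(":")
        header[key.strip()] = value.strip()
        i += 1
    if i >= len(lines):
        raise InvalidSweepError(f"{path}: no data section")
    names = lines[i].split("\t")
    if names[0] != "t_s":
        raise InvalidSweepError(f"{path}: first column must be t_s")
    data = np.loadtxt(io.StringIO("\n".join(lines[i + 1:])), ndmin=2)
    if data.shape[1] != len(names):
        raise InvalidSweepError(f"{path}: column count mismatch")

    dt = float(header["dt_s"])
    onset = float(header["step_onset_s"])
    duration = float(header.get("step_duration_s", STEP_DURATION_S))
    baseline = float(header.get("baseline_mV", BASELINE_MV))
    sweeps = []
    rest = None
    for j, name in enumerate(names[1:], start=1):
        if name == REST_COLUMN:
            rest = Sweep(dt, data[:, j], 0.0, onset, duration, baseline)
            continue
        m = _SWEEP_COL_RE.match(name)
        if m is None:
            raise InvalidSweepError(f"{path}: unrecognized column {name!r}")
        sweeps.append(Sweep(dt, data[:, j], float(m.group(1)), onset, duration, baseline))
    return StepFamily(header.get("cell_id", Path(path).stem), sweeps, rest)
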
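"""Calibrated cohort sampling and the two-species study fixture.

Per-cell feature targets are drawn from truncated normal distributions whose
means/SDs live in the packaged calibration file (``data/calibration.yaml``);
the composed-trace generator embeds them exactly (rate-derived features by
dithered integer spike counts, so cohort means stay unbiased), while the
AdEx mode maps targets onto model parameters through a simple monotone
heuristic and records the realized feature values as ground truth.

:func:`make_study_fixture` assembles the full two-species dataset with the
profiled cohort sizes (mouse 48/46 recorded, 31/44 reconstructed; macaque
46 recorded, 52 reconstructed) and a combined-complete subset of 46 macaque
+ 27 mouse cholinergic cells carrying both modalities and a full feature
vector.
"""

from __future__ import annotations

import importlib.resources
import logging
import math
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .ephys import extract_features
from .features import EPHYS_FEATURES, FeatureVector, column_name
from .morphology import Morphology, save_swc
from .synth_morph import MorphGenParams, grow_morphology
from .synth_traces import (
    AdExParams,
    SpecError,
    TraceSpec,
    compose_trace_family,
    simulate_adex,
)
from .sweeps import StepFamily, write_sweep_file

log = logging.getLogger(__name__)


def _stable_hash(name: str) -> int:
    return zlib.crc32(name.encode()) % 997

MAX_RESAMPLE = 100


@dataclass
class Dist:
    """A truncated normal feature distribution."""

    mean: float
    sd: float
    lo: float
    hi: float

    def sample(self, rng: np.random.Generator) -> float:
        if self.sd == 0:
            return float(np.clip(self.mean, self.lo, self.hi))
        for _ in range(1000):
            x = rng.normal(self.mean, self.sd)
            if self.lo <= x <= self.hi:
                return float(x)
        return float(np.clip(self.mean, self.lo, self.hi))


@dataclass
class GroupProfile:
    """Calibrated feature distributions and cohort sizes for one group."""

    name: str
    species: str
    lineage: str
    n_ephys: int
    n_morph: int
    n_complete: int
    ephys: dict[str, Dist] = field(default_factory=dict)
    morph: dict[str, Dist] = field(default_factory=dict)


def load_calibration(path: str | Path | None = None) -> dict[str, GroupProfile]:
    """Load group profiles from the packaged (or a user) calibration file."""
    if path is None:
        ref = importlib.resources.files("morphoelec").joinpath("data/calibration.yaml")
        raw = yaml.safe_load(ref.read_text())
    else:
        raw = yaml.safe_load(Path(path).read_text())
    profiles = {}
    for name, g in raw["groups"].items():
        profiles[name] = GroupProfile(
            name=name,
            species=g["species"],
            lineage=g["lineage"],
            n_ephys=int(g["n_ephys"]),
            n_morph=int(g["n_morph"]),
            n_complete=int(g.get("n_complete", g["n_ephys"])),
            ephys={k: Dist(**v) for k, v in g["ephys"].items()},
            morph={k: Dist(**v) for k, v in g["morph"].items()},
        )
    return profiles


def _dither_round(x: float, rng: np.random.Generator) -> int:
    """Unbiased stochastic rounding: floor(x) + Bernoulli(frac(x))."""
    f = math.floor(x)
    return int(f + (rng.random() < (x - f)))


def _spike_schedule(
    targets: dict[str, float], rng: np.random.Generator
) -> dict[float, np.ndarray]:
    """Per-amplitude threshold-crossing times realizing the rate targets.

    Counts are quantized (rate = 2 x count per 500-ms step) with dithered
    rounding; the maximal step carries the adaptation/CV structure.
    """
    duration_ms = 500.0
    rheo = targets["rheobase"]
    min_isi = max(targets["spike_width"] + 2.5, 9.0)  # ms
    n_cap = int((duration_ms - 20.0) / min_isi)
    n_max = max(1, min(_dither_round(targets["max_rate"] / 2.0, rng), n_cap))

    levels = np.arange(rheo, 200.1, 10.0)
    counts = np.ones(levels.size, dtype=int)
    s = targets["fi_slope"]
    for k in (1, 2):
        if k < levels.size:
            counts[k] = max(1, _dither_round(1 + 5.0 * s * k, rng))
    if levels.size > 3:
        c2 = counts[min(2, levels.size - 1)]
        span = levels[-1] - levels[min(2, levels.size - 1)]
        for j in range(3, levels.size):
            frac = (levels[j] - levels[2]) / span if span > 0 else 1.0
            counts[j] = _dither_round(c2 + (n_max - c2) * frac, rng)
    counts = np.clip(counts, 1, n_max)
    counts = np.maximum.accumulate(counts)
    counts[-1] = n_max

    schedule: dict[float, np.ndarray] = {}
    for amp, c in zip(levels, counts):
        if amp == rheo:
            schedule[float(amp)] = np.array([targets["spike_latency"] * 1e-3])
        elif amp == levels[-1]:
            schedule[float(amp)] = _maximal_step_times(
                int(c), targets["adaptation_index"], targets["cv_isi"], min_isi, rng
            )
        else:
            t0 = rng.uniform(12.0, 25.0)
            times = np.linspace(t0, duration_ms - 8.0, int(c)) * 1e-3
            schedule[float(amp)] = times
    return schedule


def _maximal_step_times(
    n: int, adaptation: float, cv: float, min_isi: float, rng: np.random.Generator
) -> np.ndarray:
    """Spike times on the 200-pA step realizing the half-count ratio and an
    approximate ISI irregularity; realized values are recorded as truth."""
    duration, half = 500.0, 250.0
    t0 = rng.uniform(12.0, 22.0)
    if n == 1:
        return np.array([t0 * 1e-3])
    n1 = int(np.clip(round(n / (1.0 + max(adaptation, 0.0))), 1, n))
    n2 = n - n1
    first = np.linspace(t0, half - 6.0, n1) if n1 > 1 else np.array([t0])
    second = (
        np.linspace(half + 6.0, duration - 6.0, n2) if n2 > 1
        else (np.array([half + (duration - half) / 2.0]) if n2 == 1 else np.empty(0))
    )
    times = np.concatenate([first, second])
    # multiplicative jitter on interior times toward the CV target
    if times.size >= 3 and cv > 0:
        isi = np.diff(times)
        jitter = np.clip(rng.normal(0.0, cv, isi.size), -0.7, 0.7)
        isi = np.maximum(isi * (1.0 + jitter), min_isi)
        cum = t0 + np.concatenate([[0.0], np.cumsum(isi)])
        if cum[-1] > duration - 5.0:
            cum = t0 + (cum - t0) * (duration - 5.0 - t0) / (cum[-1] - t0)
        times = cum
        if np.any(np.diff(times) < min_isi * 0.999):
            times = np.concatenate([first, second])  # fall back to the regular grid
    return np.sort(times) * 1e-3


def draw_trace_spec(profile: GroupProfile, rng: np.random.Generator) -> TraceSpec:
    """One cell's trace specification from a group profile (with feasibility
    resampling of jointly constrained targets)."""
    for attempt in range(MAX_RESAMPLE):
        t = {name: dist.sample(rng) for name, dist in profile.ephys.items()}
        # rheobase lives on the 10-pA protocol grid
        t["rheobase"] = float(
            np.clip(10 * _dither_round(t["rheobase"] / 10.0, rng), 10, 190)
        )
        # the first-spike AHP must complete its half-width inside the step
        if t["spike_latency"] + t["ahp_latency"] + t["ahp_width"] > 470.0:
            t["spike_latency"] = min(
                t["spike_latency"], 470.0 - t["ahp_latency"] - t["ahp_width"]
            )
            if t["spike_latency"] < 10.0:
                continue
        if t["ahp_width"] < 0.6 * t["ahp_latency"] + 2.0:
            continue
        spec = TraceSpec(
            rmp=t["rmp"],
            sag=t["sag"],
            input_resistance=t["input_resistance"],
            tau=t["tau"],
            spike_threshold=t["spike_threshold"],
            spike_amplitude=t["spike_amplitude"],
            spike_width=t["spike_width"],
            upstroke=t["upstroke"],
            downstroke=t["downstroke"],
            ahp_amplitude=t["ahp_amplitude"],
            ahp_latency=t["ahp_latency"],
            ahp_width=t["ahp_width"],
            spike_times=_spike_schedule(t, rng),
        )
        return spec
    raise SpecError(f"no feasible trace spec for {profile.name} after {MAX_RESAMPLE} draws")


def _adex_from_targets(t: TraceSpec) -> AdExParams:
    """Monotone heuristic mapping feature targets onto AdEx parameters."""
    g_leak = 1000.0 / t.input_resistance            # MOhm -> nS
    return AdExParams(
        capacitance=max(t.tau * g_leak, 10.0),      # ms * nS = pF
        g_leak=g_leak,
        e_leak=t.rmp,
        v_t=t.spike_threshold,
        b=2.0 * t.ahp_amplitude,
        tau_w=max(t.ahp_width, 20.0),
        v_reset=t.spike_threshold - t.ahp_amplitude,
    )


def sample_ephys_cohort(
    profile: GroupProfile,
    n: int | None = None,
    mode: str = "composed",
    seed: int = 0,
    dt: float = 2.5e-5,
) -> tuple[dict[str, StepFamily], pd.DataFrame]:
    """Generate ``n`` cells (default: the profiled cohort size).

    Returns (families keyed by cell id, ground-truth feature table).  In
    ``composed`` mode the truth is exact; in ``adex`` mode the extractor's
    own measurements of the simulated traces are recorded as realized truth.
    """
    if mode not in ("composed", "adex"):
        raise ValueError("mode must be 'composed' or 'adex'")
    n = profile.n_ephys if n is None else n
    rng = np.random.default_rng(seed)
    families: dict[str, StepFamily] = {}
    rows = []
    for k in range(n):
        cell_id = f"s{seed}-{profile.name}-e{k:03d}"
        family, truth = _sample_one_cell(profile, mode, rng, dt, cell_id)
        families[cell_id] = family
        rows.append({"cell_id": cell_id, **truth.to_row()})
    table = pd.DataFrame(rows).set_index("cell_id")
    return families, table


def _sample_one_cell(
    profile: GroupProfile, mode: str, rng: np.random.Generator, dt: float, cell_id: str
) -> tuple[StepFamily, FeatureVector]:
    last_err: Exception | None = None
    for attempt in range(MAX_RESAMPLE):
        spec = draw_trace_spec(profile, rng)
        try:
            if mode == "composed":
                return compose_trace_family(spec, dt=dt, cell_id=cell_id)
            family = simulate_adex(_adex_from_targets(spec), cell_id=cell_id)
            return family, extract_features(family)
        except SpecError as err:
            last_err = err
            log.debug("resampling %s (attempt %d): %s", cell_id, attempt, err)
    raise SpecError(f"{cell_id}: no feasible cell after {MAX_RESAMPLE} attempts: {last_err}")


def sample_morph_cohort(
    profile: GroupProfile, n: int | None = None, seed: int = 0
) -> tuple[dict[str, Morphology], pd.DataFrame]:
    """Generate ``n`` trees; returns (morphologies, generator ground truth)."""
    n = profile.n_morph if n is None else n
    rng = np.random.default_rng(seed + 10_000)
    morphs: dict[str, Morphology] = {}
    rows = []
    for k in range(n):
        cell_id = f"s{seed}-{profile.name}-m{k:03d}"
        params = draw_morph_params(profile, rng)
        m, gt = grow_morphology(params, rng)
        morphs[cell_id] = m
        rows.append(
            {
                "cell_id": cell_id,
                "total_length": gt.total_length,
                "n_primary": gt.n_primary,
                "n_branch_points": gt.n_branch_points,
                "kappa": gt.kappa,
            }
        )
    return morphs, pd.DataFrame(rows).set_index("cell_id")


def draw_morph_params(profile: GroupProfile, rng: np.random.Generator) -> MorphGenParams:
    m = profile.morph
    branches = m["n_branch_points"].sample(rng)
    # joint length/area feasibility: the implied radius must stay physical
    for _ in range(MAX_RESAMPLE):
        length = m["total_length"].sample(rng)
        area = m["total_area"].sample(rng)
        radius = area / (2.0 * math.pi * length)
        if 0.08 <= radius <= 2.0:
            break
    radius = float(np.clip(radius, 0.08, 2.0))
    return MorphGenParams(
        n_primary=int(round(m["n_primary"].sample(rng))),
        total_length=length,
        branch_rate=branches / length,
        kappa=m["kappa"].sample(rng),
        radius=radius,
        max_extent=m["max_extent"].sample(rng),
        z_scale=float(m["z_scale"].sample(rng)),
    )


# ---------------------------------------------------------------------------
# the full study fixture
# ---------------------------------------------------------------------------

@dataclass
class StudyFixture:
    """In-memory two-species dataset with metadata and ground truth."""

    seed: int
    ephys: dict[str, StepFamily]
    morphologies: dict[str, Morphology]
    metadata: pd.DataFrame          # indexed by cell_id
    ephys_truth: pd.DataFrame
    morph_truth: pd.DataFrame

    def write(self, outdir: str | Path) -> None:
        """Emit sweep files, SWC files and the metadata CSV."""
        out = Path(outdir)
        (out / "sweeps").mkdir(parents=True, exist_ok=True)
        (out / "swc").mkdir(parents=True, exist_ok=True)
        for cid, fam in self.ephys.items():
            write_sweep_file(fam, out / "sweeps" / f"{cid}.txt")
        for cid, m in self.morphologies.items():
            save_swc(m, out / "swc" / f"{cid}.swc")
        self.metadata.to_csv(out / "metadata.csv")
        self.ephys_truth.to_csv(out / "ephys_truth.csv")
        self.morph_truth.to_csv(out / "morph_truth.csv")


def _truth_is_complete(row: pd.Series) -> bool:
    cols = [column_name(f) for f in EPHYS_FEATURES]
    return bool(row[cols].notna().all())


def _qc_record(rng: np.random.Generator, fail: bool) -> dict[str, float]:
    if not fail:
        ra0 = rng.uniform(8.0, 20.0)
        return {
            "access_resistance_initial": ra0,
            "access_resistance_final": ra0 * rng.uniform(0.9, 1.15),
            "offset_current_initial": rng.uniform(-80.0, -10.0),
            "offset_current_final": 0.0,  # filled below
            "resting_potential": rng.uniform(-70.0, -45.0),
        }
    # one violated criterion, chosen at random
    rec = _qc_record(rng, False)
    mode = rng.integers(0, 3)
    if mode == 0:
        rec["access_resistance_final"] = 30.0
    elif mode == 1:
        rec["offset_current_initial"] = -140.0
    else:
        rec["resting_potential"] = -35.0
    return rec


def make_study_fixture(
    seed: int = 0,
    species: tuple[str, ...] = ("mouse", "macaque"),
    qc_fail_fraction: float = 0.0,
    mode: str = "composed",
    calibration: str | Path | None = None,
    dt: float = 2.5e-5,
    size_factor: float = 1.0,
) -> StudyFixture:
    """Build the complete calibrated study dataset for one seed.

    Cohort sizes follow the calibration profiles; the combined-complete
    subset (both modalities, full 18-feature vector) holds 46 macaque and 27
    mouse cholinergic cells.  Cells whose sampled firing pattern leaves a
    feature undefined (e.g. too few spikes for a CV) are replaced, with a
    log entry, only as far as needed to fill that subset.  ``size_factor``
    scales every cohort proportionally (for reduced-size smoke runs).
    """
    profiles = load_calibration(calibration)
    if size_factor != 1.0:
        for prof in profiles.values():
            prof.n_ephys = max(3, math.ceil(prof.n_ephys * size_factor))
            prof.n_morph = max(3, math.ceil(prof.n_morph * size_factor))
            prof.n_complete = max(2, math.ceil(prof.n_complete * size_factor))
    rng = np.random.default_rng(seed + 50_000)
    ephys: dict[str, StepFamily] = {}
    morphs: dict[str, Morphology] = {}
    truth_tables = []
    morph_truths = []
    meta_rows = []

    for name, profile in profiles.items():
        if profile.species not in species:
            continue
        fams, truth = sample_ephys_cohort(profile, mode=mode, seed=seed * 13 + _stable_hash(name), dt=dt)
        complete_ids = [cid for cid in truth.index if _truth_is_complete(truth.loc[cid])]
        need = min(profile.n_complete, profile.n_ephys)
        top_up = 0
        extra_rng = np.random.default_rng(seed * 17 + 1 + _stable_hash(name))
        while len(complete_ids) < need and top_up < 4 * profile.n_ephys:
            cid = f"s{seed}-{name}-e{profile.n_ephys + top_up:03d}"
            fam, tv = _sample_one_cell(profile, mode, extra_rng, dt, cid)
            top_up += 1
            row = pd.Series(tv.to_row(), name=cid)
            if not _truth_is_complete(row):
                continue
            # replace an incomplete cell so the cohort size stays exact
            incomplete = [c for c in truth.index if c not in complete_ids]
            drop = incomplete[0]
            truth = truth.drop(index=drop)
            del fams[drop]
            truth = pd.concat([truth, row.to_frame().T])
            fams[cid] = fam
            complete_ids.append(cid)
        if len(complete_ids) < need:
            log.warning("%s: only %d complete cells for a target of %d",
                        name, len(complete_ids), need)

        mm, mtruth = sample_morph_cohort(profile, seed=seed * 13 + _stable_hash(name))
        morph_ids = list(mm.keys())

        # pair morphologies with cells: complete cells first
        ephys_ids = complete_ids + [c for c in truth.index if c not in complete_ids]
        n_paired = min(profile.n_morph, profile.n_ephys)
        paired = dict(zip(ephys_ids[:n_paired], morph_ids[:n_paired]))
        qc_fail = rng.random(len(ephys_ids)) < qc_fail_fraction

        for j, cid in enumerate(ephys_ids):
            qc = _qc_record(rng, bool(qc_fail[j]))
            qc["offset_current_final"] = qc["offset_current_initial"] * rng.uniform(0.95, 1.05)
            in_subset = (
                profile.lineage == "cholinergic"
                and cid in complete_ids[:need]
                and cid in paired
            )
            meta_rows.append(
                {
                    "cell_id": cid,
                    "species": profile.species,
                    "lineage": profile.lineage,
                    "group": name,
                    "has_ephys": True,
                    "has_morph": cid in paired,
                    "morph_id": paired.get(cid, ""),
                    "in_combined_subset": in_subset,
                    **qc,
                }
            )
        # morphology-only cells (reconstructed but not analyzed electrically)
        for mid in morph_ids[n_paired:]:
            meta_rows.append(
                {
                    "cell_id": mid,
                    "species": profile.species,
                    "lineage": profile.lineage,
                    "group": name,
                    "has_ephys": False,
                    "has_morph": True,
                    "morph_id": mid,
                    "in_combined_subset": False,
                }
            )
        ephys.update(fams)
        # store morphologies under their owning cell id where paired
        inv = {v: k for k, v in paired.items()}
        for mid in morph_ids:
            morphs[inv.get(mid, mid)] = mm[mid]
        mtruth = mtruth.rename(index=lambda m: inv.get(m, m))
        truth_tables.append(truth)
        morph_truths.append(mtruth)

    metadata = pd.DataFrame(meta_rows).set_index("cell_id")
    return StudyFixture(
        seed=seed,
        ephys=ephys,
        morphologies=morphs,
        metadata=metadata,
        ephys_truth=pd.concat(truth_tables) if truth_tables else pd.DataFrame(),
        morph_truth=pd.concat(morph_truths) if morph_truths else pd.DataFrame(),
    )
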
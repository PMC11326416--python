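"""Canonical feature registries.

Every downstream table (CSV output, cohort statistics, embeddings) draws its
column names from these registries, so the two extraction modules and the
statistics layer agree on naming and units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field


#: The 18 intrinsic electrophysiological features, name -> unit.
EPHYS_FEATURES: dict[str, str] = {
    "rmp": "mV",
    "sag": "mV",
    "input_resistance": "MOhm",
    "tau": "ms",
    "rheobase": "pA",
    "spike_threshold": "mV",
    "spike_amplitude": "mV",
    "spike_width": "ms",
    "spike_latency": "ms",
    "upstroke": "mV_per_ms",
    "downstroke": "mV_per_ms",
    "ahp_amplitude": "mV",
    "ahp_latency": "ms",
    "ahp_width": "ms",
    "fi_slope": "Hz_per_pA",
    "max_rate": "Hz",
    "adaptation_index": "",
    "cv_isi": "",
}

#: The 13 morphometric features, name -> unit.
MORPH_FEATURES: dict[str, str] = {
    "total_area": "um2",
    "total_length": "um",
    "n_primary": "count",
    "length_normalized": "um",
    "n_branch_points": "count",
    "branch_points_normalized": "",
    "n_first_order": "count",
    "n_second_order": "count",
    "mean_root_angle": "rad",
    "centripetal_bias": "",
    "hull_area": "um2",
    "hull_volume": "um3",
    "sphericity": "",
}

ALL_FEATURES: dict[str, str] = {**EPHYS_FEATURES, **MORPH_FEATURES}


def column_name(feature: str) -> str:
    """CSV column name with unit suffix, e.g. ``rmp_mV``."""
    unit = ALL_FEATURES[feature]
    return f"{feature}_{unit}" if unit else feature


def feature_from_column(column: str) -> str | None:
    """Inverse of :func:`column_name`; None for non-feature columns."""
    for name in ALL_FEATURES:
        if column == column_name(name):
            return name
    return None


@dataclass
class FeatureVector:
    """A named feature set with explicit missing-value markers.

    ``values[name]`` is NaN whenever the feature is missing, and
    ``reasons[name]`` then explains why.  Missing features are never
    silently reported as zero.
    """

    registry: dict[str, str]
    values: dict[str, float] = field(default_factory=dict)
    reasons: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in self.registry:
            self.values.setdefault(name, math.nan)

    def set(self, name: str, value: float) -> None:
        if name not in self.registry:
            raise KeyError(f"unknown feature {name!r}")
        self.values[name] = float(value)
        self.reasons.pop(name, None)

    def set_missing(self, name: str, reason: str) -> None:
        if name not in self.registry:
            raise KeyError(f"unknown feature {name!r}")
        self.values[name] = math.nan
        self.reasons[name] = reason

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def is_missing(self, name: str) -> bool:
        return math.isnan(self.values[name])

    def to_row(self) -> dict[str, float]:
        """Mapping from unit-suffixed column names to values (NaN = missing)."""
        return {column_name(n): self.values[n] for n in self.registry}
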
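"""End-to-end orchestration: extract -> QC filter -> compare -> embed ->
classify, with CSV/figure outputs and a machine-readable run summary."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import MorphoElectricProfile, feature_columns
from .ephys import QCRecord, extract_features, qc_check
from .features import EPHYS_FEATURES, MORPH_FEATURES, column_name
from .morphology import load_swc
from .morphometry import extract_morph_features, sholl_profile
from .sweeps import StepFamily, read_sweep_file

log = logging.getLogger(__name__)

QC_COLUMNS = (
    "access_resistance_initial",
    "access_resistance_final",
    "offset_current_initial",
    "offset_current_final",
    "resting_potential",
)


@dataclass
class RunConfig:
    """One reproducible analysis run."""

    ephys_dir: str | Path | None = None
    morph_dir: str | Path | None = None
    ephys_csv: str | Path | None = None
    morph_csv: str | Path | None = None
    metadata_csv: str | Path | None = None
    out_dir: str | Path = "report"
    compare: str = "lineage"          # metadata column with two levels
    seed: int = 1
    apply_qc: bool = True
    n_shuffles: int = 1000
    umap_neighbors: int = 15
    umap_min_dist: float = 0.1
    make_figures: bool = True


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and offending cell."""

    def __init__(self, stage: str, cell_id: str, err: Exception):
        super().__init__(f"stage {stage!r} failed for cell {cell_id!r}: {err}")
        self.stage = stage
        self.cell_id = cell_id


def extract_ephys_table(
    families: dict[str, StepFamily] | str | Path, slope_criterion: float = 10.0
) -> pd.DataFrame:
    """Run the 18-feature extraction over families (or a directory of sweep
    files); returns a table indexed by cell_id with unit-suffixed columns."""
    if not isinstance(families, dict):
        paths = sorted(Path(families).glob("*.txt"))
        families = {p.stem: read_sweep_file(p) for p in paths}
    rows = []
    for cid, fam in families.items():
        try:
            vec = extract_features(fam)
        except Exception as err:
            raise StageError("ephys-extract", cid, err) from err
        rows.append({"cell_id": cid, **vec.to_row()})
    return pd.DataFrame(rows).set_index("cell_id")


def extract_morph_table(
    morphologies: dict | str | Path, resample_step: float = 1.0,
    sholl_step: float = 10.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """13-feature table plus a long-format Sholl table for a set of trees."""
    if not isinstance(morphologies, dict):
        paths = sorted(Path(morphologies).glob("*.swc"))
        morphologies = {p.stem: load_swc(p) for p in paths}
    rows, sholl_rows = [], []
    for cid, m in morphologies.items():
        try:
            vec = extract_morph_features(m, resample_step)
            radii, counts = sholl_profile(m, sholl_step, resample_step)
        except Exception as err:
            raise StageError("morph-extract", cid, err) from err
        rows.append({"cell_id": cid, **vec.to_row()})
        sholl_rows.extend(
            {"cell_id": cid, "radius_um": float(r), "intersections": int(c)}
            for r, c in zip(radii, counts)
        )
    return (
        pd.DataFrame(rows).set_index("cell_id"),
        pd.DataFrame(sholl_rows, columns=["cell_id", "radius_um", "intersections"]),
    )


def apply_qc_filter(metadata: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Evaluate recording QC per cell; returns (passing, failing) metadata."""
    if not all(c in metadata.columns for c in QC_COLUMNS):
        log.info("no QC columns in metadata; all cells pass")
        return metadata, metadata.iloc[0:0]
    results = {}
    for cid, row in metadata.iterrows():
        if row[list(QC_COLUMNS)].isna().any():
            results[cid] = True  # morphology-only cells carry no QC record
            continue
        ok, reasons = qc_check(QCRecord(*[float(row[c]) for c in QC_COLUMNS]))
        results[cid] = ok
        if not ok:
            log.info("QC fail %s: %s", cid, "; ".join(reasons))
    mask = metadata.index.map(results)
    return metadata[mask], metadata[~np.asarray(mask)]


def run_full_analysis(cfg: RunConfig) -> dict:
    """Execute the whole pipeline and write the report bundle.

    Returns the machine-readable summary dictionary (also written to
    ``summary.json`` in the output directory).
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    ephys = None
    families = None
    if cfg.ephys_csv is not None:
        ephys = pd.read_csv(cfg.ephys_csv, index_col="cell_id")
    elif cfg.ephys_dir is not None:
        paths = sorted(Path(cfg.ephys_dir).glob("*.txt"))
        families = {p.stem: read_sweep_file(p) for p in paths}
        ephys = extract_ephys_table(families)
        ephys.to_csv(out / "ephys_features.csv")

    morph = sholl = None
    if cfg.morph_csv is not None:
        morph = pd.read_csv(cfg.morph_csv, index_col="cell_id")
    elif cfg.morph_dir is not None:
        morph, sholl = extract_morph_table(cfg.morph_dir)
        morph.to_csv(out / "morph_features.csv")
        sholl.to_csv(out / "sholl_profiles.csv", index=False)

    if cfg.metadata_csv is None:
        raise ValueError("a metadata CSV (cell_id, group labels, QC) is required")
    metadata = pd.read_csv(cfg.metadata_csv, index_col="cell_id")

    n_in = len(metadata)
    if cfg.apply_qc:
        metadata, failed = apply_qc_filter(metadata)
        n_qc_fail = len(failed)
    else:
        n_qc_fail = 0
    if len(metadata) == 0:
        raise RuntimeError("no cells passed quality control; nothing to analyze")

    tables = [t for t in (ephys, morph) if t is not None]
    if not tables:
        raise ValueError("no feature tables: provide ephys and/or morph inputs")
    merged = metadata[[c for c in metadata.columns if c not in QC_COLUMNS]].copy()
    for t in tables:
        merged = merged.join(t, how="left")
    feats = feature_columns(merged)
    # keep cells with at least one measured feature
    merged = merged[merged[feats].notna().any(axis=1)]

    model = MorphoElectricProfile(merged, cfg.compare, feats)
    results = model.fit(
        seed=cfg.seed,
        n_shuffles=cfg.n_shuffles,
        n_neighbors=cfg.umap_neighbors,
        min_dist=cfg.umap_min_dist,
    )

    results.comparisons.to_csv(out / "comparisons.csv")
    results.embedding.to_csv(out / "embedding.csv")
    results.lda_weights.rename("abs_weight").to_csv(out / "lda_weights.csv")
    pd.DataFrame({"null_loo_accuracy": results.null_scores}).to_csv(
        out / "lda_null.csv", index=False
    )
    (out / "summary.txt").write_text(results.summary() + "\n")

    if cfg.make_figures:
        try:
            from . import plotting

            plotting.feature_panels(merged, cfg.compare, feats,
                                    results.comparisons, out / "feature_panels.png")
            plotting.umap_panel(results, out / "umap.png")
            plotting.lda_panel(results, out / "lda.png")
            if families is not None:
                labels = metadata[cfg.compare].astype(str).to_dict()
                plotting.phase_plot(families, labels, out / "phase_plane.png")
        except Exception as err:  # plotting must never sink a run
            log.warning("figure generation failed: %s", err)

    summary = {
        "software_version": __version__,
        "seed": cfg.seed,
        "compare": cfg.compare,
        "n_cells_in": n_in,
        "n_qc_failed": n_qc_fail,
        "n_cells_analyzed": int(len(merged)),
        "n_dropped_incomplete": results.n_dropped_rows,
        "n_ephys_features": len(EPHYS_FEATURES),
        "n_morph_features": len(MORPH_FEATURES),
        "n_features_tested": int(len(results.comparisons)),
        "significant_features": results.significant_features,
        "n_significant": len(results.significant_features),
        "pca_components_retained": results.n_components,
        "lda_loo_accuracy": results.loo_accuracy,
        "null_quantiles": results.null_quantiles,
        "config": {k: str(v) for k, v in asdict(cfg).items()},
    }
    write_summary(summary, out / "summary.json")
    return summary


def write_summary(summary: dict, path: str | Path) -> None:
    """Write the structured run summary (JSON, self-describing)."""
    Path(path).write_text(json.dumps(summary, indent=2, default=float) + "\n")
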
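"""End-to-end pipeline: metadata summaries, DEG categorization, activity change.

``run_pipeline`` wires the stages together in the order of the two-layer
analysis: (1) compendium summaries of the signature metadata, (2) DEG
counting and cumulative categorization of the z-score signatures with
dose/time stratification and change-fraction geometry.  Every run writes
a JSON manifest recording all parameters and the seed; re-running from
the manifest reproduces all tables bit-identically.
"""

from __future__ import annotations

import json
import logging
import time as _time
from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import activity, deg, io, simulate, summary

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Parameters of one pipeline run.

    Exactly one input mode is active: ``simulate=True`` (generate a
    synthetic compendium from the seed) or paths to a metadata TSV and a
    GCT/GCTX matrix.
    """

    simulate: bool = True
    metadata_path: str | None = None
    matrix_path: str | None = None
    out_dir: str = "lincscope_out"
    seed: int = 0
    signatures_per_cell: int = 222

    cells: list[str] | None = None  # explicit selection; else min_profiles rule
    min_profiles: int = 20
    z_hi: float = deg.Z_HI_DEFAULT
    z_lo: float = deg.Z_LO_DEFAULT
    thresholds: tuple[int, ...] = deg.DEFAULT_THRESHOLDS
    dose_cutoff_um: float = deg.DOSE_CUTOFF_UM
    times_h: tuple[float, ...] = (6.0, 24.0, 48.0)
    convention: str = "stratum"
    slope_tol: float = activity.DEFAULT_SLOPE_TOL
    hist_cap: int = summary.DEFAULT_CAP
    figures: bool = False

    def validate(self) -> None:
        file_mode = self.metadata_path is not None or self.matrix_path is not None
        if self.simulate and file_mode:
            raise ValueError("choose either simulate mode or file mode, not both")
        if not self.simulate and (self.metadata_path is None or self.matrix_path is None):
            raise ValueError("file mode needs both metadata_path and matrix_path")
        if not self.z_lo < self.z_hi:
            raise ValueError("z_lo must be below z_hi")
        if self.convention not in activity.CONVENTIONS:
            raise ValueError(f"unknown convention {self.convention!r}")
        if min(self.thresholds) < 1:
            raise ValueError("category thresholds must be positive")
        if self.dose_cutoff_um <= 0:
            raise ValueError("dose cutoff must be positive")

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)  # YAML superset also covers JSON
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        if isinstance(cfg.thresholds, list):
            cfg.thresholds = tuple(cfg.thresholds)
        if isinstance(cfg.times_h, list):
            cfg.times_h = tuple(float(t) for t in cfg.times_h)
        return cfg


def _write_tsv(frame: pd.DataFrame, path: Path) -> None:
    frame.to_csv(path, sep="\t", index=False)


def _hist_frame(per_cell: dict[str, summary.CappedHistogram]) -> pd.DataFrame:
    rows = []
    for cell, hist in per_cell.items():
        row = {"cell_id": cell}
        row.update(hist.as_series().to_dict())
        rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full two-layer analysis; returns the manifest dict.

    Writes, under ``config.out_dir``: profile counts, category
    distribution, replicate/dose/time multiplicity histograms, the
    cumulative DEG category table, per-cell / dose-group / time
    stratified categories, the activity-change report, and
    ``manifest.json``.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = _time.time()
    outputs: list[str] = []

    def emit(frame: pd.DataFrame, name: str) -> None:
        _write_tsv(frame, out / name)
        outputs.append(name)

    # ------------------------------------------------------------------ input
    if config.simulate:
        sim_config = simulate.default_config(
            seed=config.seed, signatures_per_cell=config.signatures_per_cell
        )
        meta = simulate.simulate_metadata(sim_config)
        matrix, truth = simulate.simulate_signatures(sim_config, meta)
        truth.table.to_csv(out / "planted_truth.tsv", sep="\t", index=False)
        outputs.append("planted_truth.tsv")
    else:
        meta = io.read_metadata(config.metadata_path)
        matrix = io.read_zscore_matrix(config.matrix_path)
    logger.info("input: %d metadata rows, %d x %d matrix [%.1fs]",
                len(meta), matrix.n_genes, matrix.n_signatures, _time.time() - t0)

    # ---------------------------------------------------------------- layer 1
    counts = summary.profile_counts_by_cell(meta)
    emit(counts, "profile_counts.tsv")

    if config.cells is not None:
        cells = list(config.cells)
    else:
        cells = summary.select_highly_profiled(counts, min_profiles=config.min_profiles)
    if not cells:
        raise RuntimeError(
            f"no cell line exceeds min_profiles={config.min_profiles}; nothing to analyze"
        )

    emit(summary.category_distribution(meta, cells).reset_index(), "category_distribution.tsv")
    rep_hists, rep_fraction = summary.replicate_histogram(meta, cells, cap=config.hist_cap)
    emit(_hist_frame(rep_hists), "replicate_histogram.tsv")
    emit(_hist_frame(summary.dose_multiplicity_histogram(meta, cells, cap=config.hist_cap)),
         "dose_multiplicity.tsv")
    time_hist = summary.time_multiplicity_histogram(meta, cap=config.hist_cap)
    emit(_hist_frame({"all": time_hist}), "time_multiplicity.tsv")
    logger.info("layer 1 summaries done [%.1fs]", _time.time() - t0)

    # ---------------------------------------------------------------- layer 2
    analysis_meta = deg.filter_analysis_set(meta, cells, times=config.times_h)
    if analysis_meta.empty:
        raise RuntimeError("analysis set is empty after cell/category/time filtering")
    analysis_ids = set(analysis_meta["sig_id"])
    keep = [i for i, s in enumerate(matrix.sig_ids) if s in analysis_ids]
    sub_matrix = io.SignatureMatrix(
        gene_ids=matrix.gene_ids,
        sig_ids=[matrix.sig_ids[i] for i in keep],
        z=matrix.z[:, keep],
    )
    deg_counts = deg.count_deg(sub_matrix, z_hi=config.z_hi, z_lo=config.z_lo)
    emit(deg_counts, "deg_counts.tsv")

    categories = deg.categorize_counts(deg_counts, analysis_meta, thresholds=config.thresholds)
    emit(categories.as_frame(), "category_counts.tsv")

    strat = {}
    for by, name in (
        ("cell", "by_cell.tsv"),
        ("cell_x_dose_group", "by_cell_dose.tsv"),
        ("cell_x_time", "by_cell_time.tsv"),
    ):
        strat[by] = deg.stratified_category_counts(
            deg_counts,
            analysis_meta,
            by=by,
            thresholds=config.thresholds,
            dose_cutoff_um=config.dose_cutoff_um,
        )
        emit(strat[by], name)
    logger.info("layer 2 categorization done [%.1fs]", _time.time() - t0)

    # --------------------------------------------------------------- activity
    fraction_sets = []
    for cell in cells:
        for contrast, table in (("dose", strat["cell_x_dose_group"]),
                                ("time", strat["cell_x_time"])):
            try:
                fraction_sets.append(
                    activity.compute_change_fractions(
                        table, cell, contrast, convention=config.convention
                    )
                )
            except (ValueError, ZeroDivisionError) as exc:
                logger.warning("cell %s, %s contrast not evaluable: %s", cell, contrast, exc)
    report = activity.activity_change_report(fraction_sets, slope_tol=config.slope_tol)
    emit(report, "activity_change.tsv")

    if config.figures:
        from . import plots

        made = plots.make_all_figures(
            out, counts, summary.category_distribution(meta, cells), rep_hists,
            strat["cell"], report,
        )
        outputs.extend(made)

    manifest = {
        "parameters": asdict(config),
        "replicate_fraction_below_cap": rep_fraction,
        "n_metadata_rows": len(meta),
        "n_analysis_profiles": int(categories.total_profiles),
        "n_analysis_molecules": int(categories.total_molecules),
        "selected_cells": cells,
        "outputs": outputs,
        "runtime_s": round(_time.time() - t0, 3),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    logger.info("pipeline complete [%.1fs]", _time.time() - t0)
    return manifest
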
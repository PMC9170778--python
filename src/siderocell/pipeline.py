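"""End-to-end orchestration: simulate/ingest → segment → measure → correct
→ fuse → analyze.

The pipeline streams one field at a time (blank fields of a pad first, so
the pad blank exists before its cell fields are corrected), so the full
image set never needs to be in memory.  Every output row is traceable to
(condition, time, strain, repeat, field, roi_id), and per-stage cell counts
are logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import correct, fuse, segment, stats
from .synthgen import (
    PHASE_CHANNEL,
    PYOVERDINE_CHANNEL,
    ExperimentConfig,
    FieldMeta,
    SyntheticExperiment,
    generate_experiment,
)

__all__ = [
    "PipelineParams",
    "PipelineResult",
    "run_pipeline",
    "process_fields",
    "recovery_audit",
    "ingest_external",
    "load_field_tree",
]

logger = logging.getLogger(__name__)


@dataclass
class PipelineParams:
    """Knobs for segmentation, correction, fusion and analysis."""

    segmentation: segment.SegmentationParams = field(default_factory=segment.SegmentationParams)
    floor_epsilon: float = 1.0
    min_wildtype: int = 20
    pool_wildtype_repeats: bool = True
    on_threshold_log: float = 1.0
    bimodality_min_cells: int = 100
    correlate_pairs: tuple[tuple[str, str], ...] = (("mcherry", "egfp"),)
    fuse_weighting: str = "repeat"
    trend_start_h: float = 9.0


@dataclass
class PipelineResult:
    """Everything the pipeline emits, as plain DataFrames."""

    cells: pd.DataFrame
    correction: correct.CorrectionContext
    fusion_audit: pd.DataFrame
    summaries: pd.DataFrame
    r_matrix: pd.DataFrame
    trend_tests: dict
    counts: dict

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.cells.to_csv(out / "cells.csv", index=False)
        self.correction.write(out)
        self.fusion_audit.to_csv(out / "fusion_audit.csv", index=False)
        self.summaries.to_csv(out / "stratum_summaries.csv", index=False)
        self.r_matrix.to_csv(out / "r_matrix.csv", index=False)


# ---------------------------------------------------------------------------
# field-level measurement
# ---------------------------------------------------------------------------

def _measure_one_field(
    meta: FieldMeta,
    channels: Mapping[str, np.ndarray],
    labels: np.ndarray,
    blanks: Mapping[str, float],
    fluor_channels: Sequence[str],
) -> pd.DataFrame:
    meas = segment.measure_rois(labels, {ch: channels[ch] for ch in fluor_channels})
    if meas.empty:
        return meas
    meas = correct.apply_pad_blank(meas, blanks, fluor_channels)
    offsets = {
        ch: correct.vignette_offset(
            correct.subtract_pad_blank(channels[ch], blanks[ch]), labels)
        for ch in fluor_channels
    }
    meas = correct.apply_background_correction(meas, offsets, fluor_channels)
    meas.insert(0, "condition", meta.condition)
    meas.insert(1, "time_h", meta.time_h)
    meas.insert(2, "strain", meta.strain)
    meas.insert(3, "repeat", meta.repeat)
    meas.insert(4, "field", meta.field_id)
    return meas


def process_fields(
    fields: Iterable[tuple[FieldMeta, Mapping[str, np.ndarray], np.ndarray | None]],
    fluor_channels: Sequence[str],
    params: PipelineParams,
) -> tuple[pd.DataFrame, correct.CorrectionContext, dict]:
    """Measure and background-correct a stream of fields.

    ``fields`` yields ``(meta, channels, labels_or_None)``; blank fields
    must precede the cell fields of the same pad.  When ``labels`` is None
    the built-in segmenter runs on the phase channel (external label maps
    short-circuit segmentation).
    """
    ctx = correct.CorrectionContext()
    blank_pixels: dict[tuple, dict[str, list]] = {}
    rows = []
    n_rois_raw = 0
    n_fields = 0
    for meta, channels, labels in fields:
        if meta.kind == "blank":
            acc = blank_pixels.setdefault(meta.pad_key, {ch: [] for ch in fluor_channels})
            for ch in fluor_channels:
                acc[ch].append(np.asarray(channels[ch], dtype=float))
            continue
        n_fields += 1
        pad = meta.pad_key
        if pad not in blank_pixels:
            raise ValueError(
                f"cell field {meta} arrived before any blank field of its pad; "
                "cannot estimate the pad blank")
        blanks = {}
        for ch in fluor_channels:
            key = (*pad, ch)
            if key not in ctx.pad_blank:
                ctx.pad_blank[key] = correct.estimate_pad_blank(blank_pixels[pad][ch])
            blanks[ch] = ctx.pad_blank[key]
        if labels is None:
            labels = segment.segment_field(channels[PHASE_CHANNEL], params.segmentation)
            labels = segment.filter_rois(labels, params.segmentation.area_cutoff_px)
        n_rois_raw += int(labels.max())
        meas = _measure_one_field(meta, channels, labels, blanks, fluor_channels)
        if not meas.empty:
            rows.append(meas)
    cells = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame()
    counts = {"cell_fields": n_fields, "rois_measured": int(len(cells)),
              "rois_after_cutoff": n_rois_raw}
    logger.info("measured %d ROIs across %d cell fields", len(cells), n_fields)
    return cells, ctx, counts


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------

def _pad_sorted_fields(exp: SyntheticExperiment):
    """Yield every field of the experiment, blanks of each pad first."""
    metas = sorted(exp.field_metas(), key=lambda m: (m.condition, m.time_h, m.strain,
                                                     m.repeat, m.kind != "blank", m.field_id))
    for meta in metas:
        img = exp.render(meta)
        yield meta, img.channels, None


def run_pipeline(
    config_or_experiment: ExperimentConfig | SyntheticExperiment,
    params: PipelineParams | None = None,
) -> PipelineResult:
    """Run the whole chain on a (synthetic) experiment and analyze it."""
    params = params or PipelineParams()
    if isinstance(config_or_experiment, ExperimentConfig):
        exp = generate_experiment(config_or_experiment)
    else:
        exp = config_or_experiment
    cfg = exp.config
    reporter_channels = list(cfg.population.autofluo_mu)
    fluor_channels = list(reporter_channels)
    if cfg.population.pyoverdine is not None:
        fluor_channels.append(PYOVERDINE_CHANNEL)

    cells, ctx, counts = process_fields(_pad_sorted_fields(exp), fluor_channels, params)
    if cells.empty:
        raise ValueError("pipeline aborted at stage 'measure': no cells detected")

    # step 3a: log transform
    for ch in fluor_channels:
        logs, flagged = correct.log_transform(cells[f"intden_corr_{ch}"],
                                              params.floor_epsilon)
        cells[f"log_intden_{ch}"] = logs
        cells[f"floor_flag_{ch}"] = flagged
    # step 3b: wildtype zeroing (reporter channels only)
    try:
        cells, wt_audit = correct.wildtype_zero(
            cells,
            wildtype_strain=cfg.wildtype.name,
            reporter_channels=reporter_channels,
            min_wildtype=params.min_wildtype,
            pool_repeats=params.pool_wildtype_repeats,
        )
    except ValueError as exc:
        raise ValueError(f"pipeline aborted at stage 'correct': {exc}") from exc
    ctx.wt_median_log = wt_audit
    counts["cells_corrected"] = int(len(cells))

    # fusion across repeats
    value_cols = [f"log_final_{ch}" for ch in reporter_channels]
    if PYOVERDINE_CHANNEL in fluor_channels:
        value_cols.append(f"log_intden_{PYOVERDINE_CHANNEL}")
    if cfg.repeats >= 2:
        # keep the pre-fusion corrected values: ground-truth recovery audits
        # compare against these (the fusion shift is a scale alignment, not
        # part of the per-cell correction chain)
        for col in value_cols:
            cells[f"{col}_unfused"] = cells[col]
        cells, fusion_audit = fuse.fuse_repeats(
            cells, value_cols, global_weighting=params.fuse_weighting)
    else:
        fusion_audit = pd.DataFrame()

    summaries, r_matrix = analyze_cells(cells, reporter_channels, params)
    trend_tests = trend_analyses(summaries, reporter_channels, params)
    counts["strata_summarized"] = int(len(summaries))
    logger.info("pipeline complete: %s", counts)
    return PipelineResult(cells, ctx, fusion_audit, summaries, r_matrix,
                          trend_tests, counts)


def analyze_cells(cells: pd.DataFrame, reporter_channels: Sequence[str],
                  params: PipelineParams) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-stratum summaries and the pairwise-correlation (heatmap) table."""
    sum_rows, r_rows = [], []
    for (cond, t, strain), grp in cells.groupby(["condition", "time_h", "strain"],
                                                sort=True):
        row = {"condition": cond, "time_h": t, "strain": strain, "n_cells": len(grp)}
        for ch in reporter_channels:
            vals = grp[f"log_final_{ch}"].to_numpy()
            row[f"mean_log_{ch}"] = float(np.mean(vals))
            row[f"sd_log_{ch}"] = stats.heterogeneity_sd(vals) if len(vals) > 1 else np.nan
            row[f"on_fraction_{ch}"] = stats.on_fraction(vals, params.on_threshold_log)
            if len(vals) >= params.bimodality_min_cells:
                bi = stats.bimodality_call(vals, min_cells=params.bimodality_min_cells)
                row[f"bimodal_{ch}"] = bi.bimodal
                row[f"delta_bic_{ch}"] = bi.delta_bic
            else:
                row[f"bimodal_{ch}"] = pd.NA
                row[f"delta_bic_{ch}"] = np.nan
        sum_rows.append(row)
        for ch_a, ch_b in params.correlate_pairs:
            a = grp[f"log_final_{ch_a}"].to_numpy()
            b = grp[f"log_final_{ch_b}"].to_numpy()
            if len(a) >= 3 and np.std(a) > 0 and np.std(b) > 0:
                pr = stats.pairwise_correlation(a, b)
                r_rows.append({"condition": cond, "time_h": t, "strain": strain,
                               "pair": f"{ch_a}:{ch_b}", **pr})
    return pd.DataFrame(sum_rows), pd.DataFrame(r_rows)


def trend_analyses(summaries: pd.DataFrame, reporter_channels: Sequence[str],
                   params: PipelineParams) -> dict:
    """Funnel (SD ~ media + time) and post-start-hour expression trends."""
    out: dict = {}
    for ch in reporter_channels:
        df = summaries.dropna(subset=[f"sd_log_{ch}"]).rename(
            columns={f"sd_log_{ch}": "sd_log", f"mean_log_{ch}": "mean_log"})
        if df["condition"].nunique() >= 2 and df["time_h"].nunique() >= 3:
            table = stats.linear_model(df, "sd_log", factors=["condition"],
                                       covariates=["time_h"])
            out[f"funnel_{ch}"] = {
                "time_coef": float(np.polyfit(df["time_h"], df["sd_log"], 1)[0]),
                "F_time": float(table.loc["time_h", "F"]),
                "p_time": float(table.loc["time_h", "PR(>F)"]),
            }
        late = df[df["time_h"] >= params.trend_start_h]
        if late["time_h"].nunique() >= 3:
            out[f"trend_{ch}"] = stats.trend_regression(
                late["mean_log"].to_numpy(), late["time_h"].to_numpy(),
                start_h=params.trend_start_h)
    return out


def recovery_audit(cells: pd.DataFrame, truth: pd.DataFrame,
                   channels: Sequence[str], *, reporter_strains: Sequence[str],
                   max_dist_px: float = 3.0) -> dict:
    """Match measured ROIs to ground-truth cells and score the recovery.

    Returns per-channel Pearson r between the corrected (pre-fusion)
    log(IntDen) and the true log expression, plus pooled segmentation
    recall / precision over the reporter-strain fields.
    """
    pairs: dict[str, list] = {ch: [] for ch in channels}
    n_true = n_meas = n_match = 0
    sel = cells[cells["strain"].isin(reporter_strains)]
    for (cond, t, rep, fld), grp in sel.groupby(["condition", "time_h", "repeat", "field"]):
        tg = truth[(truth["condition"] == cond) & (truth["time_h"] == t)
                   & (truth["repeat"] == rep) & (truth["field"] == fld)
                   & (truth["strain"].isin(reporter_strains))]
        m = segment.match_to_ground_truth(grp, tg, max_dist_px)
        n_true += len(tg)
        n_meas += len(grp)
        n_match += len(m["pairs"])
        for mi, ti in m["pairs"]:
            for ch in channels:
                col = (f"log_final_{ch}_unfused"
                       if f"log_final_{ch}_unfused" in grp.columns else f"log_final_{ch}")
                pairs[ch].append((grp.iloc[mi][col], tg.iloc[ti][f"expr_{ch}"]))
    out = {"recall": n_match / n_true if n_true else float("nan"),
           "precision": n_match / n_meas if n_meas else float("nan"),
           "n_matched": n_match}
    for ch in channels:
        arr = np.asarray(pairs[ch], dtype=float)
        out[f"r_{ch}"] = float(np.corrcoef(arr[:, 0], arr[:, 1])[0, 1]) if len(arr) > 2 else float("nan")
    return out


# ---------------------------------------------------------------------------
# external ingestion (real classifier / FIJI output)
# ---------------------------------------------------------------------------

def ingest_external(
    fields: Iterable[tuple[FieldMeta, Mapping[str, np.ndarray], np.ndarray]],
    fluor_channels: Sequence[str],
    params: PipelineParams | None = None,
) -> tuple[pd.DataFrame, correct.CorrectionContext, dict]:
    """Enter the pipeline at the measurement stage with external label maps.

    Each item is ``(meta, channel images, label map)``; label maps must be
    aligned (same shape) to the fluorescence images, which
    :func:`segment.measure_rois` enforces.  Blank fields (``labels`` ignored)
    must precede their pad's cell fields, as in the main pipeline.
    """
    params = params or PipelineParams()

    def gen():
        for meta, channels, labels in fields:
            if meta.kind == "cells" and labels is None:
                raise ValueError(f"field {meta}: external ingestion requires a label map")
            yield meta, channels, labels

    return process_fields(gen(), fluor_channels, params)


def load_field_tree(root) -> Iterable[tuple[FieldMeta, dict, np.ndarray | None]]:
    """Read a ``{condition}/{time}/{strain}/r{repeat}/`` TIFF tree back in.

    Recognises ``field{N}_{channel}.tif`` / ``blank{N}_{channel}.tif`` and an
    optional ``field{N}_labels.tif`` label map.  Yields blanks of each pad
    before its cell fields.
    """
    import re
    import tifffile

    root = Path(root)
    pat = re.compile(r"(field|blank)(\d+)_([A-Za-z0-9]+)\.tif$")
    by_field: dict[tuple, dict] = {}
    for path in sorted(root.rglob("*.tif")):
        m = pat.match(path.name)
        if not m:
            continue
        kind, fid, ch = m.group(1), int(m.group(2)), m.group(3)
        rel = path.relative_to(root).parts
        if len(rel) != 5:
            raise ValueError(f"unexpected tree layout for {path}; metadata keys missing")
        cond, time_s, strain, rep_s = rel[0], rel[1], rel[2], rel[3]
        meta = FieldMeta(cond, float(time_s), strain, int(rep_s.lstrip("r")), fid,
                         "cells" if kind == "field" else "blank")
        by_field.setdefault(meta.pad_key, {}).setdefault(meta, {})[ch] = tifffile.imread(path)
    for pad in sorted(by_field, key=str):
        metas = sorted(by_field[pad], key=lambda m: (m.kind != "blank", m.field_id))
        for meta in metas:
            chans = by_field[pad][meta]
            labels = chans.pop("labels", None)
            yield meta, {k: v.astype(float) for k, v in chans.items()}, labels
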
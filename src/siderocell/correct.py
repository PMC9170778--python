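"""Three-step fluorescence correction chain for per-cell IntDen values.

Step 1 — agarose-pad autofluorescence: the mean grey value over all pixels
of the pad's empty (cell-free) positions is subtracted from every
fluorescence image of that pad.

Step 2 — vignetting: residual intensity differences across the field of view
are removed per image by subtracting the mean grey value of the area outside
all ROIs from every ROI mean of that image.  Corrected IntDen is the
background-subtracted ROI mean times the ROI area.

Step 3 — cellular autofluorescence: IntDen values are log10-transformed and,
per (condition, time point) stratum, the median log(IntDen) of reporter-free
wildtype cells is subtracted from every cell, so the wildtype median is
exactly zero and values > 0 indicate expression above background.  The
natural pyoverdine channel receives steps 1–2 only, because wildtype cells
fluoresce there too.

Nonpositive corrected IntDen values are floored at a small epsilon before
the log (and flagged), so every log value stays finite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CorrectionContext",
    "estimate_pad_blank",
    "subtract_pad_blank",
    "vignette_offset",
    "apply_pad_blank",
    "apply_background_correction",
    "log_transform",
    "wildtype_zero",
]


@dataclass
class CorrectionContext:
    """Audit record of the correction scalars actually applied.

    ``pad_blank``: (pad key, channel) → mean grey of empty fields.
    ``wt_median_log``: per-stratum wildtype median log10(IntDen) table with
    columns ``condition, time_h, channel, wt_median_log, n_wildtype``.
    """

    pad_blank: dict = field(default_factory=dict)
    wt_median_log: pd.DataFrame | None = None

    def pad_blank_frame(self) -> pd.DataFrame:
        rows = [{"pad": "/".join(str(p) for p in key[:-1]), "channel": key[-1],
                 "blank_mean": v} for key, v in self.pad_blank.items()]
        return pd.DataFrame(rows)

    def write(self, out_dir) -> None:
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.pad_blank_frame().to_csv(out / "pad_blanks.csv", index=False)
        if self.wt_median_log is not None:
            self.wt_median_log.to_csv(out / "wildtype_medians.csv", index=False)


def estimate_pad_blank(empty_fields: Sequence[np.ndarray]) -> float:
    """Mean grey over all pixels of all empty fields of one pad and channel."""
    if len(empty_fields) == 0:
        raise ValueError("at least one empty (cell-free) field is required")
    if len(empty_fields) < 4:
        warnings.warn(
            f"only {len(empty_fields)} empty field(s); 4 or more are recommended",
            stacklevel=2,
        )
    total = 0.0
    npix = 0
    for img in empty_fields:
        a = np.asarray(img, dtype=float)
        total += a.sum()
        npix += a.size
    return total / npix


def subtract_pad_blank(field_image: np.ndarray, blank: float) -> np.ndarray:
    """Pixelwise image − blank. Values may go negative; nothing is clipped."""
    if blank < 0:
        raise ValueError("blank must be >= 0")
    return np.asarray(field_image, dtype=float) - blank


def vignette_offset(field_image: np.ndarray, label_map: np.ndarray) -> float:
    """Mean grey over all pixels outside every ROI of this image."""
    img = np.asarray(field_image, dtype=float)
    labels = np.asarray(label_map)
    if img.shape != labels.shape:
        raise ValueError("image and label map shapes differ")
    outside = labels == 0
    if not outside.any():
        raise ValueError("no pixels outside ROIs; cannot estimate vignetting offset")
    return float(img[outside].mean())


def apply_pad_blank(rois: pd.DataFrame, blanks: Mapping[str, float],
                    channels: Sequence[str]) -> pd.DataFrame:
    """ROI-level step 1: ``mean_blanked_{ch} = mean_{ch} − blank[ch]``.

    Subtracting a scalar from every pixel shifts the ROI mean by the same
    scalar, so applying the blank at ROI level is exact.
    """
    out = rois.copy()
    for ch in channels:
        out[f"mean_blanked_{ch}"] = out[f"mean_{ch}"] - blanks[ch]
    return out


def apply_background_correction(rois: pd.DataFrame,
                                offsets: Mapping[str, float],
                                channels: Sequence[str]) -> pd.DataFrame:
    """ROI-level step 2 for one field.

    ``mean_bgsub = mean_blanked − offset``; ``intden_corr = mean_bgsub × area``.
    """
    out = rois.copy()
    for ch in channels:
        src = f"mean_blanked_{ch}" if f"mean_blanked_{ch}" in out.columns else f"mean_{ch}"
        out[f"mean_bgsub_{ch}"] = out[src] - offsets[ch]
        out[f"intden_corr_{ch}"] = out[f"mean_bgsub_{ch}"] * out["area_px"]
    return out


def log_transform(intden_corrected, floor_epsilon: float = 1.0):
    """log10 with a positive floor: returns ``(log10 values, floored flags)``."""
    if floor_epsilon <= 0:
        raise ValueError("floor_epsilon must be > 0")
    x = np.asarray(intden_corrected, dtype=float)
    flagged = x < floor_epsilon
    return np.log10(np.maximum(x, floor_epsilon)), flagged


def wildtype_zero(
    cells: pd.DataFrame,
    *,
    wildtype_strain: str,
    reporter_channels: Sequence[str],
    strain_col: str = "strain",
    stratum_keys: Sequence[str] = ("condition", "time_h"),
    min_wildtype: int = 20,
    pool_repeats: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Step 3: subtract the per-stratum wildtype median log(IntDen).

    ``cells`` must carry ``log_intden_{ch}`` columns.  Adds
    ``log_final_{ch} = log_intden_{ch} − wt_median`` for each reporter
    channel; the pyoverdine channel is never passed here.  Returns the
    corrected table and the wildtype-median audit table.

    With ``pool_repeats`` (default) medians pool wildtype cells across
    repeats within each (condition, time point); otherwise ``repeat`` is an
    additional stratum key.
    """
    keys = list(stratum_keys)
    if not pool_repeats and "repeat" not in keys:
        keys = keys + ["repeat"]
    wt = cells[cells[strain_col] == wildtype_strain]
    if wt.empty:
        raise ValueError(f"no wildtype cells (strain {wildtype_strain!r}) in table")

    med_rows = []
    medians: dict[tuple, dict[str, float]] = {}
    for stratum, grp in wt.groupby(keys, sort=False):
        stratum = stratum if isinstance(stratum, tuple) else (stratum,)
        if len(grp) < min_wildtype:
            warnings.warn(
                f"stratum {dict(zip(keys, stratum))}: only {len(grp)} wildtype "
                f"cells (minimum {min_wildtype})",
                stacklevel=2,
            )
        medians[stratum] = {}
        for ch in reporter_channels:
            med = float(grp[f"log_intden_{ch}"].median())
            medians[stratum][ch] = med
            med_rows.append({**dict(zip(keys, stratum)), "channel": ch,
                             "wt_median_log": med, "n_wildtype": len(grp)})
    audit = pd.DataFrame(med_rows)

    out = cells.copy()
    strata = out[keys].apply(tuple, axis=1)
    missing = sorted(set(strata) - set(medians))
    if missing:
        raise ValueError(
            "no wildtype cells for stratum/strata: "
            + "; ".join(str(dict(zip(keys, s))) for s in missing)
        )
    for ch in reporter_channels:
        med_map = {s: v[ch] for s, v in medians.items()}
        out[f"log_final_{ch}"] = out[f"log_intden_{ch}"] - strata.map(med_map)
    return out, audit
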
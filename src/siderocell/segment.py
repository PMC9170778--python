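"""Cell detection in phase-contrast fields and per-ROI fluorescence measurement.

A deterministic stand-in for a trained pixel classifier: global thresholding
(Otsu by default) on the phase image, morphological opening, 8-connected
component labelling, removal of border-touching objects, and an area cut-off
that discards debris-sized regions.  Per ROI and channel we report the mean
grey value and the integrated density, IntDen = mean grey × area — the
standard ImageJ/FIJI per-cell fluorescence measure.

Externally produced label maps (e.g. from a trained classifier) can be fed
straight into :func:`measure_rois`; the segmenter here is only one way to
obtain them.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage.filters import threshold_otsu
from skimage.measure import label as sk_label
from skimage.morphology import disk, opening
from skimage.segmentation import clear_border, relabel_sequential

__all__ = [
    "SegmentationParams",
    "segment_field",
    "filter_rois",
    "measure_rois",
    "match_to_ground_truth",
]


@dataclass
class SegmentationParams:
    """Thresholding segmenter settings.

    ``cells_are_dark``: phase contrast renders cells darker than background.
    ``area_cutoff_px``: minimum ROI area in px² (debris exclusion).
    """

    cells_are_dark: bool = True
    opening_radius: int = 1
    area_cutoff_px: int = 30
    connectivity: int = 2  # skimage convention: 2 == 8-connectivity in 2-D


def segment_field(phase_image: np.ndarray,
                  params: SegmentationParams | None = None) -> np.ndarray:
    """Label cells in a single-channel 2-D phase-contrast image.

    Returns an int32 label map (0 = background) with 8-connected components
    and border-touching objects removed.  A constant image yields zero labels.
    """
    img = np.asarray(phase_image, dtype=float)
    if img.ndim != 2:
        raise ValueError(f"expected a 2-D single-channel image, got ndim={img.ndim}")
    params = params or SegmentationParams()
    if np.ptp(img) == 0:
        return np.zeros(img.shape, dtype=np.int32)
    thr = threshold_otsu(img)
    mask = img < thr if params.cells_are_dark else img > thr
    if params.opening_radius > 0:
        mask = opening(mask, disk(params.opening_radius))
    mask = clear_border(mask)
    return sk_label(mask, connectivity=params.connectivity).astype(np.int32)


def filter_rois(label_map: np.ndarray, area_cutoff_px: int) -> np.ndarray:
    """Drop regions smaller than the area cut-off; relabel consecutively."""
    if area_cutoff_px < 0:
        raise ValueError("area_cutoff_px must be >= 0")
    labels = np.asarray(label_map).copy()
    if area_cutoff_px > 1 and labels.max() > 0:
        areas = np.bincount(labels.ravel())
        small = np.flatnonzero(areas < area_cutoff_px)
        labels[np.isin(labels, small[small > 0])] = 0
    out, _, _ = relabel_sequential(labels)
    return out.astype(np.int32)


def measure_rois(label_map: np.ndarray,
                 channel_images: Mapping[str, np.ndarray]) -> pd.DataFrame:
    """Per-ROI mean grey and IntDen for every channel.

    One row per ROI with ``roi_id``, ``area_px``, centroid (pixel-centred,
    (row, col), 0-based) and, per channel ``ch``, ``mean_{ch}`` and
    ``intden_{ch} = mean_{ch} * area_px``.
    """
    labels = np.asarray(label_map)
    for name, img in channel_images.items():
        if np.asarray(img).shape != labels.shape:
            raise ValueError(
                f"channel {name!r} shape {np.asarray(img).shape} does not match "
                f"label map shape {labels.shape}")
    ids = np.arange(1, labels.max() + 1) if labels.max() > 0 else np.array([], dtype=int)
    if ids.size == 0:
        cols = ["roi_id", "area_px", "centroid_row", "centroid_col"]
        for ch in channel_images:
            cols += [f"mean_{ch}", f"intden_{ch}"]
        return pd.DataFrame(columns=cols)
    areas = ndimage.sum_labels(np.ones_like(labels, dtype=float), labels, ids)
    centroids = ndimage.center_of_mass(np.ones_like(labels, dtype=float), labels, ids)
    centroids = np.asarray(centroids, dtype=float)
    out = pd.DataFrame({
        "roi_id": ids,
        "area_px": areas.astype(float),
        "centroid_row": centroids[:, 0],
        "centroid_col": centroids[:, 1],
    })
    for ch, img in channel_images.items():
        means = ndimage.mean(np.asarray(img, dtype=float), labels, ids)
        out[f"mean_{ch}"] = means
        out[f"intden_{ch}"] = means * out["area_px"].to_numpy()
    return out


def match_to_ground_truth(measurements: pd.DataFrame,
                          truth: pd.DataFrame,
                          max_dist_px: float = 3.0) -> dict:
    """Greedy one-to-one centroid matching of measured ROIs to true cells.

    ``truth`` needs ``row``/``col`` columns (true rod centres).  Returns a
    dict with the matched index pairs, distances, and recall / precision
    (true cells recovered / ROIs that are true cells).
    """
    mrows = measurements[["centroid_row", "centroid_col"]].to_numpy(dtype=float)
    trows = truth[["row", "col"]].to_numpy(dtype=float)
    if len(trows) == 0 or len(mrows) == 0:
        return {"pairs": [], "distances": np.array([]),
                "recall": 0.0 if len(trows) else float("nan"),
                "precision": 0.0 if len(mrows) else float("nan")}
    tree = cKDTree(trows)
    dist, idx = tree.query(mrows, k=1)
    order = np.argsort(dist)
    used_t: set[int] = set()
    pairs, dists = [], []
    for i in order:
        if dist[i] > max_dist_px:
            break
        if int(idx[i]) in used_t:
            continue
        used_t.add(int(idx[i]))
        pairs.append((int(i), int(idx[i])))
        dists.append(float(dist[i]))
    n_match = len(pairs)
    return {
        "pairs": pairs,
        "distances": np.asarray(dists),
        "recall": n_match / len(trows),
        "precision": n_match / len(mrows),
    }
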
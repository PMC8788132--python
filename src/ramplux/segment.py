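"""Activity-threshold segmentation of calcium movies.

A pixel counts as active when its temporal maximum reaches 175% of its
temporal mean (a minimum change of 75% over that pixel's average
intensity). Active pixels are grouped into 8-connected components, split
where a pixel's trace decorrelates from its component's mean trace, and
summarized as an active-area fraction relative to a total labeled-input
mask, plus per-anatomical-layer ROI tallies from a user-supplied label
mask.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage

#: detection threshold: max >= (threshold_pct/100) * temporal mean
THRESHOLD_PCT = 175.0
EIGHT_CONN = np.ones((3, 3), dtype=bool)


@dataclass
class ROISet:
    """Disjoint 8-connected active ROIs of a movie."""

    labels: np.ndarray  # H x W int mask, 0 = background
    traces: Dict[int, np.ndarray]  # ROI id -> mean trace

    @property
    def n_rois(self) -> int:
        return len(self.traces)

    @property
    def ids(self) -> List[int]:
        return sorted(self.traces)

    def sizes(self) -> Dict[int, int]:
        return {i: int((self.labels == i).sum()) for i in self.ids}

    def total_area_px(self) -> int:
        return int((self.labels > 0).sum())


def active_pixel_mask(
    movie: np.ndarray,
    threshold_pct: float = THRESHOLD_PCT,
    mode: str = "ratio",
) -> np.ndarray:
    """Pixels whose activity clears the detection threshold.

    ``mode="ratio"`` (default): active iff max over time >=
    (threshold_pct/100) x the pixel's temporal mean — the multiplicative
    reading of a 175% detection threshold. ``mode="dff"``: active iff
    (max - mean)/mean >= (threshold_pct - 100)/100, provided for data
    where a delta-F-over-F criterion is preferred (identical for
    positive-mean pixels; differs only in how non-positive means are
    handled upstream).
    """
    movie = np.asarray(movie, dtype=float)
    if movie.ndim != 3 or movie.shape[0] < 2:
        raise ValueError("movie must be a T x H x W stack with T >= 2")
    mean = movie.mean(axis=0)
    mx = movie.max(axis=0)
    bad = mean <= 0
    if bad.any():
        warnings.warn(f"{int(bad.sum())} pixels with non-positive temporal "
                      "mean excluded from activity detection")
    if mode == "ratio":
        act = mx >= (threshold_pct / 100.0) * mean
    elif mode == "dff":
        with np.errstate(divide="ignore", invalid="ignore"):
            act = (mx - mean) / mean >= (threshold_pct - 100.0) / 100.0
    else:
        raise ValueError("mode must be 'ratio' or 'dff'")
    act[bad] = False
    return act


def _refine(
    pixels: np.ndarray,  # (n, 2) row/col indices of one candidate group
    movie: np.ndarray,
    corr_min: float,
    depth: int = 0,
) -> List[np.ndarray]:
    """Split a pixel group until every pixel tracks its group's mean trace."""
    if pixels.shape[0] == 0:
        return []
    tr = movie[:, pixels[:, 0], pixels[:, 1]]  # T x n
    if pixels.shape[0] == 1 or depth > 8:
        return [pixels]
    mean = tr.mean(axis=1)
    cor = _corr_with(tr, mean)
    ok = cor >= corr_min
    if not ok.any():
        # no pixel tracks the (possibly self-cancelling) mean: re-seed on
        # the highest-variance pixel and partition by correlation with it
        ref = tr[:, int(np.argmax(tr.var(axis=0)))]
        cor = _corr_with(tr, ref)
        ok = cor >= corr_min
    if ok.all() or not ok.any():
        return [pixels]
    # a low-correlation subgroup is split off only if its own mean trace
    # decorrelates from the rest: single-pixel noise does not fragment ROIs
    m_in = tr[:, ok].mean(axis=1)
    m_out = tr[:, ~ok].mean(axis=1)
    if _corr_with(m_out[:, None], m_in)[0] >= corr_min:
        return [pixels]
    return _refine(pixels[ok], movie, corr_min, depth + 1) + _refine(
        pixels[~ok], movie, corr_min, depth + 1
    )


def _corr_with(tr: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Pearson correlation of each column of ``tr`` with ``ref``."""
    t = tr - tr.mean(axis=0)
    r = ref - ref.mean()
    denom = np.sqrt((t**2).sum(axis=0) * (r**2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        c = (t * r[:, None]).sum(axis=0) / denom
    return np.nan_to_num(c)


def group_rois(
    mask: np.ndarray,
    movie: np.ndarray,
    min_size_px: int = 4,
    corr_min: float = 0.7,
) -> ROISet:
    """Group active pixels into ROIs.

    8-connected components of the active mask are split wherever a pixel's
    trace correlates below ``corr_min`` with its component's mean trace
    (recursively, so adjacent regions with distinct dynamics separate);
    fragments smaller than ``min_size_px`` are discarded.
    """
    lab, n = ndimage.label(mask, structure=EIGHT_CONN)
    groups: List[np.ndarray] = []
    for k in range(1, n + 1):
        pix = np.argwhere(lab == k)
        groups.extend(_refine(pix, np.asarray(movie, dtype=float), corr_min))
    out = np.zeros_like(lab)
    traces: Dict[int, np.ndarray] = {}
    nxt = 1
    for pix in groups:
        # a split may leave a spatially disconnected fragment set
        sub = np.zeros(mask.shape, dtype=bool)
        sub[pix[:, 0], pix[:, 1]] = True
        sl, sn = ndimage.label(sub, structure=EIGHT_CONN)
        for j in range(1, sn + 1):
            comp = sl == j
            if comp.sum() < min_size_px:
                continue
            out[comp] = nxt
            traces[nxt] = movie[:, comp].mean(axis=1)
            nxt += 1
    return ROISet(labels=out, traces=traces)


def segment_movie(
    movie: np.ndarray,
    threshold_pct: float = THRESHOLD_PCT,
    min_size_px: int = 4,
    corr_min: float = 0.7,
    mode: str = "ratio",
) -> Tuple[ROISet, np.ndarray]:
    """Full segmentation: activity mask then ROI grouping."""
    mask = active_pixel_mask(movie, threshold_pct=threshold_pct, mode=mode)
    return group_rois(mask, movie, min_size_px=min_size_px, corr_min=corr_min), mask


def active_area_fraction(rois: ROISet, total_mask: np.ndarray) -> float:
    """Active ROI area relative to the total labeled-input area."""
    total = int(np.asarray(total_mask, dtype=bool).sum())
    if total == 0:
        raise ValueError("total mask is empty")
    return rois.total_area_px() / total


def layer_tally(rois: ROISet, layer_mask: np.ndarray) -> pd.DataFrame:
    """Count ROIs per anatomical layer of an integer-labeled mask.

    Each ROI is assigned to the layer under its centroid; if the centroid
    lands outside every layer (label 0) the ROI goes to the layer holding
    the majority of its pixels, and to ``unassigned`` when no layer
    overlaps it at all.
    """
    layer_mask = np.asarray(layer_mask)
    if layer_mask.shape != rois.labels.shape:
        raise ValueError("layer mask shape must match ROI mask shape")
    counts: Dict[object, int] = {}
    for i in rois.ids:
        comp = rois.labels == i
        r, c = np.argwhere(comp).mean(axis=0)
        layer = int(layer_mask[int(round(r)), int(round(c))])
        if layer == 0:
            vals = layer_mask[comp]
            vals = vals[vals > 0]
            layer = int(np.bincount(vals).argmax()) if vals.size else 0
        key = layer if layer > 0 else "unassigned"
        counts[key] = counts.get(key, 0) + 1
    return pd.DataFrame(
        [{"layer": k, "n_rois": v} for k, v in sorted(counts.items(), key=str)]
    )
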
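"""Synapse counting by puncta colocalization in two-channel images.

A structurally complete synapse is scored where a presynaptic marker
punctum (e.g. VGAT, VGlut1) spatially overlaps a postsynaptic scaffold
punctum (gephyrin, PSD95) in a single-plane field of view (66.5 x 66.5 µm
by default).  Per channel, puncta are segmented by background subtraction,
Otsu thresholding and an area gate; colocalization is the count of
presynaptic puncta sharing at least ``min_overlap_px`` pixels with any
postsynaptic punctum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.morphology import disk, white_tophat


@dataclass(frozen=True)
class SegmentationParams:
    background_radius_px: int = 10  # top-hat structuring radius
    min_area_px: int = 4
    max_area_px: int = 400
    pixel_size_um: float = 0.1


@dataclass(frozen=True)
class PunctaImage:
    """Two-channel field: presynaptic and postsynaptic marker intensities."""

    pre: np.ndarray
    post: np.ndarray
    pixel_size_um: float = 0.1
    field_um: float = 66.5

    def __post_init__(self) -> None:
        if self.pre.shape != self.post.shape:
            raise ValueError("channels must have the same shape")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel size must be positive")


@dataclass
class SynapseCountResult:
    n_pre: int
    n_post: int
    n_colocalized: int

    def __post_init__(self) -> None:
        if self.n_colocalized > min(self.n_pre, self.n_post):
            raise ValueError("colocalized count cannot exceed either channel count")


def segment_puncta(channel: np.ndarray, params: SegmentationParams | None = None) -> np.ndarray:
    """Labeled puncta mask of one channel.

    Rolling-ball-style background removal (white top-hat), Otsu threshold,
    connected components, area gate.  A constant (e.g. saturated) image
    yields zero puncta with a warning.
    """
    params = params or SegmentationParams()
    img = np.asarray(channel, dtype=float)
    if img.size == 0:
        raise ValueError("empty image")
    if np.ptp(img) == 0:
        warnings.warn("constant image: no puncta detectable")
        return np.zeros(img.shape, dtype=np.int32)
    footprint = disk(params.background_radius_px, decomposition="sequence")
    flat = white_tophat(img, footprint=footprint)
    if np.ptp(flat) == 0:
        warnings.warn("image has no local structure after background removal")
        return np.zeros(img.shape, dtype=np.int32)
    mask = flat > threshold_otsu(flat)
    lab = cc_label(mask, connectivity=2)
    areas = np.bincount(lab.ravel())
    bad = np.flatnonzero((areas < params.min_area_px) | (areas > params.max_area_px))
    lab[np.isin(lab, bad[bad > 0])] = 0
    return cc_label(lab > 0, connectivity=2).astype(np.int32)


def count_colocalized(
    pre_mask: np.ndarray, post_mask: np.ndarray, min_overlap_px: int = 1
) -> SynapseCountResult:
    """Count presynaptic puncta overlapping postsynaptic puncta.

    Each presynaptic punctum counts at most once, regardless of how many
    postsynaptic puncta it touches.
    """
    if pre_mask.shape != post_mask.shape:
        raise ValueError("masks must have the same shape")
    n_pre = int(pre_mask.max())
    n_post = int(post_mask.max())
    if n_pre == 0 or n_post == 0:
        return SynapseCountResult(n_pre, n_post, 0)
    overlap_px = np.bincount(pre_mask[(pre_mask > 0) & (post_mask > 0)], minlength=n_pre + 1)
    n_coloc = int(np.sum(overlap_px[1:] >= min_overlap_px))
    return SynapseCountResult(n_pre, n_post, n_coloc)


def count_synapses(image: PunctaImage, params: SegmentationParams | None = None,
                   min_overlap_px: int = 1) -> SynapseCountResult:
    """Segment both channels and count colocalized puncta."""
    pre = segment_puncta(image.pre, params)
    post = segment_puncta(image.post, params)
    return count_colocalized(pre, post, min_overlap_px)


def condition_percent_change(
    counts: dict[str, np.ndarray], control: str = "control", n_comparisons: int | None = None
) -> pd.DataFrame:
    """Percent change of per-field synapse density vs the control condition.

    ``counts`` maps condition name -> per-field synapse counts (>= 5 fields
    each).  Densities are normalized to the control median; the table
    reports median percent change, the 25-75% IQR, and a Bonferroni-adjusted
    Kruskal-Wallis p value per treated condition.
    """
    from .stats import bonferroni, kruskal_wallis

    if control not in counts:
        raise ValueError(f"control condition {control!r} missing")
    for name, vals in counts.items():
        if len(vals) < 5:
            raise ValueError(f"condition {name!r} has fewer than 5 fields")
    ref = np.asarray(counts[control], dtype=float)
    ref_med = np.median(ref)
    if ref_med == 0:
        raise ValueError("control median density is zero")
    treated = [c for c in counts if c != control]
    m = n_comparisons if n_comparisons is not None else max(1, len(treated))
    rows = []
    for name in counts:
        vals = 100.0 * (np.asarray(counts[name], dtype=float) - ref_med) / ref_med
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        if name == control:
            p_adj = np.nan
        else:
            _, p = kruskal_wallis([ref, np.asarray(counts[name], dtype=float)])
            p_adj = bonferroni([p], m)[0]
        rows.append(
            {
                "condition": name,
                "median_pct_change": med,
                "iqr_low": q1,
                "iqr_high": q3,
                "n_fields": len(counts[name]),
                "p_adj": p_adj,
            }
        )
    return pd.DataFrame(rows)
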
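"""Cell segmentation, cross-sectional areas, and swelling quantification.

Cells are segmented from the membrane-dye channel when available (the dye
stains every cell, so non-transfected cells are measured too), with the
tagged-protein channel as fallback. Swelling is expressed as the post-challenge
cross-sectional area as a percentage of the pre-challenge area (100 = no
change), matched per cell between the two frames.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops

log = logging.getLogger(__name__)

__all__ = [
    "AreaMeasurement",
    "segment_cells",
    "segmentation_background",
    "classify_transfected",
    "match_cells",
    "area_change",
    "measure_swelling",
]

MIN_PARTICLE_PX = 50
MATCH_MAX_DISPLACEMENT_FRAC = 0.25  # of the mean cell equivalent diameter


@dataclass
class AreaMeasurement:
    """Per-cell area pair; ``area_change_pct`` is 100 * post / pre."""

    cell_id: int
    area_pre: float  # µm²
    area_post: float  # µm²
    transfected: bool

    @property
    def area_change_pct(self) -> float:
        return 100.0 * self.area_post / self.area_pre


def segment_cells(image: np.ndarray, min_size: int = MIN_PARTICLE_PX) -> np.ndarray:
    """Particle detection: Otsu threshold, hole filling, 8-connected labelling.

    Components smaller than ``min_size`` pixels are removed. Labels are
    assigned in raster order of component centroids so repeated calls on the
    same field of view are stable. Returns an int label image (0=background);
    an image with no detectable cells yields an all-zero label image.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("segment_cells expects a 2D image")
    if np.ptp(img) == 0:
        return np.zeros(img.shape, dtype=np.int32)
    mask = img > threshold_otsu(img)
    mask = ndimage.binary_fill_holes(mask)
    lab = label(mask, connectivity=2)
    props = [p for p in regionprops(lab) if p.area >= min_size]
    props.sort(key=lambda p: (p.centroid[0], p.centroid[1]))
    out = np.zeros(img.shape, dtype=np.int32)
    for new_id, p in enumerate(props, start=1):
        out[lab == p.label] = new_id
    return out


def segmentation_background(image: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """(mode, sd) of the intensity distribution outside all labelled cells."""
    vals = np.asarray(image, dtype=float)[labels == 0]
    if vals.size == 0:
        return 0.0, 0.0
    if np.ptp(vals) == 0:
        return float(vals[0]), 0.0
    hist, edges = np.histogram(vals, bins=256)
    i = int(np.argmax(hist))
    return float(0.5 * (edges[i] + edges[i + 1])), float(vals.std())


def classify_transfected(
    cell_mask: np.ndarray,
    protein_channel: np.ndarray,
    background_mode: float,
    background_sd: float,
) -> bool:
    """A cell is transfected iff its mean tagged-protein intensity strictly
    exceeds background mode + 3 * background SD (ties break non-transfected)."""
    mean = float(np.asarray(protein_channel, dtype=float)[cell_mask].mean())
    return mean > background_mode + 3.0 * background_sd


def match_cells(
    labels_pre: np.ndarray, labels_post: np.ndarray
) -> list[tuple[int, int]]:
    """Greedy nearest-centroid matching of cells between two frames.

    Pairs are accepted closest-first while both members are unused and their
    centroid displacement is below 25% of the mean cell equivalent diameter;
    unmatched cells are dropped with a warning.
    """
    props_pre = {p.label: p for p in regionprops(labels_pre)}
    props_post = {p.label: p for p in regionprops(labels_post)}
    if not props_pre or not props_post:
        return []
    diam = np.mean(
        [p.equivalent_diameter_area for p in props_pre.values()]
        + [p.equivalent_diameter_area for p in props_post.values()]
    )
    max_d = MATCH_MAX_DISPLACEMENT_FRAC * diam
    candidates = []
    for la, pa in props_pre.items():
        for lb, pb in props_post.items():
            d = math.dist(pa.centroid, pb.centroid)
            if d <= max_d:
                candidates.append((d, la, lb))
    candidates.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    pairs = []
    for d, la, lb in candidates:
        if la in used_a or lb in used_b:
            continue
        pairs.append((la, lb))
        used_a.add(la)
        used_b.add(lb)
    for la in props_pre:
        if la not in used_a:
            log.warning("cell %d in pre-frame has no match; dropped", la)
    for lb in props_post:
        if lb not in used_b:
            log.warning("cell %d in post-frame has no match; dropped", lb)
    return pairs


def area_change(
    measurements: list[AreaMeasurement], transfected: bool | None = None
) -> dict:
    """Group summary of per-cell percent area change.

    Returns mean and SEM of ``area_change_pct`` over the selected group plus
    ``increase`` = mean - 100. An empty group is flagged absent.
    """
    sel = [
        m for m in measurements
        if transfected is None or m.transfected == transfected
    ]
    if not sel:
        return dict(mean=float("nan"), sem=float("nan"), increase=float("nan"),
                    n=0, flag="empty group")
    pct = np.array([m.area_change_pct for m in sel])
    mean = float(pct.mean())
    sem = float(pct.std(ddof=1) / math.sqrt(len(pct))) if len(pct) > 1 else float("nan")
    return dict(mean=mean, sem=sem, increase=mean - 100.0, n=len(pct), flag="")


def measure_swelling(
    pre_channels: dict[str, np.ndarray],
    post_channels: dict[str, np.ndarray],
    pixel_size: float,
    dye_channel: str = "membrane_dye",
    protein_channel: str = "protein",
) -> list[AreaMeasurement]:
    """Segment, match, classify and measure a pre/post challenge image pair.

    Segmentation uses the membrane-dye channel when present (it covers
    non-transfected cells), otherwise the protein channel. Transfection is
    decided per pre-frame cell from the protein channel.
    """
    seg_name = dye_channel if dye_channel in pre_channels else protein_channel
    lab_pre = segment_cells(pre_channels[seg_name])
    lab_post = segment_cells(post_channels[seg_name])
    pairs = match_cells(lab_pre, lab_post)
    protein = pre_channels.get(protein_channel)
    bg_mode, bg_sd = (
        segmentation_background(protein, lab_pre) if protein is not None else (0.0, 0.0)
    )
    px_area = pixel_size**2
    out = []
    for la, lb in pairs:
        a_pre = float((lab_pre == la).sum()) * px_area
        a_post = float((lab_post == lb).sum()) * px_area
        tf = (
            classify_transfected(lab_pre == la, protein, bg_mode, bg_sd)
            if protein is not None else True
        )
        out.append(
            AreaMeasurement(cell_id=la, area_pre=a_pre, area_post=a_post, transfected=tf)
        )
    return out
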
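"""Marker-controlled watershed segmentation and nucleus-validated cell filtering.

The segmentation of one grayscale raster (the blue channel for nuclei,
or the blue/red merge for cell candidates) proceeds in three stages:

1. ``foreground_mask`` -- an edge-based binary mask: contrast stretch,
   Sobel gradient, gradient threshold, dilation / hole filling / erosion
   and small-object removal, then a second masked-grayscale binarisation
   pass that tightens the mask to the actual signal.
2. ``build_seed_landscape`` -- the negated Euclidean distance transform
   of the mask, with shallow minima suppressed by the extended-minima
   (h-minima) transform; the surviving minima are the watershed seeds.
   The seed raster is the classic marker array X.
3. ``watershed_labels`` -- marker-controlled watershed of the landscape
   restricted to the foreground, one label per seed, ridge pixels left
   as background.

``filter_cells`` then keeps only those candidate segments that contain
exactly one nucleus and do not touch the image border; everything else
(nucleus-free debris, unresolved clusters, multinucleate cells,
boundary-clipped cells) is excluded from analysis.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from enum import Enum
from typing import Optional

import numpy as np
from scipy import ndimage as ndi
from skimage import filters, morphology, segmentation as skseg
from skimage.measure import label as cc_label

logger = logging.getLogger(__name__)


class ValidationError(ValueError):
    pass


class EmptyForegroundError(RuntimeError):
    """Raised when a seed landscape is requested for an empty mask."""


class LabelSource(str, Enum):
    NUCLEI = "nuclei"
    CANDIDATES = "candidates"
    CELLS = "cells"


@dataclass
class SegmentationParams:
    """Tunables of the segmentation procedure.

    h_blue / h_merged are the extended-minima depths applied to the
    negated distance transform (pixel-distance units): 0.6 for nucleus
    images, 1.0 (or 2.0 for coarser merges) for blue/red merged images.
    """

    h_blue: float = 0.6
    h_merged: float = 1.0
    min_object_area_px: int = 30
    morph_radius_px: int = 2
    contrast_low_pct: float = 1.0
    contrast_high_pct: float = 99.0
    nucleus_overlap_fraction: float = 0.5
    gradient_threshold: Optional[float] = None  # None -> triangle method on the gradient

    def __post_init__(self) -> None:
        if self.h_blue <= 0 or self.h_merged <= 0:
            raise ValidationError("h values must be positive")
        if self.min_object_area_px < 1:
            raise ValidationError("min_object_area_px must be >= 1")
        if not self.contrast_low_pct < self.contrast_high_pct:
            raise ValidationError("contrast percentile bounds must satisfy low < high")
        if not 0 < self.nucleus_overlap_fraction <= 1:
            raise ValidationError("nucleus_overlap_fraction must be in (0, 1]")


@dataclass
class LabelMap:
    """Integer-labelled segmentation raster; 0 is background."""

    labels: np.ndarray
    source: LabelSource

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValidationError("label raster must be 2-D")
        if self.labels.size and self.labels.min() < 0:
            raise ValidationError("labels must be non-negative")
        self.source = LabelSource(self.source)

    @property
    def n_labels(self) -> int:
        return int(self.labels.max())

    def label_ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids > 0]


@dataclass
class SeedLandscape:
    """Flooding landscape for the watershed: negated distance transform,
    seed mask X (extended minima) and the foreground it lives in."""

    negated_distance: np.ndarray
    seed_mask: np.ndarray
    foreground_mask: np.ndarray

    def __post_init__(self) -> None:
        if self.seed_mask.shape != self.negated_distance.shape:
            raise ValidationError("seed mask and landscape dimensions differ")
        if np.any(self.seed_mask & ~self.foreground_mask):
            raise ValidationError("seeds outside the foreground mask")


def _remove_small(binary: np.ndarray, min_area: int) -> np.ndarray:
    labels, n = ndi.label(binary, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        return binary
    areas = np.bincount(labels.ravel())
    keep = areas >= min_area
    keep[0] = False
    return keep[labels]


def _stretch(gray: np.ndarray, low_pct: float, high_pct: float) -> np.ndarray:
    """Percentile contrast stretch to [0, 1]; constant images map to 0.

    The upper bound never drops below half the image maximum: in
    sparse images the foreground can occupy less than 1 - high_pct/100
    of the pixels, and a purely percentile ceiling would sit in the
    background and blow the noise up to full range.
    """
    lo, hi = np.percentile(gray, [low_pct, high_pct])
    hi = max(hi, 0.5 * float(gray.max()))
    if hi <= lo:
        return np.zeros_like(gray, dtype=float)
    return np.clip((gray - lo) / (hi - lo), 0.0, 1.0)


def _gradient_threshold(value: Optional[float], grad: np.ndarray) -> float:
    # gradient-magnitude histograms are unimodal and heavily skewed
    # toward zero; the triangle method keeps weak (dim-cell) edges that
    # a bimodal-assumption threshold like Otsu's would discard
    if value is not None:
        return value
    return float(filters.threshold_triangle(grad))


def foreground_mask(gray: np.ndarray, params: SegmentationParams) -> np.ndarray:
    """Edge-based foreground mask of a [0, 1] grayscale raster.

    Stage one finds object outlines from the Sobel gradient magnitude,
    closes them into solid regions (dilate, fill holes, erode) and drops
    components below ``min_object_area_px``.  Stage two re-thresholds
    the contrast-stretched grayscale inside that mask, so the final
    foreground follows the actual signal boundary rather than the
    dilated edge band.  A blank (constant) input yields an all-false
    mask rather than an error.
    """
    gray = np.asarray(gray, dtype=float)
    if gray.ndim != 2:
        raise ValidationError("expected a 2-D raster")
    if gray.size == 0 or gray.max() == gray.min():
        return np.zeros(gray.shape, dtype=bool)

    selem = morphology.disk(params.morph_radius_px)

    # (1) contrast/intensity enhancement, (2) Sobel edges -> solid binary
    enhanced = _stretch(gray, params.contrast_low_pct, params.contrast_high_pct)
    grad = filters.sobel(enhanced)
    if grad.max() == 0:
        return np.zeros(gray.shape, dtype=bool)
    edges = grad > _gradient_threshold(params.gradient_threshold, grad)
    binary = morphology.dilation(edges, selem)
    binary = ndi.binary_fill_holes(binary)
    binary = morphology.erosion(binary, selem)
    binary = _remove_small(binary, params.min_object_area_px)
    if not binary.any():
        return binary

    # (3) use the binary as a mask on the enhanced grayscale, (4)
    # re-binarise and close the result (dilate, fill holes, erode) so
    # the mask is scale-preserving at object borders.  The second
    # threshold is referenced to the background (pixels outside the
    # stage-one mask): cells of very different brightness coexist in
    # one image, and an Otsu threshold over the masked histogram would
    # erase the dim ones.
    masked = np.where(binary, enhanced, 0.0)
    if masked.max() == 0:
        return np.zeros(gray.shape, dtype=bool)
    outside = enhanced[~binary]
    if outside.size:
        t = float(np.percentile(outside, 99.5))
    else:
        t = float(filters.threshold_otsu(enhanced))
    binary2 = masked > t
    binary2 = morphology.dilation(binary2, selem)
    binary2 = ndi.binary_fill_holes(binary2)
    binary2 = morphology.erosion(binary2, selem)
    binary2 = _remove_small(binary2, params.min_object_area_px)
    return binary2


def build_seed_landscape(binary: np.ndarray, h: float) -> SeedLandscape:
    """Distance-transform landscape with h-minima-suppressed seeds.

    The Euclidean distance transform of the foreground is negated so
    that object centres become basins; the extended-minima transform
    with depth ``h`` removes shallow basins that would over-segment,
    leaving the seed array X.  Seeds outside the foreground (a side
    effect of the plateau-filling reconstruction) are discarded, which
    together with restricting the watershed to the foreground plays the
    role of forcing the background to be minimal.
    """
    binary = np.asarray(binary, dtype=bool)
    if not binary.any():
        raise EmptyForegroundError("no foreground to seed")
    distance = ndi.distance_transform_edt(binary)
    negated = -distance
    # extended minima = regional minima of the h-minima transform
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        seeds = morphology.local_minima(
            morphology.reconstruction(negated + h, negated, method="erosion"),
            connectivity=2,
        )
    seeds = seeds & binary
    return SeedLandscape(negated_distance=negated, seed_mask=seeds, foreground_mask=binary)


def watershed_labels(landscape: SeedLandscape) -> LabelMap:
    """Marker-controlled watershed of a seed landscape.

    One label per connected seed component; ridge pixels between basins
    are assigned to background and labels never leave the foreground.
    """
    markers = cc_label(landscape.seed_mask, connectivity=2)
    if markers.max() == 0:
        return LabelMap(
            labels=np.zeros(landscape.seed_mask.shape, dtype=np.int32),
            source=LabelSource.CANDIDATES,
        )
    labels = skseg.watershed(
        landscape.negated_distance,
        markers=markers,
        mask=landscape.foreground_mask,
        connectivity=2,
        watershed_line=True,
    )
    return LabelMap(labels=labels.astype(np.int32), source=LabelSource.CANDIDATES)


def segment_channel(
    gray: np.ndarray, h: float, params: SegmentationParams, source: LabelSource | str = LabelSource.CANDIDATES
) -> LabelMap:
    """Full single-channel segmentation: mask, seed landscape, watershed.

    Use ``h=params.h_blue`` with ``source="nuclei"`` on the blue channel
    and ``h=params.h_merged`` with ``source="candidates"`` on the merged
    raster.  An empty foreground yields an empty LabelMap.
    """
    mask = foreground_mask(gray, params)
    source = LabelSource(source)
    if not mask.any():
        logger.warning("segment_channel: empty foreground, returning 0 labels")
        return LabelMap(labels=np.zeros(mask.shape, dtype=np.int32), source=source)
    landscape = build_seed_landscape(mask, h)
    lm = watershed_labels(landscape)
    return LabelMap(labels=lm.labels, source=source)


def _border_labels(labels: np.ndarray) -> set[int]:
    edge = np.concatenate(
        [labels[0, :], labels[-1, :], labels[:, 0], labels[:, -1]]
    )
    return set(np.unique(edge[edge > 0]).tolist())


def filter_cells(
    candidates: LabelMap,
    nuclei: LabelMap,
    params: SegmentationParams,
    counts_out: Optional[dict] = None,
) -> LabelMap:
    """Keep candidate segments containing exactly one nucleus, away from the border.

    A nucleus is *contained* in a candidate segment iff more than
    ``nucleus_overlap_fraction`` of the nucleus's pixels lie inside that
    segment; each nucleus is assigned to at most one segment (the one
    holding its largest overlap, ties broken toward the lower segment
    label).  Segments with zero or multiple nuclei, and segments with
    any pixel on the outermost rows/columns, are excluded.  Survivors
    are relabelled consecutively from 1.

    ``counts_out``, if given, receives an audit of the exclusion
    pipeline: candidate / no-nucleus / multinucleate / border / accepted
    counts.
    """
    cand = np.asarray(candidates.labels)
    nuc = np.asarray(nuclei.labels)
    if cand.shape != nuc.shape:
        raise ValidationError("candidate and nucleus rasters have different dimensions")

    nucleus_count: dict[int, int] = {}
    for nucleus_id in np.unique(nuc[nuc > 0]):
        pixels = cand[nuc == nucleus_id]
        total = pixels.size
        ids, overlaps = np.unique(pixels[pixels > 0], return_counts=True)
        if ids.size == 0:
            continue
        best = int(ids[np.argmax(overlaps)])  # np.unique sorts ids: ties -> lower label
        if overlaps.max() / total > params.nucleus_overlap_fraction:
            nucleus_count[best] = nucleus_count.get(best, 0) + 1

    border = _border_labels(cand)
    all_ids = np.unique(cand[cand > 0])
    accepted = [
        int(cid)
        for cid in all_ids
        if nucleus_count.get(int(cid), 0) == 1 and int(cid) not in border
    ]

    if counts_out is not None:
        counts_out.update(
            candidates=int(all_ids.size),
            excluded_no_nucleus=sum(
                1 for cid in all_ids if nucleus_count.get(int(cid), 0) == 0
            ),
            excluded_multinucleate=sum(
                1 for cid in all_ids if nucleus_count.get(int(cid), 0) > 1
            ),
            excluded_border=sum(
                1
                for cid in all_ids
                if int(cid) in border and nucleus_count.get(int(cid), 0) == 1
            ),
            accepted=len(accepted),
        )

    out = np.zeros_like(cand, dtype=np.int32)
    for new_id, cid in enumerate(sorted(accepted), start=1):
        out[cand == cid] = new_id
    if not accepted:
        logger.warning("filter_cells: no accepted cells in this image")
    return LabelMap(labels=out, source=LabelSource.CELLS)
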
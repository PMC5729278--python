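"""Per-cell morphometric and intensity features.

For every accepted cell the pipeline records centroid, area, perimeter,
eccentricity and the minor/major axis lengths of the second-moment
ellipse, plus the mean red (lipid stain) intensity.  Per-cell means are
normalised by the brightest red pixel across *all* images of the batch
and reported on a 0-255 scale, matching how intensity values in the
80-170 au range arise from images normalised to the batch maximum.

Coordinates are 0-based with x = column and y = row.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from skimage.measure import regionprops

from foamquant.segmentation import LabelMap, LabelSource

logger = logging.getLogger(__name__)

DEFAULT_REPORTING_SCALE = 255.0


@dataclass
class CellRecord:
    """Features of one accepted cell.

    area is in pixel^2 multiplied by pixel_size_um^2 (so um^2 when the
    batch is calibrated); perimeter and axis lengths are in pixels;
    eccentricity is that of the ellipse with the same second central
    moments as the region (0 for a circle, -> 1 for a line).
    """

    cell_id: int
    condition_label: str = ""
    well_id: str = ""
    centroid_x: float = np.nan
    centroid_y: float = np.nan
    area: float = np.nan
    perimeter: float = np.nan
    eccentricity: float = np.nan
    minor_axis_len: float = np.nan
    major_axis_len: float = np.nan
    mean_red_raw: float = np.nan
    mean_red_norm: float = np.nan


@dataclass
class PixelDensityHistogram:
    """Count-density histogram of in-cell pixel intensities.

    Normalised so each bin's *area* (height x width) is the fraction of
    observed pixels in that intensity range; the areas sum to 1.
    """

    bin_edges: np.ndarray
    density: np.ndarray

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.density = np.asarray(self.density, dtype=float)
        if self.bin_edges.size != self.density.size + 1:
            raise ValueError("bin_edges must have one more element than density")

    @property
    def bin_areas(self) -> np.ndarray:
        return self.density * np.diff(self.bin_edges)


def region_properties(cells: LabelMap, pixel_size_um: float = 1.0) -> list[CellRecord]:
    """Geometry features for every label of an accepted-cell map.

    Area = pixel count x pixel_size_um^2; perimeter by boundary-step
    length; centroid = unweighted pixel mean; eccentricity / axis
    lengths from the second-moment-equivalent ellipse.  Degenerate
    regions (< 3 pixels) get eccentricity 0 with a warning.
    """
    if cells.source != LabelSource.CELLS:
        raise ValueError("region_properties expects an accepted-cell LabelMap")
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be positive")
    records = []
    for rp in regionprops(np.asarray(cells.labels)):
        if rp.num_pixels < 3 or not np.isfinite(rp.eccentricity):
            logger.warning(
                "cell %d has %d pixels: degenerate moments, eccentricity set to 0",
                rp.label,
                rp.num_pixels,
            )
            ecc = 0.0
        else:
            ecc = float(rp.eccentricity)
        row, col = rp.centroid
        records.append(
            CellRecord(
                cell_id=int(rp.label),
                centroid_x=float(col),
                centroid_y=float(row),
                area=float(rp.num_pixels) * pixel_size_um**2,
                perimeter=float(rp.perimeter),
                eccentricity=ecc,
                minor_axis_len=float(rp.axis_minor_length),
                major_axis_len=float(rp.axis_major_length),
            )
        )
    return records


def per_cell_red_intensity(
    cells: LabelMap,
    red: np.ndarray,
    batch_max: float,
    reporting_scale: float = DEFAULT_REPORTING_SCALE,
) -> dict[int, tuple[float, float]]:
    """Mean red intensity per cell, raw and batch-normalised.

    ``batch_max`` is the brightest red pixel across every image of the
    batch.  mean_red_norm = mean_red_raw / batch_max x reporting_scale,
    so a cell sitting at the batch maximum scores exactly the reporting
    scale (255 by default).
    """
    if batch_max <= 0:
        raise ValueError("no red signal in batch (batch_max must be > 0)")
    red = np.asarray(red, dtype=float)
    labels = np.asarray(cells.labels)
    if labels.shape != red.shape:
        raise ValueError("label raster and red channel dimensions differ")
    out: dict[int, tuple[float, float]] = {}
    for cid in cells.label_ids():
        raw = float(red[labels == cid].mean())
        out[int(cid)] = (raw, raw / batch_max * reporting_scale)
    return out


def pixel_density_histogram(
    cells: LabelMap,
    red: np.ndarray,
    batch_max: float,
    bin_count: int = 50,
    reporting_scale: float = DEFAULT_REPORTING_SCALE,
) -> PixelDensityHistogram:
    """Count-density histogram of red intensities of all in-cell pixels.

    Pools pixels belonging to accepted cells only, scales them by the
    batch maximum to the reporting scale, and bins into ``bin_count``
    equal-width bins spanning [0, reporting_scale].
    """
    if batch_max <= 0:
        raise ValueError("no red signal in batch (batch_max must be > 0)")
    labels = np.asarray(cells.labels)
    values = np.asarray(red, dtype=float)[labels > 0]
    if values.size == 0:
        raise ValueError("no cells to histogram")
    scaled = values / batch_max * reporting_scale
    density, edges = np.histogram(
        scaled, bins=bin_count, range=(0.0, reporting_scale), density=True
    )
    return PixelDensityHistogram(bin_edges=edges, density=density)
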
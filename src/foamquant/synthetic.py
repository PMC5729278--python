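"""Seeded synthetic two-channel fluorescence fixtures with ground truth.

The generator emulates the structure of the real image data: elliptical
macrophages rendered in the red (lipid stain) channel with one interior
nucleus each in the blue (nuclear counterstain) channel, a configurable
number of binucleate cells and boundary-touching cells (both of which
the validation filter must reject), optional small-overlap cell
clusters, condition-dependent per-cell red intensity drawn from a
truncated normal, an optional bright-droplet texture, and additive
Gaussian pixel noise.  Every image comes with ground-truth label
rasters and a per-cell table, and the same seed reproduces the exact
same rasters.

It does not simulate optics (point-spread function, vignetting, uneven
illumination) or bright-field contrast.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats as sps
from skimage.draw import ellipse as draw_ellipse

from foamquant.imaging_io import BatchManifest, ManifestEntry, MultiChannelImage, save_gray
from foamquant.stats import percent_change

_MAX_PLACEMENT_TRIES = 500


@dataclass
class SyntheticSpec:
    """Generative parameters for one condition's images.

    red_mean / red_sd are the condition's per-cell mean lipid-stain
    intensity distribution on the [0, 1] scale; the invariant
    red_mean + 3 red_sd <= 1 keeps draws in gamut.  droplet_fraction
    of each cell's pixels can be re-rendered as bright puncta
    (droplet_gain x the cell mean) to mimic lipid bodies.
    """

    image_size: tuple[int, int] = (512, 512)
    n_cells: int = 60
    cell_semi_axes_range: tuple[float, float] = (7.0, 14.0)
    nucleus_semi_axes_range: tuple[float, float] = (3.5, 5.5)
    n_binucleate: int = 0
    n_border_touching: int = 0
    cluster_fraction: float = 0.0
    red_mean: float = 0.30
    red_sd: float = 0.05
    nucleus_intensity: float = 0.8
    background_level: float = 0.05
    noise_sd: float = 0.02
    droplet_fraction: float = 0.0
    droplet_gain: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.nucleus_semi_axes_range[1] >= self.cell_semi_axes_range[0]:
            raise ValueError("nucleus axes must be smaller than cell axes")
        if self.n_binucleate + self.n_border_touching > self.n_cells:
            raise ValueError("binucleate + border-touching cells exceed n_cells")
        if self.red_mean + 3 * self.red_sd > 1:
            raise ValueError("red_mean + 3*red_sd must be <= 1")
        if not 0 <= self.cluster_fraction <= 1:
            raise ValueError("cluster_fraction must be in [0, 1]")


@dataclass
class GroundTruth:
    """True labels and per-cell parameters for one synthetic image."""

    cell_labels: np.ndarray
    nucleus_labels: np.ndarray
    cells: pd.DataFrame = field(repr=False)
    # columns: cell_id, true_area_px, true_eccentricity, true_mean_red,
    #          is_binucleate, is_border, is_clustered, expected_accepted

    @property
    def n_expected_accepted(self) -> int:
        return int(self.cells["expected_accepted"].sum())


def _truncnorm(rng: np.random.Generator, mean: float, sd: float, n: int) -> np.ndarray:
    if sd == 0:
        return np.full(n, mean)
    a, b = (0.0 - mean) / sd, (1.0 - mean) / sd
    return sps.truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)


def _ellipse_mask(shape, center, axes, angle):
    rr, cc = draw_ellipse(
        center[0], center[1], axes[0], axes[1], shape=shape, rotation=angle
    )
    return rr, cc


def generate_image(spec: SyntheticSpec) -> tuple[MultiChannelImage, GroundTruth]:
    """Render one blue/red image pair plus its ground truth.

    Cells are placed by rejection sampling: interior cells keep a
    minimum gap of 5 px between ellipse envelopes so that, barring the
    configured clusters, they form separate connected components; a
    ``cluster_fraction`` of cells is instead attached to a previously
    placed cell with a slight overlap.  Boundary-touching cells are
    centred close enough to the edge that the ellipse is clipped.
    Raises if placement is infeasible after bounded retries.
    """
    rng = np.random.default_rng(spec.seed)
    rows, cols = spec.image_size
    a_lo, a_hi = spec.cell_semi_axes_range
    margin = 5.0

    n_special = spec.n_binucleate + spec.n_border_touching
    n_clustered = int(round(spec.cluster_fraction * (spec.n_cells - n_special)))

    placed = []  # (center_r, center_c, max_axis)
    cells = []

    def too_close(r, c, radius, min_gap):
        for pr, pc, prad in placed:
            if np.hypot(r - pr, c - pc) < radius + prad + min_gap:
                return True
        return False

    for i in range(spec.n_cells):
        is_border = i < spec.n_border_touching
        is_binucleate = spec.n_border_touching <= i < n_special
        is_clustered = (not is_border and not is_binucleate) and (
            i >= spec.n_cells - n_clustered
        )
        axes = np.sort(rng.uniform(a_lo, a_hi, size=2))[::-1]
        if is_binucleate:
            # multinucleate macrophages are rendered larger so that two
            # interior, well-separated nuclei fit inside the ellipse
            axes = axes * 1.6
        angle = rng.uniform(0, np.pi)
        for attempt in range(_MAX_PLACEMENT_TRIES):
            if is_border:
                # centre within half the major axis of a randomly chosen edge
                edge = rng.integers(4)
                d = rng.uniform(0, axes[0] * 0.5)
                if edge == 0:
                    r, c = d, rng.uniform(a_hi, cols - a_hi)
                elif edge == 1:
                    r, c = rows - 1 - d, rng.uniform(a_hi, cols - a_hi)
                elif edge == 2:
                    r, c = rng.uniform(a_hi, rows - a_hi), d
                else:
                    r, c = rng.uniform(a_hi, rows - a_hi), cols - 1 - d
                if not too_close(r, c, axes[0], margin):
                    break
            elif is_clustered and placed:
                j = rng.integers(len(placed))
                pr, pc, prad = placed[j]
                theta = rng.uniform(0, 2 * np.pi)
                dist = (prad + axes[0]) * 0.85  # slight envelope overlap
                r, c = pr + dist * np.sin(theta), pc + dist * np.cos(theta)
                lo = a_hi + margin
                if lo <= r <= rows - 1 - lo and lo <= c <= cols - 1 - lo:
                    ok = True
                    for k, (qr, qc, qrad) in enumerate(placed):
                        if k == j:
                            continue
                        if np.hypot(r - qr, c - qc) < axes[0] + qrad + margin:
                            ok = False
                            break
                    if ok:
                        break
            else:
                lo = axes[0] + margin
                r = rng.uniform(lo, rows - 1 - lo)
                c = rng.uniform(lo, cols - 1 - lo)
                if not too_close(r, c, axes[0], margin):
                    break
        else:
            raise RuntimeError(
                f"cannot place cells: no valid position for cell {i + 1} "
                f"after {_MAX_PLACEMENT_TRIES} tries"
            )
        placed.append((r, c, axes[0]))
        cells.append(
            dict(
                cell_id=i + 1,
                center=(r, c),
                axes=axes,
                angle=angle,
                is_border=is_border,
                is_binucleate=is_binucleate,
                is_clustered=is_clustered,
            )
        )

    red_means = _truncnorm(rng, spec.red_mean, spec.red_sd, spec.n_cells)

    blue = np.full(spec.image_size, spec.background_level)
    red = np.full(spec.image_size, spec.background_level)
    cell_labels = np.zeros(spec.image_size, dtype=np.int32)
    nucleus_labels = np.zeros(spec.image_size, dtype=np.int32)

    n_lo, n_hi = spec.nucleus_semi_axes_range
    nucleus_id = 0
    rows_out = []
    for cell, mu in zip(cells, red_means):
        r, c = cell["center"]
        a, b = cell["axes"]
        rr, cc = _ellipse_mask(spec.image_size, (r, c), (a, b), cell["angle"])
        red[rr, cc] = mu
        cell_labels[rr, cc] = cell["cell_id"]

        if spec.droplet_fraction > 0 and rr.size:
            n_droplet_px = int(round(spec.droplet_fraction * rr.size))
            if n_droplet_px:
                idx = rng.choice(rr.size, size=n_droplet_px, replace=False)
                red[rr[idx], cc[idx]] = np.clip(mu * spec.droplet_gain, 0, 1)

        n_nuclei = 2 if cell["is_binucleate"] else 1
        for k in range(n_nuclei):
            nucleus_id += 1
            # nucleus axes capped relative to the cell's minor axis so
            # the nucleus stays strictly interior even when offset
            hi = min(n_hi, 0.42 * b if n_nuclei == 2 else 0.65 * b)
            hi = max(hi, n_lo)
            na, nb = np.sort(rng.uniform(n_lo, hi, size=2))[::-1]
            # offset along the major axis keeps both nuclei of a
            # binucleate cell interior and disjoint
            if n_nuclei == 2:
                shift = (0.52 if k == 0 else -0.52) * a
            else:
                shift = rng.uniform(-0.2, 0.2) * a
            nr = r + shift * np.cos(cell["angle"])
            nc = c + shift * np.sin(cell["angle"])
            nrr, ncc = _ellipse_mask(spec.image_size, (nr, nc), (na, nb), cell["angle"])
            blue[nrr, ncc] = spec.nucleus_intensity
            nucleus_labels[nrr, ncc] = nucleus_id

        ecc = np.sqrt(1 - (b / a) ** 2)
        rows_out.append(
            dict(
                cell_id=cell["cell_id"],
                true_area_px=int(rr.size),
                true_eccentricity=float(ecc),
                true_mean_red=float(mu),
                is_binucleate=cell["is_binucleate"],
                is_border=cell["is_border"],
                is_clustered=cell["is_clustered"],
                expected_accepted=not (cell["is_binucleate"] or cell["is_border"]),
            )
        )

    if spec.noise_sd > 0:
        blue = blue + rng.normal(0, spec.noise_sd, spec.image_size)
        red = red + rng.normal(0, spec.noise_sd, spec.image_size)
    blue = np.clip(blue, 0, 1)
    red = np.clip(red, 0, 1)

    # clustered overlaps can overwrite earlier cells; record realised areas
    truth = pd.DataFrame(rows_out)
    realised = np.bincount(cell_labels.ravel(), minlength=spec.n_cells + 1)
    truth["true_area_px"] = realised[truth["cell_id"].to_numpy()]

    img = MultiChannelImage(blue=blue, red=red, condition_label="", well_id="")
    return img, GroundTruth(
        cell_labels=cell_labels, nucleus_labels=nucleus_labels, cells=truth
    )


def generate_experiment(
    condition_specs: Mapping[str, SyntheticSpec],
    wells_per_condition: int,
    out_dir: str | Path,
    pixel_size_um: float = 1.0,
) -> tuple[BatchManifest, dict[tuple[str, str], GroundTruth]]:
    """Write a multi-condition, multi-well synthetic experiment to disk.

    Each well gets a distinct seed derived from its condition spec's
    seed and the well index, so wells are independent replicates of the
    same condition.  Images are written as 8-bit TIFFs next to a
    manifest CSV; ground truth is returned keyed by (condition, well).
    """
    if len(condition_specs) < 2:
        raise ValueError("need at least 2 conditions")
    labels = list(condition_specs)
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate condition labels")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    entries = []
    truths: dict[tuple[str, str], GroundTruth] = {}
    for ci, (label, spec) in enumerate(condition_specs.items()):
        for w in range(wells_per_condition):
            well_id = f"{label}_w{w + 1}"
            well_spec = replace(spec, seed=(spec.seed + 10007 * ci + 101 * w) % (2**31))
            img, truth = generate_image(well_spec)
            blue_path = out_dir / f"{well_id}_blue.tif"
            red_path = out_dir / f"{well_id}_red.tif"
            save_gray(blue_path, img.blue, bit_depth=8)
            save_gray(red_path, img.red, bit_depth=8)
            entries.append(
                ManifestEntry(
                    condition_label=label,
                    well_id=well_id,
                    blue_path=blue_path,
                    red_path=red_path,
                )
            )
            truths[(label, well_id)] = truth

    manifest = BatchManifest(entries=entries, pixel_size_um=pixel_size_um)
    manifest.to_csv(out_dir / "manifest.csv")
    return manifest, truths


def programmed_percent_change(control: SyntheticSpec, treated: SyntheticSpec) -> int:
    """Percent change of the programmed mean red intensity, control -> treated."""
    return percent_change(control.red_mean, treated.red_mean)
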
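"""Batch orchestration: images in, per-cell tables and reports out.

``run_pipeline`` drives the full analysis for one experiment batch:
load the manifest, compute the batch-wide red maximum, segment nuclei
and cell candidates per image, filter candidates by nucleus content and
border contact, extract per-cell features, then write the per-cell
table, per-condition summaries, pairwise statistical comparisons,
red-vs-area correlation verdicts and per-condition pixel-intensity
histograms.  Per-image accepted/excluded counts are logged so the
exclusion pipeline is auditable.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from foamquant.imaging_io import (
    BatchManifest,
    MultiChannelImage,
    batch_red_max,
    load_batch,
    merge_channels,
)
from foamquant.segmentation import (
    LabelSource,
    SegmentationParams,
    filter_cells,
    segment_channel,
)
from foamquant.features import (
    DEFAULT_REPORTING_SCALE,
    per_cell_red_intensity,
    pixel_density_histogram,
    region_properties,
)
from foamquant import stats as fstats

logger = logging.getLogger(__name__)

FEATURES_COMPARED = ("mean_red_norm", "area", "eccentricity")


@dataclass
class PipelineConfig:
    manifest_path: Optional[Path] = None
    params: SegmentationParams = field(default_factory=SegmentationParams)
    pixel_size_um: float = 1.0
    reporting_scale: float = DEFAULT_REPORTING_SCALE
    bin_count: int = 50
    pairings: list[tuple[str, str]] = field(default_factory=list)  # (control, treated)
    output_dir: Path = Path("foamquant_out")
    merge_rule: str = "max"
    seed: int = 0

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = json.load(fh)
        params = SegmentationParams(**raw.pop("params", {}))
        pairings = [tuple(p) for p in raw.pop("pairings", [])]
        cfg = cls(params=params, pairings=pairings, **raw)
        if cfg.manifest_path is not None:
            cfg.manifest_path = Path(cfg.manifest_path)
        cfg.output_dir = Path(cfg.output_dir)
        return cfg


@dataclass
class ImageResult:
    condition_label: str
    well_id: str
    cells: "pd.DataFrame"
    exclusion_counts: dict


@dataclass
class PipelineResult:
    per_cell: pd.DataFrame
    summaries: pd.DataFrame
    comparisons: Optional[pd.DataFrame]
    correlations: pd.DataFrame
    histograms: dict[str, pd.DataFrame]
    batch_max: float
    artifacts: dict[str, Path] = field(default_factory=dict)


def process_image(
    img: MultiChannelImage,
    params: SegmentationParams,
    batch_max: float,
    reporting_scale: float = DEFAULT_REPORTING_SCALE,
    merge_rule: str = "max",
) -> tuple[ImageResult, np.ndarray]:
    """Segment one image and extract its per-cell feature rows.

    Returns the per-image result plus the accepted-cell label raster
    (useful for debug output and ground-truth matching).
    """
    merged = merge_channels(img, rule=merge_rule)
    nuclei = segment_channel(img.blue, params.h_blue, params, LabelSource.NUCLEI)
    candidates = segment_channel(merged, params.h_merged, params, LabelSource.CANDIDATES)
    counts: dict = {}
    cells = filter_cells(candidates, nuclei, params, counts)
    logger.info(
        "%s/%s: %s", img.condition_label, img.well_id, counts or "no candidates"
    )

    records = region_properties(cells, img.pixel_size_um)
    reds = per_cell_red_intensity(cells, img.red, batch_max, reporting_scale)
    rows = []
    for rec in records:
        raw, norm = reds[rec.cell_id]
        rows.append(
            dict(
                condition=img.condition_label,
                well=img.well_id,
                cell_id=rec.cell_id,
                centroid_x=rec.centroid_x,
                centroid_y=rec.centroid_y,
                area=rec.area,
                perimeter=rec.perimeter,
                eccentricity=rec.eccentricity,
                minor_axis_len=rec.minor_axis_len,
                major_axis_len=rec.major_axis_len,
                mean_red_raw=raw,
                mean_red_norm=norm,
            )
        )
    columns = [
        "condition", "well", "cell_id", "centroid_x", "centroid_y", "area",
        "perimeter", "eccentricity", "minor_axis_len", "major_axis_len",
        "mean_red_raw", "mean_red_norm",
    ]
    df = pd.DataFrame(rows, columns=columns)
    return (
        ImageResult(img.condition_label, img.well_id, df, counts),
        cells.labels,
    )


def summarize_batch(per_cell: pd.DataFrame) -> pd.DataFrame:
    """Per-condition ConditionSummary rows for every compared feature."""
    rows = []
    for condition, group in per_cell.groupby("condition", sort=True):
        for feat in FEATURES_COMPARED:
            s = fstats.summarize_condition(group[feat].to_numpy())
            rows.append(dict(condition=condition, feature=feat, **asdict(s)))
    return pd.DataFrame(rows)


def compare_conditions(
    per_cell: pd.DataFrame, pairings: Sequence[tuple[str, str]]
) -> pd.DataFrame:
    """Pairwise control-vs-treated comparisons for every compared feature.

    For each (control, treated) pairing and each feature the report
    carries the selected test and its p-value, the significance flags,
    the percent change of the treated mean relative to control, and
    both population summaries.
    """
    present = set(per_cell["condition"])
    rows = []
    for control, treated in pairings:
        for label in (control, treated):
            if label not in present:
                raise ValueError(f"pairing references absent condition: {label!r}")
        a = per_cell.loc[per_cell["condition"] == control]
        b = per_cell.loc[per_cell["condition"] == treated]
        for feat in FEATURES_COMPARED:
            x = a[feat].to_numpy()
            y = b[feat].to_numpy()
            res = fstats.select_and_run_test(x, y)
            sx = fstats.summarize_condition(x)
            sy = fstats.summarize_condition(y)
            rows.append(
                dict(
                    control=control,
                    treated=treated,
                    feature=feat,
                    test=res.test_name.value,
                    p_value=res.p_value,
                    significant=res.significant,
                    notable=res.notable,
                    percent_change=fstats.percent_change(sx.mean, sy.mean)
                    if sx.mean > 0
                    else np.nan,
                    control_n=sx.n,
                    control_mean=sx.mean,
                    control_sem=sx.sem,
                    treated_n=sy.n,
                    treated_mean=sy.mean,
                    treated_sem=sy.sem,
                )
            )
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig, manifest: Optional[BatchManifest] = None) -> PipelineResult:
    """Run the whole batch analysis and write its artifact files.

    Raises RuntimeError if the batch yields zero accepted cells;
    per-image failures are logged and the image skipped.
    """
    if manifest is None:
        if config.manifest_path is None:
            raise ValueError("either a manifest or a manifest_path is required")
        manifest = BatchManifest.from_csv(config.manifest_path, config.pixel_size_um)
    images = load_batch(manifest)
    if not images:
        raise RuntimeError("empty batch")
    bmax = batch_red_max(images)
    if bmax <= 0:
        raise RuntimeError("no red signal in batch")

    frames = []
    pooled_pixels: dict[str, list[np.ndarray]] = {}
    for img in images:
        try:
            result, labels = process_image(
                img, config.params, bmax, config.reporting_scale, config.merge_rule
            )
        except Exception:
            logger.exception("image %s/%s failed; skipping", img.condition_label, img.well_id)
            continue
        frames.append(result.cells)
        if labels.max() > 0:
            pooled_pixels.setdefault(img.condition_label, []).append(
                img.red[labels > 0] / bmax * config.reporting_scale
            )

    frames = [f for f in frames if not f.empty]
    per_cell = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    if per_cell.empty:
        raise RuntimeError("zero accepted cells batch-wide: check inputs and parameters")

    summaries = summarize_batch(per_cell)
    comparisons = (
        compare_conditions(per_cell, config.pairings) if config.pairings else None
    )

    corr_rows = []
    for condition, group in per_cell.groupby("condition", sort=True):
        if len(group) < 10:
            continue
        v = fstats.correlation_verdict(
            group["mean_red_norm"].to_numpy(), group["area"].to_numpy()
        )
        corr_rows.append(
            dict(
                condition=condition,
                pearson_r=v.pearson_r,
                pearson_p=v.pearson_p,
                spearman_r=v.spearman_r,
                spearman_p=v.spearman_p,
                verdict=v.verdict.value,
            )
        )
    correlations = pd.DataFrame(corr_rows)

    histograms = {}
    edges = np.linspace(0.0, config.reporting_scale, config.bin_count + 1)
    for condition, chunks in sorted(pooled_pixels.items()):
        values = np.concatenate(chunks)
        density, _ = np.histogram(values, bins=edges, density=True)
        histograms[condition] = pd.DataFrame(
            dict(bin_left=edges[:-1], bin_right=edges[1:], density=density)
        )

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts = {}

    def _write(name: str, df: pd.DataFrame) -> None:
        path = out / name
        df.to_csv(path, index=False)
        artifacts[name] = path

    _write("per_cell.csv", per_cell)
    _write("condition_summaries.csv", summaries)
    if comparisons is not None:
        _write("comparisons.csv", comparisons)
    if not correlations.empty:
        _write("correlations.csv", correlations)
    for condition, hist in histograms.items():
        _write(f"histogram_{condition}.csv", hist)
    meta = dict(
        batch_max=bmax,
        reporting_scale=config.reporting_scale,
        pixel_size_um=config.pixel_size_um,
        calibrated=config.pixel_size_um != 1.0,
        n_images=len(images),
        n_cells=int(len(per_cell)),
        coordinate_convention="0-based, x=column, y=row",
        normality_test="shapiro",
        variance_test="levene",
        percentile_method="linear interpolation",
    )
    meta_path = out / "run_metadata.json"
    meta_path.write_text(json.dumps(meta, indent=2))
    artifacts["run_metadata.json"] = meta_path

    return PipelineResult(
        per_cell=per_cell,
        summaries=summaries,
        comparisons=comparisons,
        correlations=correlations,
        histograms=histograms,
        batch_max=bmax,
        artifacts=artifacts,
    )
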
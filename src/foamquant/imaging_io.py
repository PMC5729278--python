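"""Loading, normalising and merging fluorescence channel rasters.

Each well contributes a co-registered image triple: a blue channel
(nuclear counterstain), a red channel (lipophilic stain) and an optional
bright-field image.  Rasters are converted to float in [0, 1] on load by
dividing by the bit-depth maximum of the source file (255 for 8-bit,
65535 for 16-bit), so all downstream processing is bit-depth agnostic.
Bright-field images are carried as metadata only; segmentation uses the
blue channel and the blue/red merge.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import imageio.v3 as iio


class LoadError(RuntimeError):
    """An image file referenced by the manifest is missing or unreadable."""


class ValidationError(ValueError):
    """An input violates a structural contract (shape, channel count...)."""


@dataclass
class MultiChannelImage:
    """Co-registered blue/red(/bright-field) rasters for one well.

    Attributes
    ----------
    blue, red : ndarray
        2-D float rasters in [0, 1].
    brightfield : ndarray or None
        Optional 2-D float raster in [0, 1]; never used quantitatively.
    condition_label : str
        Experimental condition (e.g. ``"PBS"``, ``"Chol"``).
    well_id : str
    pixel_size_um : float
        Microns per pixel side; 1.0 means uncalibrated (areas in px^2).
    """

    blue: np.ndarray
    red: np.ndarray
    brightfield: Optional[np.ndarray] = None
    condition_label: str = ""
    well_id: str = ""
    pixel_size_um: float = 1.0

    def __post_init__(self) -> None:
        self.blue = np.asarray(self.blue, dtype=float)
        self.red = np.asarray(self.red, dtype=float)
        if self.blue.ndim != 2 or self.red.ndim != 2:
            raise ValidationError("channel rasters must be 2-D")
        if self.blue.shape != self.red.shape:
            raise ValidationError(
                f"blue {self.blue.shape} and red {self.red.shape} dimensions differ"
            )
        if self.brightfield is not None:
            self.brightfield = np.asarray(self.brightfield, dtype=float)
            if self.brightfield.shape != self.blue.shape:
                raise ValidationError("bright-field dimensions differ from blue/red")
        for name in ("blue", "red"):
            arr = getattr(self, name)
            if arr.size and (arr.min() < 0 or arr.max() > 1):
                raise ValidationError(f"{name} channel values outside [0, 1]")
        if self.pixel_size_um <= 0:
            raise ValidationError("pixel_size_um must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.blue.shape


@dataclass
class ManifestEntry:
    condition_label: str
    well_id: str
    blue_path: Path
    red_path: Path
    brightfield_path: Optional[Path] = None

    def __post_init__(self) -> None:
        if not self.condition_label:
            raise ValidationError("condition label must be non-empty")
        self.blue_path = Path(self.blue_path)
        self.red_path = Path(self.red_path)
        if self.brightfield_path is not None:
            self.brightfield_path = Path(self.brightfield_path)


@dataclass
class BatchManifest:
    """Ordered list of image triples with a batch-wide pixel calibration."""

    entries: list[ManifestEntry] = field(default_factory=list)
    pixel_size_um: float = 1.0

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValidationError("pixel_size_um must be positive")

    @classmethod
    def from_csv(cls, path: str | Path, pixel_size_um: float = 1.0) -> "BatchManifest":
        """Read a manifest CSV with header condition,well,blue_path,red_path[,brightfield_path].

        Relative image paths are resolved against the CSV's directory.
        """
        path = Path(path)
        root = path.parent
        entries = []
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                bf = row.get("brightfield_path") or None
                entries.append(
                    ManifestEntry(
                        condition_label=row["condition"],
                        well_id=row["well"],
                        blue_path=root / row["blue_path"],
                        red_path=root / row["red_path"],
                        brightfield_path=(root / bf) if bf else None,
                    )
                )
        return cls(entries=entries, pixel_size_um=pixel_size_um)

    def to_csv(self, path: str | Path) -> None:
        """Write the manifest; image paths are stored relative to the CSV
        directory when possible so the batch directory stays portable."""
        path = Path(path)
        root = path.parent.resolve()

        def rel(p: Optional[Path]) -> str:
            if p is None:
                return ""
            p = Path(p).resolve()
            try:
                return str(p.relative_to(root))
            except ValueError:
                return str(p)

        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["condition", "well", "blue_path", "red_path", "brightfield_path"])
            for e in self.entries:
                writer.writerow(
                    [
                        e.condition_label,
                        e.well_id,
                        rel(e.blue_path),
                        rel(e.red_path),
                        rel(e.brightfield_path),
                    ]
                )


_BIT_DEPTH_MAX = {np.dtype(np.uint8): 255.0, np.dtype(np.uint16): 65535.0}


def _read_gray(path: Path) -> np.ndarray:
    """Read a single-channel 8/16-bit raster and rescale to [0, 1]."""
    if not Path(path).is_file():
        raise LoadError(f"image file not found: {path}")
    try:
        arr = iio.imread(path)
    except Exception as exc:  # pragma: no cover - backend specific
        raise LoadError(f"cannot decode image file: {path}: {exc}") from exc
    if arr.ndim == 3:
        raise ValidationError(
            f"{path}: multi-channel image where single grayscale channel expected; "
            "extract the relevant channel before building the manifest"
        )
    if arr.ndim != 2:
        raise ValidationError(f"{path}: expected a 2-D raster, got shape {arr.shape}")
    scale = _BIT_DEPTH_MAX.get(arr.dtype)
    if scale is None:
        raise ValidationError(
            f"{path}: unsupported dtype {arr.dtype}; expected 8- or 16-bit unsigned"
        )
    return arr.astype(float) / scale


def load_batch(manifest: BatchManifest) -> list[MultiChannelImage]:
    """Load every manifest entry, in manifest order.

    Each raster is divided by its source bit-depth maximum so 255 in an
    8-bit file and 65535 in a 16-bit file both map to 1.0.  Blue/red
    dimension equality is enforced per entry.
    """
    images = []
    for entry in manifest.entries:
        blue = _read_gray(entry.blue_path)
        red = _read_gray(entry.red_path)
        bf = _read_gray(entry.brightfield_path) if entry.brightfield_path else None
        images.append(
            MultiChannelImage(
                blue=blue,
                red=red,
                brightfield=bf,
                condition_label=entry.condition_label,
                well_id=entry.well_id,
                pixel_size_um=manifest.pixel_size_um,
            )
        )
    return images


def merge_channels(img: MultiChannelImage, rule: str = "max") -> np.ndarray:
    """Merge blue and red channels into one grayscale raster in [0, 1].

    The default per-pixel maximum preserves both nucleus and cytoplasm
    signal without saturating where the channels overlap; ``"sum"``
    gives a clipped sum instead.
    """
    if img.blue.shape != img.red.shape:  # defensive; the dataclass enforces it
        raise ValidationError("channel dimensions differ")
    if rule == "max":
        return np.maximum(img.blue, img.red)
    if rule == "sum":
        return np.clip(img.blue + img.red, 0.0, 1.0)
    raise ValueError(f"unknown merge rule: {rule!r}")


def save_gray(path: str | Path, arr: np.ndarray, bit_depth: int = 8) -> None:
    """Write a [0, 1] float raster as an 8- or 16-bit grayscale file."""
    arr = np.asarray(arr, dtype=float)
    if arr.min() < 0 or arr.max() > 1:
        raise ValidationError("values outside [0, 1]")
    if bit_depth == 8:
        out = np.round(arr * 255).astype(np.uint8)
    elif bit_depth == 16:
        out = np.round(arr * 65535).astype(np.uint16)
    else:
        raise ValueError("bit_depth must be 8 or 16")
    iio.imwrite(Path(path), out)


def batch_red_max(images: Sequence[MultiChannelImage]) -> float:
    """Brightest red-channel pixel across all images of the batch.

    This is the normalisation constant for per-cell red intensities:
    one value for the whole batch, not per image or per condition.
    """
    if not images:
        raise ValidationError("empty batch")
    return float(max(img.red.max() for img in images))
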
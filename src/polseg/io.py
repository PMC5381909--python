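"""Reading and writing pipeline artifacts: intensity TIFF stacks, Delta_T
maps, masks, label maps and their color previews."""

from __future__ import annotations


from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

from .polarimetry import (ANALYZER_STATES, BACKGROUND_SENTINEL,
                          GENERATOR_STATES, DepolarizationMap,
                          PolarizationImageSet, PolarizationState)
from .segmentation import (LABEL_BACKGROUND, LABEL_CORE, LABEL_HEALTHY,
                           LABEL_RIM, LabelMap)

__all__ = [
    "write_image_set", "read_image_set",
    "write_delta", "read_delta",
    "write_labels", "read_labels",
    "write_mask", "read_mask",
    "label_colors", "write_label_preview", "write_delta_preview",
]

DEFAULT_PATTERN = "I_{gen}_{ana}.tif"

#: pseudo-colors: dark blue core, light blue rim, yellow healthy, black bg
LABEL_COLORS = {
    LABEL_BACKGROUND: (0, 0, 0),
    LABEL_CORE: (0, 0, 139),
    LABEL_RIM: (135, 206, 250),
    LABEL_HEALTHY: (255, 215, 0),
}


def write_image_set(images: PolarizationImageSet, outdir: str | Path,
                    pattern: str = DEFAULT_PATTERN) -> list[Path]:
    """Write the 24 intensity images as 32-bit float TIFFs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for (g, a), im in images.images.items():
        p = outdir / pattern.format(gen=g.value, ana=a.value)
        tifffile.imwrite(p, im.astype(np.float32))
        paths.append(p)
    return paths


def read_image_set(indir: str | Path,
                   pattern: str = DEFAULT_PATTERN) -> PolarizationImageSet:
    """Load a 24-image set written with :func:`write_image_set`."""
    indir = Path(indir)
    images = {}
    missing = []
    for g in GENERATOR_STATES:
        for a in ANALYZER_STATES:
            p = indir / pattern.format(gen=g.value, ana=a.value)
            if not p.exists():
                missing.append(p.name)
                continue
            images[(g, a)] = np.asarray(tifffile.imread(p), dtype=float)
    if missing:
        raise FileNotFoundError(f"missing intensity images: {', '.join(missing)}")
    return PolarizationImageSet(images)


def write_delta(dmap: DepolarizationMap, path: str | Path) -> Path:
    """Write Delta_T as 32-bit float TIFF (background stays NaN)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, dmap.delta.astype(np.float32))
    return path


def read_delta(path: str | Path, mask: np.ndarray | None = None,
               percent_scale: bool | None = None) -> DepolarizationMap:
    """Load a Delta_T map from TIFF or CSV.

    Values may be in [0, 1] or percent; percent is auto-detected when
    ``percent_scale`` is None (max value > 1.5).  Without an explicit mask,
    tissue is wherever the value is finite.
    """
    path = Path(path)
    if path.suffix.lower() == ".csv":
        delta = np.loadtxt(path, delimiter=",")
    else:
        delta = np.asarray(tifffile.imread(path), dtype=float)
    if percent_scale is None:
        finite = delta[np.isfinite(delta)]
        percent_scale = finite.size > 0 and np.nanmax(finite) > 1.5
    if percent_scale:
        delta = delta / 100.0
    if mask is None:
        mask = np.isfinite(delta)
    delta = np.where(mask, np.clip(delta, 0.0, 1.0), BACKGROUND_SENTINEL)
    return DepolarizationMap(delta=delta, mask=np.asarray(mask, dtype=bool))


def write_labels(labels: LabelMap, path: str | Path) -> Path:
    """Write the integer-coded label map as TIFF."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, labels.labels.astype(np.uint8))
    return path


def read_labels(path: str | Path) -> LabelMap:
    return LabelMap(labels=np.asarray(tifffile.imread(path), dtype=np.int64))


def write_mask(mask: np.ndarray, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    iio.imwrite(path, (np.asarray(mask, dtype=bool) * 255).astype(np.uint8))
    return path


def read_mask(path: str | Path) -> np.ndarray:
    return np.asarray(iio.imread(path)) > 127


def label_colors(labels: LabelMap) -> np.ndarray:
    """RGB rendering of a label map with the standard pseudo-colors."""
    rgb = np.zeros(labels.shape + (3,), dtype=np.uint8)
    for lab, color in LABEL_COLORS.items():
        rgb[labels.labels == lab] = color
    return rgb


def write_label_preview(labels: LabelMap, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    iio.imwrite(path, label_colors(labels))
    return path


def write_delta_preview(dmap: DepolarizationMap, path: str | Path) -> Path:
    """8-bit grayscale preview of the percent-scaled map (background black)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pct = np.where(dmap.mask, dmap.delta, 0.0)
    iio.imwrite(path, np.round(pct * 255).astype(np.uint8))
    return path
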
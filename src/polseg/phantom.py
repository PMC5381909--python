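"""Synthetic three-zone ablation-lesion phantoms with known ground truth.

A phantom is an elliptical tissue sample containing an irregular lesion core
surrounded by a fixed-width rim annulus, embedded in healthy tissue, on a
dark background.  Per-zone total-depolarization values are drawn from
Gaussian distributions whose default means and standard deviations are
0.833 +/- 0.035 (core), 0.877 +/- 0.014 (rim) and 0.915 +/- 0.013 (healthy),
matching the zone statistics reported for radiofrequency-ablated porcine
myocardium; a small masked blur creates the gradual inter-zone transitions
that defeat rigid thresholding.  Because the ground-truth label map is known
exactly, every downstream stage (Mueller simulation, reconstruction,
decomposition, segmentation, evaluation) is testable without any real data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .polarimetry import (BACKGROUND_SENTINEL, DepolarizationMap, MuellerImage,
                          PolarizationImageSet, forward_simulate)
from .segmentation import (LABEL_BACKGROUND, LABEL_CORE, LABEL_HEALTHY,
                           LABEL_RIM, LabelMap)

__all__ = ["PhantomSpec", "Phantom", "make_labels", "make_delta",
           "make_mueller_phantom", "generate", "suggest_rois"]

#: (mean, SD) of Delta_T per zone, in [0, 1].
DEFAULT_ZONE_STATS = {
    LABEL_CORE: (0.833, 0.035),
    LABEL_RIM: (0.877, 0.014),
    LABEL_HEALTHY: (0.915, 0.013),
}


@dataclass
class PhantomSpec:
    """Geometry, per-zone statistics and randomness of a synthetic lesion.

    Lengths are in pixels.  ``tissue_axes`` / ``core_axes`` are ellipse
    semi-axes (row, col); ``rim_width`` is the width of the annulus dilated
    around the core; ``transition_sigma`` blurs zone boundaries;
    ``boundary_irregularity`` is the relative amplitude of the low-order
    harmonic perturbation of the core outline.
    """

    height: int = 256
    width: int = 256
    tissue_center: tuple[float, float] = (128.0, 128.0)
    tissue_axes: tuple[float, float] = (112.0, 100.0)
    core_center: tuple[float, float] = (122.0, 132.0)
    core_axes: tuple[float, float] = (42.0, 34.0)
    rim_width: float = 12.0
    zone_stats: dict = field(default_factory=lambda: dict(DEFAULT_ZONE_STATS))
    transition_sigma: float = 1.0
    boundary_irregularity: float = 0.1
    seed: int = 42

    def __post_init__(self) -> None:
        if self.rim_width < 2:
            raise ValueError("rim_width must be >= 2 pixels")
        means = [self.zone_stats[k][0] for k in (LABEL_CORE, LABEL_RIM, LABEL_HEALTHY)]
        if not (means[0] < means[1] < means[2]):
            raise ValueError("zone means must be strictly increasing core < rim < healthy")


@dataclass
class Phantom:
    """A generated phantom: ground truth, depolarization map, optional images."""

    gt: LabelMap
    delta: DepolarizationMap
    spec: PhantomSpec
    images: PolarizationImageSet | None = None
    mueller: MuellerImage | None = None


def _ellipse_mask(shape, center, axes) -> np.ndarray:
    rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
    return (((rr - center[0]) / axes[0]) ** 2
            + ((cc - center[1]) / axes[1]) ** 2) <= 1.0


def make_labels(spec: PhantomSpec) -> LabelMap:
    """Deterministic ground-truth label map for a phantom spec.

    The core is an ellipse whose radius is perturbed by a fixed-seed
    low-order harmonic series (orders 2-5); the rim is the morphological
    dilation of the core by ``rim_width`` restricted to tissue; remaining
    tissue is healthy; everything outside the tissue ellipse is background.
    """
    shape = (spec.height, spec.width)
    tissue = _ellipse_mask(shape, spec.tissue_center, spec.tissue_axes)

    rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
    dr = rr - spec.core_center[0]
    dc = cc - spec.core_center[1]
    theta = np.arctan2(dc, dr)
    # radial distance normalized by the ellipse radius in that direction
    rho = np.sqrt((dr / spec.core_axes[0]) ** 2 + (dc / spec.core_axes[1]) ** 2)

    if spec.boundary_irregularity > 0:
        rng = np.random.default_rng(spec.seed)
        orders = np.arange(2, 6)
        a = rng.standard_normal(orders.size)
        b = rng.standard_normal(orders.size)
        f = sum(a[i] * np.cos(k * theta) + b[i] * np.sin(k * theta)
                for i, k in enumerate(orders))
        f = f / np.max(np.abs(f))
        boundary = 1.0 + spec.boundary_irregularity * f
    else:
        boundary = 1.0
    core = (rho <= boundary) & tissue
    if not core.any() or core.sum() >= tissue.sum():
        raise ValueError("core must be a strict nonempty subset of the tissue")

    # rim = dilation of core by rim_width (Euclidean), clipped to tissue
    dist = ndimage.distance_transform_edt(~core)
    rim = (dist <= spec.rim_width) & ~core & tissue
    if (core | rim).sum() >= tissue.sum():
        raise ValueError("core plus rim exceeds the tissue sample")

    labels = np.zeros(shape, dtype=np.int64)
    labels[tissue] = LABEL_HEALTHY
    labels[rim] = LABEL_RIM
    labels[core] = LABEL_CORE
    return LabelMap(labels=labels)


def make_delta(labels: LabelMap, spec: PhantomSpec,
               seed: int | None = None) -> DepolarizationMap:
    """Draw the per-pixel depolarization map for a ground-truth label map.

    The map is (blurred zone-mean structure) + (white per-zone noise),
    clipped to [0, 1].  The piecewise-constant map of zone means is blurred
    (mask-normalized) with ``transition_sigma`` to create the gradual
    inter-zone transitions; zero-mean Gaussian noise with each zone's SD is
    then added per pixel.  Keeping the noise out of the blur preserves the
    per-zone statistics exactly — an ROI measurement on the final map
    reports the spec's mean and SD — and keeps the noise white, matching
    the uncorrelated pixel noise of a real polarimetric image (the gradual
    transition is a tissue property; the noise is not).
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    mask = labels.mask
    mean_map = np.zeros(labels.shape)
    sd_map = np.zeros(labels.shape)
    for zone in (LABEL_CORE, LABEL_RIM, LABEL_HEALTHY):
        mean, sd = spec.zone_stats[zone]
        sel = labels.labels == zone
        mean_map[sel] = mean
        sd_map[sel] = sd
    if spec.transition_sigma > 0:
        mask_f = mask.astype(float)
        num = ndimage.gaussian_filter(mean_map * mask_f, spec.transition_sigma)
        den = ndimage.gaussian_filter(mask_f, spec.transition_sigma)
        with np.errstate(invalid="ignore", divide="ignore"):
            mean_map = np.where(mask, num / den, 0.0)
    delta = mean_map + sd_map * rng.standard_normal(labels.shape)
    delta = np.clip(delta, 0.0, 1.0)
    out = np.where(mask, delta, BACKGROUND_SENTINEL)
    return DepolarizationMap(delta=out, mask=mask)


def make_mueller_phantom(dmap: DepolarizationMap) -> MuellerImage:
    """Ideal isotropic-depolarizer Mueller field realizing a Delta_T map.

    Each tissue pixel becomes diag(1, a, a, a) with a = 1 - Delta_T, whose
    polar decomposition returns exactly that Delta_T.  Background pixels get
    the zero matrix (no light), so they come back dark and are masked out by
    the intensity threshold on reconstruction.
    """
    h, w = dmap.shape
    m = np.zeros((h, w, 4, 4))
    a = np.where(dmap.mask, 1.0 - dmap.delta, 0.0)
    m[..., 0, 0] = dmap.mask.astype(float)
    for i in (1, 2, 3):
        m[..., i, i] = a * dmap.mask
    return MuellerImage(m)


def generate(spec: PhantomSpec | None = None, with_images: bool = False,
             noise_sd: float = 0.0, seed: int | None = None) -> Phantom:
    """Generate a complete phantom; optionally also the 24 intensity images.

    ``seed`` overrides ``spec.seed`` for both geometry and noise draws.
    """
    spec = spec or PhantomSpec()
    if seed is not None:
        # re-seed geometry and value draws coherently
        spec = PhantomSpec(**{**spec.__dict__, "seed": seed})
    gt = make_labels(spec)
    dmap = make_delta(gt, spec)
    images = None
    mueller = None
    if with_images:
        mueller = make_mueller_phantom(dmap)
        images = forward_simulate(mueller, noise_sd=noise_sd,
                                  seed=spec.seed + 1)
    return Phantom(gt=gt, delta=dmap, spec=spec, images=images, mueller=mueller)


def suggest_rois(gt: LabelMap, roi_size: int = 50,
                 min_tissue: float = 0.9) -> list[tuple[int, int]]:
    """Pick one roi_size x roi_size ROI origin per zone (core, rim, healthy).

    For each zone, returns the window origin maximizing that zone's pixel
    count, among windows with at least ``min_tissue`` tissue coverage —
    emulating the manual placement of ROIs near each zone's center.
    """
    mask_cov = ndimage.uniform_filter(gt.mask.astype(float), size=roi_size,
                                      mode="constant")
    origins = []
    half = roi_size // 2
    for zone in (LABEL_CORE, LABEL_RIM, LABEL_HEALTHY):
        cov = ndimage.uniform_filter((gt.labels == zone).astype(float),
                                     size=roi_size, mode="constant")
        score = np.where(mask_cov >= min_tissue, cov, -1.0)
        # valid window centers only (window fully inside image)
        h, w = gt.shape
        score[:half, :] = -1
        score[h - half:, :] = -1
        score[:, :half] = -1
        score[:, w - half:] = -1
        idx = np.unravel_index(np.argmax(score), score.shape)
        if score[idx] < 0:
            raise ValueError(f"no valid ROI window found for zone {zone}")
        origins.append((int(idx[0] - half), int(idx[1] - half)))
    return origins
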
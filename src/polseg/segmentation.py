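"""Local fuzzy thresholding of depolarization maps, plus the global rigid
thresholding baseline.

The local fuzzy method models the tissue histogram as an L-component Gaussian
mixture h(I) ~ sum_l w_l p_l(x; theta_l), assigns every pixel a fuzzy
membership vector (the posterior responsibility under the mixture), averages
memberships over each pixel's spatial neighborhood, and labels by argmax.
The neighborhood aggregation is what suppresses the isolated misclassified
pixels that plain intensity cut-offs produce.

Class identity is the rank of the mixture mean: the ablation core has the
lowest total depolarization, the rim is intermediate, healthy tissue highest.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .polarimetry import BACKGROUND_SENTINEL, DepolarizationMap

__all__ = [
    "LABEL_BACKGROUND",
    "LABEL_CORE",
    "LABEL_RIM",
    "LABEL_HEALTHY",
    "MixtureModel",
    "MembershipField",
    "LabelMap",
    "SegmentationConfig",
    "preprocess",
    "fit_mixture",
    "memberships",
    "aggregate",
    "classify",
    "segment_local_fuzzy",
    "global_cutoffs",
    "segment_global",
]

LABEL_BACKGROUND = 0
LABEL_CORE = 1
LABEL_RIM = 2
LABEL_HEALTHY = 3

LABEL_NAMES = {
    LABEL_BACKGROUND: "background",
    LABEL_CORE: "core",
    LABEL_RIM: "rim",
    LABEL_HEALTHY: "healthy",
}


@dataclass
class MixtureModel:
    """Fitted 1-D Gaussian mixture; components sorted ascending by mean."""

    weights: np.ndarray
    means: np.ndarray
    variances: np.ndarray
    log_likelihood: float = np.nan
    n_iter: int = 0

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.means = np.asarray(self.means, dtype=float)
        self.variances = np.asarray(self.variances, dtype=float)
        if not (len(self.weights) == len(self.means) == len(self.variances)):
            raise ValueError("component arrays must have equal length")
        if abs(self.weights.sum() - 1.0) > 1e-9 or np.any(self.weights < 0):
            raise ValueError("weights must be nonnegative and sum to 1")
        if np.any(self.variances <= 0):
            raise ValueError("variances must be positive")
        if np.any(np.diff(self.means) <= 0):
            raise ValueError("means must be strictly ascending")

    @property
    def L(self) -> int:
        return len(self.means)

    def component_pdf(self, x: np.ndarray) -> np.ndarray:
        """Per-component Gaussian densities, shape (..., L)."""
        x = np.asarray(x, dtype=float)[..., None]
        var = self.variances
        return np.exp(-0.5 * (x - self.means) ** 2 / var) / np.sqrt(2 * np.pi * var)

    def pdf(self, x: np.ndarray) -> np.ndarray:
        """Mixture density h(x) = sum_l w_l p_l(x)."""
        return self.component_pdf(x) @ self.weights

    def responsibilities(self, x: np.ndarray) -> np.ndarray:
        """Posterior membership w_l p_l(x) / sum_k w_k p_k(x), shape (..., L).

        Pixels where every component density underflows are assigned crisp
        membership in the nearest-mean component.
        """
        x = np.asarray(x, dtype=float)
        # work in log space to dodge underflow for extreme x
        var = self.variances
        log_p = (-0.5 * (x[..., None] - self.means) ** 2 / var
                 - 0.5 * np.log(2 * np.pi * var) + np.log(self.weights))
        log_p -= log_p.max(axis=-1, keepdims=True)
        p = np.exp(log_p)
        return p / p.sum(axis=-1, keepdims=True)


@dataclass
class MembershipField:
    """Per-pixel fuzzy membership vector over the L classes, shape (H, W, L).

    At masked pixels memberships are in [0, 1] and sum to 1; background
    pixels hold zeros.
    """

    mu: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mu.shape[:2] != self.mask.shape:
            raise ValueError("membership / mask shape mismatch")
        inside = self.mu[self.mask]
        if inside.size:
            if np.any(inside < -1e-9) or np.any(inside > 1 + 1e-9):
                raise ValueError("memberships must lie in [0, 1]")
            sums = inside.sum(axis=-1)
            if np.any(np.abs(sums - 1.0) > 1e-6):
                raise ValueError("memberships must sum to 1 at masked pixels")

    @property
    def L(self) -> int:
        return self.mu.shape[-1]


@dataclass
class LabelMap:
    """Per-pixel categorical map: 0 background, 1 core, 2 rim, 3 healthy."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            self.labels = self.labels.astype(np.int64)

    @property
    def mask(self) -> np.ndarray:
        return self.labels != LABEL_BACKGROUND

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def class_pixels(self, label: int) -> np.ndarray:
        return self.labels == label


@dataclass
class SegmentationConfig:
    """Tunable parameters of the local fuzzy thresholding pipeline.

    smooth_sigma : Gaussian pre-smoothing width in pixels (0 disables).
    window : odd side length of the square aggregation neighborhood.
    n_aggregation_passes : how many times memberships are re-averaged.
    """

    L: int = 3
    smooth_sigma: float = 1.5
    window: int = 3
    n_aggregation_passes: int = 2
    em_max_iter: int = 300
    em_tol: float = 1e-7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.L < 2:
            raise ValueError("need at least 2 classes")
        if self.window < 1 or self.window % 2 == 0:
            raise ValueError("window must be odd and >= 1")
        if self.smooth_sigma < 0:
            raise ValueError("smooth_sigma must be >= 0")


# ---------------------------------------------------------------------------
# Stage 1: pre-processing


def preprocess(dmap: DepolarizationMap, smooth_sigma: float) -> DepolarizationMap:
    """Masked Gaussian smoothing of the depolarization map.

    Uses normalized convolution — blur(value * mask) / blur(mask) — so the
    background sentinel never bleeds into tissue values.  sigma 0 returns the
    input unchanged.
    """
    if not dmap.mask.any():
        raise ValueError("empty tissue mask")
    if smooth_sigma == 0:
        return dmap
    mask_f = dmap.mask.astype(float)
    filled = np.where(dmap.mask, dmap.delta, 0.0)
    num = ndimage.gaussian_filter(filled, smooth_sigma, mode="constant")
    den = ndimage.gaussian_filter(mask_f, smooth_sigma, mode="constant")
    with np.errstate(invalid="ignore", divide="ignore"):
        smoothed = num / den
    out = np.where(dmap.mask, np.clip(smoothed, 0.0, 1.0), BACKGROUND_SENTINEL)
    return DepolarizationMap(delta=out, mask=dmap.mask.copy())


# ---------------------------------------------------------------------------
# Stage 2: histogram mixture fit (EM)


def _initial_components(x: np.ndarray, L: int, var_floor: float):
    """Deterministic EM seed: multi-Otsu partition, quantile fallback."""
    groups = None
    try:
        from skimage.filters import threshold_multiotsu
        th = threshold_multiotsu(x, classes=L)
        groups = np.digitize(x, th)
        if len(np.unique(groups)) < L:
            groups = None
    except Exception:
        groups = None
    if groups is None:
        qs = np.quantile(x, np.arange(1, L) / L)
        groups = np.digitize(x, qs)
    means = np.empty(L)
    variances = np.empty(L)
    weights = np.empty(L)
    pooled = max(x.var(), var_floor)
    for g in range(L):
        sel = x[groups == g]
        weights[g] = max(sel.size / x.size, 1e-6)
        means[g] = sel.mean() if sel.size else np.quantile(x, (2 * g + 1) / (2 * L))
        variances[g] = max(sel.var(), var_floor) if sel.size > 1 else pooled
    weights /= weights.sum()
    return means, variances, weights


def fit_mixture(values: np.ndarray, L: int = 3, seed: int = 0,
                em_max_iter: int = 300, em_tol: float = 1e-7,
                var_floor: float = 1e-12) -> MixtureModel:
    """Fit an L-component 1-D Gaussian mixture to the tissue histogram by EM.

    Initialization is deterministic: the values are partitioned into L groups
    by multi-Otsu thresholding of their histogram and each component starts
    from its group's mass, mean and variance.  (Otsu partitioning tracks the
    histogram's actual modes even when zone areas are very unequal — e.g. a
    small lesion in a large healthy sample — where equal-mass quantile
    seeding drops a component into the dominant peak and EM stalls in a
    local optimum that splits it.)  If thresholding fails, equal-mass
    quantile seeding is the fallback.  The log-likelihood is non-decreasing
    across iterations; iteration stops when its change drops below ``em_tol``
    or at ``em_max_iter``.  Components are reordered ascending by mean on
    return.

    Raises on degenerate (constant) data; floors collapsing variances with a
    warning.
    """
    x = np.asarray(values, dtype=float).ravel()
    x = x[np.isfinite(x)]
    if L < 2:
        raise ValueError("need at least 2 components")
    if x.size < 10 * L:
        raise ValueError(f"need at least {10 * L} values, got {x.size}")
    if np.ptp(x) == 0:
        raise ValueError("histogram not multimodal: all values identical")

    means, variances, weights = _initial_components(x, L, var_floor)

    prev_ll = -np.inf
    n_iter = 0
    ll = prev_ll
    floored = False
    for n_iter in range(1, em_max_iter + 1):
        # E step (log-space responsibilities)
        log_p = (-0.5 * (x[:, None] - means) ** 2 / variances
                 - 0.5 * np.log(2 * np.pi * variances) + np.log(weights))
        m = log_p.max(axis=1, keepdims=True)
        p = np.exp(log_p - m)
        norm = p.sum(axis=1, keepdims=True)
        resp = p / norm
        ll = float(np.sum(m.ravel() + np.log(norm.ravel())))
        # EM guarantee; violation signals a bug (variance flooring is an
        # off-model intervention and legitimately breaks the guarantee)
        if not floored and ll + 1e-9 < prev_ll:
            raise RuntimeError("EM log-likelihood decreased")
        converged = ll - prev_ll < em_tol
        prev_ll = ll
        if converged and n_iter > 1:
            break
        # M step
        nk = resp.sum(axis=0)
        nk = np.maximum(nk, 1e-300)
        weights = nk / x.size
        means = (resp * x[:, None]).sum(axis=0) / nk
        variances = (resp * (x[:, None] - means) ** 2).sum(axis=0) / nk
        if np.any(variances < var_floor):
            warnings.warn("mixture component variance collapsed; flooring",
                          RuntimeWarning, stacklevel=2)
            variances = np.maximum(variances, var_floor)
            floored = True

    order = np.argsort(means)
    means, variances, weights = means[order], variances[order], weights[order]
    if np.any(np.diff(means) <= 0):
        raise ValueError("histogram not multimodal: coincident component means")
    return MixtureModel(weights=weights, means=means, variances=variances,
                        log_likelihood=ll, n_iter=n_iter)


# ---------------------------------------------------------------------------
# Stage 3: fuzzy membership functions


def memberships(dmap: DepolarizationMap, model: MixtureModel) -> MembershipField:
    """Assign each tissue pixel its membership vector under the mixture.

    The membership of pixel r in class l is the posterior responsibility
    mu_l(r) = w_l p_l(I(r)) / sum_k w_k p_k(I(r)).
    """
    mu = np.zeros(dmap.shape + (model.L,))
    vals = dmap.delta[dmap.mask]
    mu[dmap.mask] = model.responsibilities(vals)
    return MembershipField(mu=mu, mask=dmap.mask.copy())


# ---------------------------------------------------------------------------
# Stage 4: neighborhood aggregation


def aggregate(fld: MembershipField, window: int = 3, passes: int = 2) -> MembershipField:
    """Average each membership channel over the window x window neighborhood.

    Background pixels are excluded from every average (mask-normalized mean
    filter); after each pass memberships are renormalized across classes.
    Uniform fields are a fixed point.
    """
    if window % 2 == 0 or window < 1:
        raise ValueError("window must be odd and >= 1")
    if window > min(fld.mask.shape):
        raise ValueError("window larger than image")
    mu = fld.mu.copy()
    mask_f = fld.mask.astype(float)
    den = ndimage.uniform_filter(mask_f, size=window, mode="constant")
    for _ in range(passes):
        for l in range(fld.L):
            num = ndimage.uniform_filter(mu[..., l] * mask_f, size=window,
                                         mode="constant")
            with np.errstate(invalid="ignore", divide="ignore"):
                mu[..., l] = np.where(fld.mask, num / den, 0.0)
        total = mu.sum(axis=-1, keepdims=True)
        mu = np.where(fld.mask[..., None], mu / np.where(total > 0, total, 1.0), 0.0)
    return MembershipField(mu=mu, mask=fld.mask.copy())


# ---------------------------------------------------------------------------
# Stage 5: final labeling


def classify(fld: MembershipField) -> LabelMap:
    """Label each tissue pixel by its maximal membership.

    Ties break toward the lower-mean class (argmax returns the first
    maximum, and class order is ascending in mean), i.e. toward calling
    lesion rather than healthy.
    """
    labels = np.zeros(fld.mask.shape, dtype=np.int64)
    # class index l -> label l+1 (0 is background)
    labels[fld.mask] = np.argmax(fld.mu[fld.mask], axis=-1) + 1
    return LabelMap(labels=labels)


# ---------------------------------------------------------------------------
# End-to-end drivers


@dataclass
class FuzzySegmentationResult:
    """Label map plus every intermediate stage, for inspection."""

    labels: LabelMap
    smoothed: DepolarizationMap
    model: MixtureModel
    memberships_initial: MembershipField
    memberships_aggregated: MembershipField


def segment_local_fuzzy(dmap: DepolarizationMap,
                        config: SegmentationConfig | None = None,
                        return_intermediates: bool = False):
    """Run the five-step local fuzzy thresholding pipeline.

    preprocess -> fit_mixture -> memberships -> aggregate -> classify.
    Deterministic for a given input and config.
    """
    cfg = config or SegmentationConfig()
    smoothed = preprocess(dmap, cfg.smooth_sigma)
    model = fit_mixture(smoothed.values(), L=cfg.L, seed=cfg.seed,
                        em_max_iter=cfg.em_max_iter, em_tol=cfg.em_tol)
    mu0 = memberships(smoothed, model)
    mu = aggregate(mu0, window=cfg.window, passes=cfg.n_aggregation_passes)
    labels = classify(mu)
    if return_intermediates:
        return FuzzySegmentationResult(labels=labels, smoothed=smoothed,
                                       model=model, memberships_initial=mu0,
                                       memberships_aggregated=mu)
    return labels


def global_cutoffs(dmap: DepolarizationMap,
                   roi_origins: list[tuple[int, int]],
                   roi_size: int = 50) -> tuple[float, float]:
    """Derive the two rigid cut-offs from per-zone ROI mean depolarizations.

    Each ROI is a roi_size x roi_size square given by its (row, col) origin,
    one per zone; the cut-offs are the midpoints between the sorted ROI
    means.  ROIs must lie inside the image with >= 90% tissue coverage.
    """
    if len(roi_origins) != 3:
        raise ValueError("exactly three ROIs required (core, rim, healthy)")
    h, w = dmap.shape
    means = []
    for r0, c0 in roi_origins:
        r0, c0 = int(r0), int(c0)
        if r0 < 0 or c0 < 0 or r0 + roi_size > h or c0 + roi_size > w:
            raise ValueError(f"ROI at ({r0}, {c0}) extends outside the image")
        sub_mask = dmap.mask[r0:r0 + roi_size, c0:c0 + roi_size]
        if sub_mask.mean() < 0.9:
            raise ValueError(f"ROI at ({r0}, {c0}) has <90% tissue coverage")
        sub = dmap.delta[r0:r0 + roi_size, c0:c0 + roi_size]
        means.append(float(np.mean(sub[sub_mask])))
    means = np.sort(means)
    if np.any(np.diff(means) == 0):
        raise ValueError("zones not separable: identical ROI means")
    return (float((means[0] + means[1]) / 2), float((means[1] + means[2]) / 2))


def segment_global(dmap: DepolarizationMap,
                   cutoffs: tuple[float, float]) -> LabelMap:
    """Global rigid thresholding: classify each pixel by fixed cut-offs.

    Delta_T < cutoff_low -> core; cutoff_low <= Delta_T < cutoff_high -> rim;
    else healthy.  No smoothing, no spatial context — this deliberately
    reproduces the isolated-pixel artifact of hard thresholding.
    """
    low, high = cutoffs
    if not low < high:
        raise ValueError("cutoff_low must be < cutoff_high")
    labels = np.zeros(dmap.shape, dtype=np.int64)
    d = dmap.delta
    labels[dmap.mask & (d < low)] = LABEL_CORE
    labels[dmap.mask & (d >= low) & (d < high)] = LABEL_RIM
    labels[dmap.mask & (d >= high)] = LABEL_HEALTHY
    return LabelMap(labels=labels)


def count_isolated_pixels(labels: LabelMap, target: int) -> int:
    """Number of single-pixel 8-connected components of a class."""
    binary = labels.class_pixels(target)
    structure = np.ones((3, 3), dtype=bool)
    lab, n = ndimage.label(binary, structure=structure)
    if n == 0:
        return 0
    sizes = np.bincount(lab.ravel())[1:]
    return int(np.sum(sizes == 1))
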
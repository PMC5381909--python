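"""Mueller-matrix polarimetry: forward intensity model, per-pixel Mueller
reconstruction, and Lu-Chipman polar decomposition.

The measurement model is a polarization-state generator (PSG) cycling through
four input states (H, V, +45 linear, right circular) and a polarization-state
analyzer (PSA) projecting onto six output states (H, V, +45, -45, right, left
circular), giving 24 intensity images.  The per-pixel 4x4 Mueller matrix M is
recovered from Stokes-vector differences of those intensities, and the total
depolarization Delta_T is extracted from the depolarizer factor of the polar
decomposition M = M_delta . M_R . M_D.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

__all__ = [
    "PolarizationState",
    "GENERATOR_STATES",
    "ANALYZER_STATES",
    "PolarizationImageSet",
    "MuellerImage",
    "PolarDecomposition",
    "DepolarizationMap",
    "BACKGROUND_SENTINEL",
    "stokes_of",
    "forward_simulate",
    "reconstruct_mueller",
    "polar_decompose",
    "depolarization_map",
]

#: Value stored at background (non-tissue) pixels of a DepolarizationMap.
BACKGROUND_SENTINEL = np.nan


class PolarizationState(str, Enum):
    """The ten pure polarization states used by the PSG/PSA optics.

    Linear states are named by their orientation (H = 0 deg, V = 90 deg,
    P45 = +45 deg, M45 = -45 deg); circular states by handedness.
    """

    H = "H"
    V = "V"
    P45 = "P45"
    M45 = "M45"
    R = "R"
    L = "L"

    @property
    def is_linear(self) -> bool:
        return self in (PolarizationState.H, PolarizationState.V,
                        PolarizationState.P45, PolarizationState.M45)


GENERATOR_STATES = (
    PolarizationState.H,
    PolarizationState.V,
    PolarizationState.P45,
    PolarizationState.R,
)

ANALYZER_STATES = (
    PolarizationState.H,
    PolarizationState.V,
    PolarizationState.P45,
    PolarizationState.M45,
    PolarizationState.R,
    PolarizationState.L,
)

_STOKES = {
    PolarizationState.H: np.array([1.0, 1.0, 0.0, 0.0]),
    PolarizationState.V: np.array([1.0, -1.0, 0.0, 0.0]),
    PolarizationState.P45: np.array([1.0, 0.0, 1.0, 0.0]),
    PolarizationState.M45: np.array([1.0, 0.0, -1.0, 0.0]),
    PolarizationState.R: np.array([1.0, 0.0, 0.0, 1.0]),
    PolarizationState.L: np.array([1.0, 0.0, 0.0, -1.0]),
}


def stokes_of(state: PolarizationState) -> np.ndarray:
    """Unit-intensity Stokes vector of a pure polarization state.

    Linear at angle theta maps to (1, cos 2theta, sin 2theta, 0); right/left
    circular map to (1, 0, 0, +/-1).
    """
    state = PolarizationState(state)
    try:
        return _STOKES[state].copy()
    except KeyError:  # pragma: no cover - enum already restricts
        raise ValueError(f"unsupported polarization state: {state!r}")


@dataclass
class PolarizationImageSet:
    """The 24 co-registered PSGxPSA intensity images.

    ``images`` maps ``(generator, analyzer)`` state pairs to 2-D nonnegative
    float arrays of identical shape.
    """

    images: dict[tuple[PolarizationState, PolarizationState], np.ndarray]

    def __post_init__(self) -> None:
        expected = {(g, a) for g in GENERATOR_STATES for a in ANALYZER_STATES}
        got = set(self.images)
        missing = expected - got
        if missing:
            names = sorted(f"({g.value},{a.value})" for g, a in missing)
            raise ValueError(f"missing state pairs: {', '.join(names)}")
        extra = got - expected
        if extra:
            raise ValueError(f"unexpected state pairs: {sorted(extra)}")
        shapes = {im.shape for im in self.images.values()}
        if len(shapes) != 1:
            raise ValueError(f"images have inconsistent shapes: {shapes}")
        for key, im in self.images.items():
            if not np.all(np.isfinite(im)):
                raise ValueError(f"non-finite intensities in image {key}")
            if np.any(im < 0):
                raise ValueError(f"negative intensities in image {key}")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.images.values())).shape

    @property
    def height(self) -> int:
        return self.shape[0]

    @property
    def width(self) -> int:
        return self.shape[1]

    def __getitem__(self, key):
        return self.images[key]

    def total_intensity(self) -> np.ndarray:
        """Sum of all 24 intensity images (used for background masking)."""
        return np.sum([im for im in self.images.values()], axis=0)


@dataclass
class MuellerImage:
    """Per-pixel 4x4 real Mueller matrix field, shape (H, W, 4, 4)."""

    m: np.ndarray

    def __post_init__(self) -> None:
        self.m = np.asarray(self.m, dtype=float)
        if self.m.ndim != 4 or self.m.shape[-2:] != (4, 4):
            raise ValueError(f"expected (H, W, 4, 4) array, got {self.m.shape}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.m.shape[:2]

    @property
    def m00(self) -> np.ndarray:
        return self.m[..., 0, 0]


@dataclass
class PolarDecomposition:
    """Lu-Chipman factors and the scalar maps derived from them.

    ``delta_total`` is 1 - |tr(m_delta)|/3 with m_delta the 3x3 block of the
    depolarizer factor; ``valid`` marks pixels where the factorization
    succeeded (non-singular diattenuator, finite input).
    """

    m_depol: np.ndarray
    m_ret: np.ndarray
    m_diatt: np.ndarray
    delta_total: np.ndarray
    retardance: np.ndarray
    diattenuation: np.ndarray
    valid: np.ndarray


@dataclass
class DepolarizationMap:
    """Per-pixel total depolarization Delta_T in [0, 1] with a tissue mask.

    Background pixels hold ``BACKGROUND_SENTINEL`` (NaN) and are excluded
    from every statistic, histogram and neighborhood average downstream.
    """

    delta: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.delta = np.asarray(self.delta, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.delta.shape != self.mask.shape:
            raise ValueError(
                f"delta shape {self.delta.shape} != mask shape {self.mask.shape}")
        inside = self.delta[self.mask]
        if inside.size and (np.any(inside < 0) or np.any(inside > 1)
                            or not np.all(np.isfinite(inside))):
            raise ValueError("masked delta values must be finite and in [0, 1]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.delta.shape

    def values(self) -> np.ndarray:
        """1-D array of Delta_T at tissue pixels."""
        if not self.mask.any():
            raise ValueError("no tissue pixels in mask")
        return self.delta[self.mask]

    def percent(self) -> np.ndarray:
        """Delta_T rendered as percent (background stays NaN)."""
        out = np.where(self.mask, self.delta * 100.0, BACKGROUND_SENTINEL)
        return out


# ---------------------------------------------------------------------------
# Forward model


def forward_simulate(mueller: MuellerImage, noise_sd: float = 0.0,
                     seed: int | None = None) -> PolarizationImageSet:
    """Simulate the 24 PSG/PSA intensity images of a Mueller matrix field.

    For generator state ``g`` and analyzer state ``a`` the detected intensity
    is the ideal-polarizer projection ``I = 0.5 * (S0 + S . a_vec)`` where
    ``S = M @ stokes_of(g)`` and ``a_vec`` is the analyzer's normalized Stokes
    direction.  Optional multiplicative Gaussian noise of relative standard
    deviation ``noise_sd`` is applied per pixel; intensities are clipped at 0.
    """
    if not np.all(np.isfinite(mueller.m)):
        raise ValueError("Mueller image contains non-finite elements")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    images: dict[tuple[PolarizationState, PolarizationState], np.ndarray] = {}
    for g in GENERATOR_STATES:
        s_out = mueller.m @ stokes_of(g)  # (H, W, 4)
        for a in ANALYZER_STATES:
            # ideal analyzer projection: I = 0.5 * (S0 + S1 a1 + S2 a2 + S3 a3)
            intensity = 0.5 * (s_out @ stokes_of(a))
            if noise_sd > 0:
                intensity = intensity * (1.0 + noise_sd * rng.standard_normal(intensity.shape))
            images[(g, a)] = np.clip(intensity, 0.0, None)
    return PolarizationImageSet(images)


# ---------------------------------------------------------------------------
# Mueller reconstruction


def reconstruct_mueller(images: PolarizationImageSet) -> MuellerImage:
    """Recover the per-pixel Mueller matrix from the 24-image set.

    For each generator state the output Stokes vector is assembled from the
    six analyzer intensities,

        S0 = I_H + I_V,   S1 = I_H - I_V,
        S2 = I_P45 - I_M45,   S3 = I_R - I_L,

    and the Mueller columns follow from the four input states:
    col0 = (S(H)+S(V))/2, col1 = (S(H)-S(V))/2, col2 = S(P45) - col0,
    col3 = S(R) - col0.  This inverts :func:`forward_simulate` exactly in the
    noiseless case.
    """
    P = PolarizationState

    def stokes_out(g: PolarizationState) -> np.ndarray:
        s0 = images[(g, P.H)] + images[(g, P.V)]
        s1 = images[(g, P.H)] - images[(g, P.V)]
        s2 = images[(g, P.P45)] - images[(g, P.M45)]
        s3 = images[(g, P.R)] - images[(g, P.L)]
        return np.stack([s0, s1, s2, s3], axis=-1)

    s_h = stokes_out(P.H)
    s_v = stokes_out(P.V)
    s_p = stokes_out(P.P45)
    s_r = stokes_out(P.R)

    col0 = 0.5 * (s_h + s_v)
    col1 = 0.5 * (s_h - s_v)
    col2 = s_p - col0
    col3 = s_r - col0
    m = np.stack([col0, col1, col2, col3], axis=-1)  # (H, W, 4, 4)
    return MuellerImage(m)


# ---------------------------------------------------------------------------
# Lu-Chipman polar decomposition


def _diattenuator_factor(m_norm: np.ndarray):
    """Build M_D and its inverse from the first row of the normalized M.

    Returns (M_D, M_D_inv, diattenuation, singular_mask) on flattened pixels.
    """
    n = m_norm.shape[0]
    d_vec = m_norm[:, 0, 1:]  # (n, 3)
    d_mag = np.linalg.norm(d_vec, axis=1)
    singular = d_mag >= 1.0 - 1e-9

    d_safe = np.clip(d_mag, 0.0, 1.0 - 1e-9)
    sqrt_term = np.sqrt(1.0 - d_safe**2)

    # m_D = sqrt(1-D^2) I3 + (1 - sqrt(1-D^2)) Dhat Dhat^T
    with np.errstate(invalid="ignore", divide="ignore"):
        d_hat = np.where(d_mag[:, None] > 1e-300, d_vec / np.maximum(d_mag[:, None], 1e-300), 0.0)
    outer = d_hat[:, :, None] * d_hat[:, None, :]
    eye3 = np.broadcast_to(np.eye(3), (n, 3, 3))
    m_d_small = sqrt_term[:, None, None] * eye3 + (1.0 - sqrt_term)[:, None, None] * outer

    m_d = np.zeros((n, 4, 4))
    m_d[:, 0, 0] = 1.0
    m_d[:, 0, 1:] = d_vec
    m_d[:, 1:, 0] = d_vec
    m_d[:, 1:, 1:] = m_d_small

    # closed-form inverse of a pure diattenuator: 1/(1-D^2) * M_D(-D) with
    # adjusted 3x3 block; use numpy solve for robustness instead
    m_d_inv = np.empty_like(m_d)
    ok = ~singular
    if ok.any():
        m_d_inv[ok] = np.linalg.inv(m_d[ok])
    m_d_inv[singular] = np.eye(4)
    return m_d, m_d_inv, d_mag, singular


def polar_decompose(mueller: MuellerImage, mask: np.ndarray | None = None,
                    atol: float = 1e-12) -> PolarDecomposition:
    """Lu-Chipman polar decomposition M = M_delta . M_R . M_D per pixel.

    The matrix is normalized by m00; the diattenuator factor M_D comes from
    the first row, M' = M M_D^-1 is split by eigen-analysis of m'(m')^T into
    the depolarizer block m_delta (sign fixed by det m'), and the retarder is
    M_R = M_delta^-1 M'.  Total depolarization is Delta_T = 1 - |tr m_delta|/3,
    clamped to [0, 1]; retardance is acos(tr(M_R)/2 - 1).

    Pixels with m00 <= 0 or a singular diattenuator (|D| >= 1) are flagged
    invalid rather than imputed.
    """
    m = mueller.m
    if not np.all(np.isfinite(m)):
        raise ValueError("Mueller image contains non-finite elements")
    h, w = mueller.shape
    flat = m.reshape(-1, 4, 4)
    n = flat.shape[0]

    if mask is None:
        mask_flat = np.ones(n, dtype=bool)
    else:
        mask_flat = np.asarray(mask, dtype=bool).reshape(-1)

    m00 = flat[:, 0, 0]
    valid = mask_flat & (m00 > 0)
    m_norm = np.where(valid[:, None, None],
                      flat / np.where(m00 > 0, m00, 1.0)[:, None, None],
                      np.broadcast_to(np.eye(4), flat.shape))

    m_d, m_d_inv, d_mag, singular = _diattenuator_factor(m_norm)
    valid &= ~singular

    m_prime = m_norm @ m_d_inv
    mp = m_prime[:, 1:, 1:]  # 3x3 block m'
    p_delta = m_prime[:, 1:, 0]

    mmt = mp @ mp.transpose(0, 2, 1)
    # symmetrize against roundoff before the eigen-solve
    mmt = 0.5 * (mmt + mmt.transpose(0, 2, 1))
    lam = np.linalg.eigvalsh(mmt)
    lam = np.clip(lam, 0.0, None)
    s = np.sqrt(lam)  # singular values of m', ascending
    s1, s2, s3 = s[:, 2], s[:, 1], s[:, 0]

    det = np.linalg.det(mp)
    sign = np.where(det < 0, -1.0, 1.0)

    eye3 = np.broadcast_to(np.eye(3), (n, 3, 3))
    lhs = mmt + (s1 * s2 + s2 * s3 + s3 * s1)[:, None, None] * eye3
    rhs = (s1 + s2 + s3)[:, None, None] * mmt + (s1 * s2 * s3)[:, None, None] * eye3

    m_delta_small = np.empty((n, 3, 3))
    solvable = valid & (np.abs(np.linalg.det(lhs)) > atol)
    if solvable.any():
        m_delta_small[solvable] = sign[solvable, None, None] * np.linalg.solve(
            lhs[solvable], rhs[solvable])
    # fully depolarizing pixels (m' ~ 0): m_delta -> 0
    m_delta_small[~solvable] = 0.0

    delta_total = 1.0 - np.abs(np.trace(m_delta_small, axis1=1, axis2=2)) / 3.0
    delta_total = np.clip(delta_total, 0.0, 1.0)

    m_depol = np.zeros((n, 4, 4))
    m_depol[:, 0, 0] = 1.0
    m_depol[:, 1:, 0] = p_delta
    m_depol[:, 1:, 1:] = m_delta_small

    # retarder: M_R = M_delta^-1 M'; for near-singular m_delta fall back to
    # identity retarder (pure depolarizer pixel)
    m_ret = np.broadcast_to(np.eye(4), (n, 4, 4)).copy()
    det_md = np.abs(np.linalg.det(m_delta_small))
    invertible = valid & (det_md > atol)
    if invertible.any():
        m_ret[invertible] = np.linalg.solve(m_depol[invertible], m_prime[invertible])

    tr_r = np.trace(m_ret, axis1=1, axis2=2)
    retardance = np.arccos(np.clip(tr_r / 2.0 - 1.0, -1.0, 1.0))

    shape2 = (h, w)
    return PolarDecomposition(
        m_depol=m_depol.reshape(h, w, 4, 4),
        m_ret=m_ret.reshape(h, w, 4, 4),
        m_diatt=m_d.reshape(h, w, 4, 4),
        delta_total=delta_total.reshape(shape2),
        retardance=retardance.reshape(shape2),
        diattenuation=np.clip(d_mag, 0.0, 1.0).reshape(shape2),
        valid=valid.reshape(shape2),
    )


def depolarization_map(decomp: PolarDecomposition,
                       mask: np.ndarray | None = None) -> DepolarizationMap:
    """Package Delta_T under a tissue mask; background gets the NaN sentinel.

    The mask is intersected with the decomposition's own validity flags, so
    pixels where the factorization failed never enter statistics.
    """
    delta = decomp.delta_total
    if mask is None:
        mask = np.ones(delta.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != delta.shape:
        raise ValueError(
            f"mask shape {mask.shape} != delta shape {delta.shape}")
    mask = mask & decomp.valid
    out = np.where(mask, np.clip(delta, 0.0, 1.0), BACKGROUND_SENTINEL)
    return DepolarizationMap(delta=out, mask=mask)
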
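"""Stain separation and reference-based color normalization for H&E patches.

The color model is the Beer-Lambert law in base-10 optical density (OD):
a pixel with incident white point ``I0`` and stain concentrations ``c``
(a 2-vector, hematoxylin and eosin) is rendered as

    I_ch = I0_ch * 10 ** ( -(S @ c)_ch )

where ``S`` is the 3x2 stain matrix whose unit-norm columns are the
per-channel absorption coefficients of the two stains.  Stain-matrix
estimation inverts this model from pixels alone, either geometrically
(Macenko: principal plane of the OD cloud plus percentile-extreme angles)
or by sparse nonnegative factorization (SPCN).  Normalizing a patch to a
reference re-expresses its concentrations in the reference's stain basis
after matching robust concentration scales, which removes inter-laboratory
staining variation before a source-domain classifier is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateStainError, InsufficientTissueError

DEFAULT_I0 = 255.0

# Minimum pixels above the OD threshold for stain estimation.
MIN_TISSUE_PIXELS = 100
# Ratio of second to first eigenvalue below which the OD cloud is rank-1.
_RANK_TOL = 1e-4


@dataclass(frozen=True)
class ODImage:
    """Per-pixel base-10 optical densities with the white point that made them."""

    values: np.ndarray  # (H, W, 3), float64, >= 0
    source_I0: np.ndarray  # (3,)

    def pixels(self):
        return self.values.reshape(-1, 3)


@dataclass(frozen=True)
class StainMatrix:
    """3x2 matrix of unit-norm absorption columns, hematoxylin first.

    Canonical ordering puts the column with the larger blue-channel
    coefficient first (hematoxylin absorbs red/green, transmitting blue
    weakly relative to eosin... operationally: H is the bluer absorber).
    """

    columns: np.ndarray  # (3, 2)

    def __post_init__(self):
        m = np.asarray(self.columns, dtype=np.float64)
        if m.shape != (3, 2):
            raise ValueError(f"stain matrix must be 3x2, got {m.shape}")
        if not np.all(np.isfinite(m)) or np.any(m < -1e-12):
            raise ValueError("stain matrix entries must be finite and nonnegative")
        norms = np.linalg.norm(m, axis=0)
        if np.any(norms <= 0):
            raise ValueError("stain columns must be nonzero")
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("stain columns must have unit norm")
        if self.angle_between() < 1.0:
            raise DegenerateStainError("stain columns are (near-)collinear")
        object.__setattr__(self, "columns", m)

    def angle_between(self):
        m = np.asarray(self.columns, dtype=np.float64)
        cosang = np.clip(m[:, 0] @ m[:, 1], -1.0, 1.0)
        return float(np.degrees(np.arccos(cosang)))

    @property
    def hematoxylin(self):
        return self.columns[:, 0]

    @property
    def eosin(self):
        return self.columns[:, 1]


def canonical_stain_order(columns):
    """Order columns so the larger blue-channel coefficient comes first."""
    columns = np.asarray(columns, dtype=np.float64)
    if columns[2, 0] < columns[2, 1]:
        columns = columns[:, ::-1]
    return columns


@dataclass
class ReferenceProfile:
    """A reference patch summarized by its stain basis and concentration scale."""

    stain: StainMatrix
    scale: np.ndarray  # (2,) robust (99th percentile) max concentration per stain

    def __post_init__(self):
        self.scale = np.asarray(self.scale, dtype=np.float64)
        if self.scale.shape != (2,) or np.any(self.scale <= 0):
            raise ValueError("reference scale must be two positive values")

    @classmethod
    def from_patch(cls, patch, method="macenko", I0=DEFAULT_I0, seed=0, **kwargs):
        stain, conc = estimate_stains(patch, method=method, I0=I0, seed=seed, **kwargs)
        return cls(stain=stain, scale=robust_concentration_scale(conc))


def _as_i0(I0):
    I0 = np.broadcast_to(np.asarray(I0, dtype=np.float64), (3,)).copy()
    if np.any(I0 <= 0) or np.any(I0 > 255):
        raise ValueError("I0 must lie in (0, 255] per channel")
    return I0


def rgb_to_od(patch, I0=DEFAULT_I0):
    """Convert an 8-bit RGB patch to base-10 optical densities.

    Pixel values are floored at 1 before the logarithm so a fully absorbing
    (zero) pixel maps to the finite density log10(I0).
    """
    I0 = _as_i0(I0)
    img = np.asarray(patch, dtype=np.float64)
    od = np.log10(I0 / np.maximum(img, 1.0))
    return ODImage(values=np.maximum(od, 0.0), source_I0=I0)


def od_to_rgb(od):
    """Invert :func:`rgb_to_od`: clip to [0, 255] and round to 8 bits."""
    img = od.source_I0 * np.power(10.0, -np.asarray(od.values, dtype=np.float64))
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def estimate_stain_matrix_macenko(patch, od_threshold=0.15, angle_percentile=1.0,
                                  I0=DEFAULT_I0):
    """Estimate the stain matrix geometrically from the OD point cloud.

    High-density pixels are projected onto the two leading principal
    directions of their covariance; the extreme polar angles (at
    ``angle_percentile`` and its complement) are mapped back to 3-space,
    rectified and normalized.
    """
    od = rgb_to_od(patch, I0=I0).pixels()
    mask = np.linalg.norm(od, axis=1) > od_threshold
    tissue = od[mask]
    if tissue.shape[0] < MIN_TISSUE_PIXELS:
        raise InsufficientTissueError(
            f"only {tissue.shape[0]} pixels above OD threshold {od_threshold}"
        )
    cov = np.cov(tissue, rowvar=False)
    evals, evecs = np.linalg.eigh(cov)
    # ascending order: take the two largest.
    lead = evecs[:, [2, 1]]
    if evals[1] <= _RANK_TOL * max(evals[2], 1e-12):
        raise DegenerateStainError("OD cloud is effectively one-dimensional")
    # orient each basis vector toward the data.
    for j in range(2):
        if (tissue @ lead[:, j]).sum() < 0:
            lead[:, j] = -lead[:, j]
    proj = tissue @ lead  # (n, 2)
    phi = np.arctan2(proj[:, 1], proj[:, 0])
    lo = np.percentile(phi, angle_percentile)
    hi = np.percentile(phi, 100.0 - angle_percentile)
    v1 = lead @ np.array([np.cos(lo), np.sin(lo)])
    v2 = lead @ np.array([np.cos(hi), np.sin(hi)])
    cols = np.stack([v1, v2], axis=1)
    cols = np.maximum(cols, 0.0)
    norms = np.linalg.norm(cols, axis=0)
    if np.any(norms <= 0):
        raise DegenerateStainError("a rectified stain direction vanished")
    cols = cols / norms
    return StainMatrix(canonical_stain_order(cols))


def concentrations_from_od(od, stain, nonneg=False):
    """Per-pixel least-squares concentrations ``argmin_c ||od - S c||``.

    With ``nonneg`` the exact two-variable nonnegative solution is found by
    enumerating active sets (free, one coordinate clamped, both clamped) and
    keeping the feasible candidate with the smallest residual.
    """
    values = od.values if isinstance(od, ODImage) else np.asarray(od, dtype=np.float64)
    shape = values.shape[:-1]
    v = values.reshape(-1, 3)
    s = stain.columns
    c_free = v @ np.linalg.pinv(s).T  # (n, 2) unconstrained solution
    if not nonneg:
        return c_free.reshape(*shape, 2)
    # candidate with only stain j active: c_j = <s_j, od> / <s_j, s_j>
    c1 = np.maximum(v @ s[:, 0] / (s[:, 0] @ s[:, 0]), 0.0)
    c2 = np.maximum(v @ s[:, 1] / (s[:, 1] @ s[:, 1]), 0.0)

    def residual(c):
        return np.einsum("ij,ij->i", v - c @ s.T, v - c @ s.T)

    cands = [
        np.maximum(c_free, 0.0) * (c_free >= 0).all(axis=1, keepdims=True),
        np.stack([c1, np.zeros_like(c1)], axis=1),
        np.stack([np.zeros_like(c2), c2], axis=1),
    ]
    feasible = (c_free >= 0).all(axis=1)
    res = np.stack([np.where(feasible, residual(cands[0]), np.inf),
                    residual(cands[1]), residual(cands[2])], axis=1)
    pick = np.argmin(res, axis=1)
    out = np.choose(pick[:, None], cands)
    return out.reshape(*shape, 2)


def robust_concentration_scale(conc, percentile=99.0):
    """Per-stain robust maximum concentration, floored away from zero."""
    c = np.asarray(conc, dtype=np.float64).reshape(-1, 2)
    scale = np.percentile(np.maximum(c, 0.0), percentile, axis=0)
    return np.maximum(scale, 1e-6)


@dataclass
class SPCNFit:
    """Result of the sparse nonnegative stain factorization."""

    stain: StainMatrix
    concentrations: np.ndarray  # (H, W, 2)
    converged: bool = True
    objective: float = field(default=np.nan)

    def __iter__(self):
        return iter((self.stain, self.concentrations))


def fit_spcn(patch, sparsity=0.1, n_iter=200, seed=0, I0=DEFAULT_I0,
             od_threshold=0.15):
    """Sparse nonnegative stain factorization of the OD image.

    Minimizes ``||OD - S C||_F^2 + sparsity * ||C||_1`` subject to
    ``S, C >= 0`` by alternating multiplicative updates, re-imposing unit
    column norms on ``S`` each outer iteration.  Deterministic given
    ``seed``.  Non-convergence (relative objective decrease still above
    1e-3 at the last iteration) sets ``converged=False`` on the result
    rather than raising.
    """
    odimg = rgb_to_od(patch, I0=I0)
    h, w = odimg.values.shape[:2]
    od = odimg.pixels()
    mask = np.linalg.norm(od, axis=1) > od_threshold
    if int(mask.sum()) < MIN_TISSUE_PIXELS:
        raise InsufficientTissueError(
            f"only {int(mask.sum())} pixels above OD threshold {od_threshold}"
        )
    v = od[mask].T  # (3, n) tissue pixels drive the dictionary
    rng = np.random.default_rng(seed)
    s = rng.uniform(0.1, 1.0, size=(3, 2))
    s /= np.linalg.norm(s, axis=0)
    c = np.maximum(np.linalg.pinv(s) @ v, 1e-6)
    eps = 1e-10
    prev_obj = np.inf
    rel = np.inf
    for _ in range(n_iter):
        # multiplicative update for C with L1 penalty
        c *= (s.T @ v) / (s.T @ s @ c + 0.5 * sparsity + eps)
        # multiplicative update for S
        s *= (v @ c.T) / (s @ c @ c.T + eps)
        norms = np.maximum(np.linalg.norm(s, axis=0), eps)
        s /= norms
        c *= norms[:, None]
        obj = float(np.sum((v - s @ c) ** 2) + sparsity * np.sum(np.abs(c)))
        rel = abs(prev_obj - obj) / max(obj, eps)
        prev_obj = obj
        if rel <= 1e-6:
            break
    cols = canonical_stain_order(np.maximum(s, 0.0))
    cols /= np.linalg.norm(cols, axis=0)
    stain = StainMatrix(cols)
    conc = concentrations_from_od(odimg, stain, nonneg=True)
    return SPCNFit(stain=stain, concentrations=conc, converged=bool(rel <= 1e-3),
                   objective=prev_obj)


def estimate_stains(patch, method="macenko", I0=DEFAULT_I0, seed=0, **kwargs):
    """Estimate (StainMatrix, nonnegative ConcentrationMap) with either method."""
    if method == "macenko":
        stain = estimate_stain_matrix_macenko(patch, I0=I0, **kwargs)
        conc = concentrations_from_od(rgb_to_od(patch, I0=I0), stain, nonneg=True)
        return stain, conc
    if method == "spcn":
        fit = fit_spcn(patch, seed=seed, I0=I0, **kwargs)
        return fit.stain, fit.concentrations
    raise ValueError(f"unknown stain method {method!r}")


def normalize_to_reference(patch, ref, method="macenko", I0=DEFAULT_I0, seed=0,
                           **kwargs):
    """Re-render ``patch`` in the reference's stain basis and scale.

    The patch's own stain matrix and concentrations are estimated with
    ``method``; each stain's concentrations are rescaled by the ratio of the
    reference scale to the patch's own 99th-percentile concentration, then
    re-rendered through the reference stain matrix.  Estimation failures
    (insufficient tissue, degenerate stains) propagate to the caller.
    """
    _, conc = estimate_stains(patch, method=method, I0=I0, seed=seed, **kwargs)
    own_scale = robust_concentration_scale(conc)
    scaled = conc * (ref.scale / own_scale)
    od_new = scaled @ ref.stain.columns.T
    return od_to_rgb(ODImage(values=od_new, source_I0=_as_i0(I0)))
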
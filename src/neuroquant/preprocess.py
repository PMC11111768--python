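"""Preprocessing chain: bias-field correction, affine registration to a
template grid, percentile clipping, and robust z-scoring.

The intensity normalisation is a robust variant of z-scoring: the location is
the median of voxels strictly above the 10th percentile and the scale is the
standard deviation inside the (p10, p90] band, making the map invariant to
positive affine intensity transforms and insensitive to background and tail
outliers.  Registration estimates a 12-parameter affine by maximising
normalised cross-correlation with a deterministic moments-based
initialisation and multi-resolution Powell refinement; its determinant is
retained downstream as the head-size scaling factor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy import ndimage, optimize

from .core import LabelMap, Volume, resample_to_grid

logger = logging.getLogger("neuroquant")


@dataclass(frozen=True)
class NormalizationParams:
    """Percentile parameters for clipping and robust z-scoring."""

    clip_low: float = 1.0
    clip_high: float = 99.0
    location_floor: float = 10.0   # median taken over voxels above this pct
    scale_ceiling: float = 90.0    # sd taken within (floor, ceiling] band
    scale_band: Literal["floor_to_ceiling", "zero_to_ceiling"] = "floor_to_ceiling"
    strict_floor: bool = True      # exclude exact-percentile ties from the band

    def __post_init__(self) -> None:
        if not (0 <= self.clip_low < self.clip_high <= 100):
            raise ValueError("clip percentiles must satisfy 0 <= low < high <= 100")
        if not (0 <= self.location_floor < self.scale_ceiling <= 100):
            raise ValueError("normalization percentiles out of order")


@dataclass(frozen=True)
class AffineTransform:
    """World-to-world affine (moving mm -> template mm)."""

    matrix: np.ndarray
    provenance: Literal["estimated", "given"] = "given"

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (4, 4):
            raise ValueError("matrix must be 4x4")
        if abs(np.linalg.det(m[:3, :3])) < 1e-12:
            raise ValueError("transform determinant is zero")
        object.__setattr__(self, "matrix", m)

    @property
    def determinant(self) -> float:
        return float(np.linalg.det(self.matrix[:3, :3]))


def clip_percentiles(vol: Volume, params: NormalizationParams | None = None) -> Volume:
    """Clamp intensities to the in-volume [p_low, p_high] percentile range.

    Percentiles are computed over all voxels (no brain mask); for a constant
    volume this is the identity.
    """
    params = params or NormalizationParams()
    data = vol.data
    if np.isnan(data).all():
        raise ValueError("all-NaN volume")
    lo, hi = np.nanpercentile(data, [params.clip_low, params.clip_high])
    return Volume(data=np.clip(data, lo, hi), affine=vol.affine.copy())


def robust_zscore(vol: Volume, params: NormalizationParams | None = None) -> Volume:
    """Normalise to (x - m)/s with a median location and banded scale.

    m is the median of voxels strictly above the ``location_floor``
    percentile; s is the standard deviation of voxels in the
    (floor, ceiling] percentile band (or [0, ceiling] when configured).
    """
    params = params or NormalizationParams()
    data = vol.data.astype(np.float64)
    p_lo = np.percentile(data, params.location_floor)
    p_hi = np.percentile(data, params.scale_ceiling)
    above = data > p_lo if params.strict_floor else data >= p_lo
    if not above.any():
        raise ValueError("empty location set above floor percentile")
    m = np.median(data[above])
    if params.scale_band == "floor_to_ceiling":
        band = above & (data <= p_hi)
    else:
        band = data <= p_hi
    s = float(np.std(data[band]))
    if s <= 0:
        raise ValueError("zero intensity scale in normalization band")
    return Volume(data=((data - m) / s).astype(np.float32), affine=vol.affine.copy())


def _poly_design(shape: tuple[int, int, int], order: int) -> np.ndarray:
    axes = [np.linspace(-1.0, 1.0, n, dtype=np.float64) for n in shape]
    X, Y, Z = np.meshgrid(*axes, indexing="ij")
    cols = [np.ones(shape)]
    if order >= 1:
        cols += [X, Y, Z]
    if order >= 2:
        cols += [X * X, Y * Y, Z * Z, X * Y, X * Z, Y * Z]
    return np.stack([c.ravel() for c in cols], axis=1)


def correct_bias(
    vol: Volume,
    mask: LabelMap | np.ndarray | None = None,
    order: int = 2,
    reference_band: tuple[float, float] = (60.0, 95.0),
    external: "callable | None" = None,
) -> Volume:
    """Remove a smooth multiplicative bias field.

    Built-in fallback: a low-order polynomial is least-squares fitted to the
    log-intensities of a bright-tissue reference set (voxels inside the mask
    whose intensity lies in the ``reference_band`` percentile range — in a T1
    image predominantly white matter, whose true intensity is nearly uniform,
    so smooth variation over it is attributable to bias rather than anatomy),
    then divided out of the whole volume with the mean intensity inside the
    mask preserved.  An external corrector (e.g. an N4 wrapper) can be
    slotted in via ``external`` and takes precedence.

    Non-positive intensities inside the mask are handled by a shift-and-warn
    policy: the volume is shifted to be positive for the log fit and the
    shift is removed afterwards.
    """
    if external is not None:
        return external(vol, mask)
    data = vol.data.astype(np.float64)
    if mask is None:
        m = np.ones(vol.shape, dtype=bool)
        logger.info("bias correction without mask: whole-volume fit")
    elif isinstance(mask, LabelMap):
        m = mask.labels > 0
    else:
        m = np.asarray(mask, dtype=bool)

    shift = 0.0
    inside_min = data[m].min()
    if inside_min <= 0:
        shift = -inside_min + 1e-3 * (np.ptp(data[m]) or 1.0)
        logger.warning("non-positive intensities in mask; shifting by %.4g", shift)
    work = data + shift

    lo, hi = np.percentile(work[m], reference_band)
    ref = m & (work >= lo) & (work <= hi)
    if not ref.any():  # pragma: no cover - degenerate but guarded
        ref = m
    design = _poly_design(vol.shape, order)
    coef, *_ = np.linalg.lstsq(design[ref.ravel()], np.log(work[ref]), rcond=None)
    log_field = (design @ coef).reshape(vol.shape)
    log_field -= log_field[m].mean()  # preserve mean intensity inside mask
    corrected = work / np.exp(log_field) - shift
    return Volume(data=corrected.astype(np.float32), affine=vol.affine.copy())


# ---------------------------------------------------------------------------
# Affine registration


def _params_to_matrix(p: np.ndarray) -> np.ndarray:
    tx, ty, tz, rx, ry, rz, lsx, lsy, lsz, kxy, kxz, kyz = p
    cx, sx = np.cos(rx), np.sin(rx)
    cy, sy = np.cos(ry), np.sin(ry)
    cz, sz = np.cos(rz), np.sin(rz)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    K = np.array([[1, kxy, kxz], [0, 1, kyz], [0, 0, 1]])
    S = np.diag(np.exp([lsx, lsy, lsz]))
    T = np.eye(4)
    T[:3, :3] = Rz @ Ry @ Rx @ K @ S
    T[:3, 3] = (tx, ty, tz)
    return T


def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    d = np.sqrt((a * a).sum() * (b * b).sum())
    if d == 0:
        return 0.0
    return float((a * b).sum() / d)


def _moments(vol: Volume) -> tuple[np.ndarray, np.ndarray]:
    w = np.clip(vol.data, 0, None).astype(np.float64)
    w_sum = w.sum()
    idx = np.indices(vol.shape, dtype=np.float64)
    world = np.einsum("ij,j...->i...", vol.affine[:3, :3], idx) + vol.affine[:3, 3][
        :, None, None, None
    ]
    c = np.array([(world[i] * w).sum() / w_sum for i in range(3)])
    var = np.array([((world[i] - c[i]) ** 2 * w).sum() / w_sum for i in range(3)])
    return c, var


def _downsample(vol: Volume, factor: int) -> Volume:
    data = ndimage.gaussian_filter(vol.data.astype(np.float32), sigma=factor / 2.0)
    data = data[::factor, ::factor, ::factor]
    aff = vol.affine.copy()
    aff[:3, :3] *= factor
    return Volume(data=data, affine=aff)


def register_affine(
    moving: Volume,
    template: Volume,
    levels: tuple[int, ...] = (4, 2),
    maxiter: tuple[int, ...] = (6, 2),
    refine_full: bool = False,
) -> AffineTransform:
    """Estimate the 12-parameter moving-to-template world affine.

    Deterministic: translation and per-axis scale are initialised from
    intensity moments, then refined by Powell maximisation of normalised
    cross-correlation at successively finer resolutions.  Raises if the
    objective turns non-finite.
    """
    c_m, v_m = _moments(moving)
    c_t, v_t = _moments(template)
    scale0 = np.sqrt(v_t / v_m)
    p0 = np.zeros(12)
    p0[6:9] = np.log(scale0)
    p0[0:3] = c_t - scale0 * c_m

    pyramids = [
        (_downsample(moving, f) if f > 1 else moving,
         _downsample(template, f) if f > 1 else template)
        for f in levels + ((1,) if refine_full else ())
    ]
    iters = list(maxiter) + [1]

    p = p0
    for (mov_l, tmp_l), it in zip(pyramids, iters):
        def objective(q: np.ndarray) -> float:
            T = _params_to_matrix(q)
            res = resample_to_grid(
                mov_l, tmp_l.shape, tmp_l.affine, transform=T, interpolation="linear"
            )
            val = -_ncc(res.data, tmp_l.data)
            if not np.isfinite(val):
                raise FloatingPointError("non-finite registration objective")
            return val

        result = optimize.minimize(
            objective,
            p,
            method="Powell",
            options={"maxiter": it, "xtol": 1e-3, "ftol": 1e-6},
        )
        p = result.x
    return AffineTransform(matrix=_params_to_matrix(p), provenance="estimated")


def preprocess_pipeline(
    vol: Volume,
    template: Volume,
    norm: NormalizationParams | None = None,
    bias_order: int = 2,
    mask: LabelMap | np.ndarray | None = None,
    register: bool = True,
) -> tuple[Volume, AffineTransform]:
    """Bias correction, registration+resampling, clipping, normalisation.

    Stage order is fixed; the returned transform feeds head-size
    normalisation in the quantification stage.
    """
    norm = norm or NormalizationParams()
    out = correct_bias(vol, mask=mask, order=bias_order)
    if register:
        xfm = register_affine(out, template)
        out = resample_to_grid(
            out, template.shape, template.affine, transform=xfm.matrix,
            interpolation="linear",
        )
    else:
        xfm = AffineTransform(matrix=np.eye(4), provenance="given")
    out = clip_percentiles(out, norm)
    out = robust_zscore(out, norm)
    return out, xfm
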
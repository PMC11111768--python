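"""GMM-based intensity augmentation.

A 1-D Gaussian mixture (default K = 3: the CSF/GM/WM modes of a T1 image) is
fitted to brain-voxel intensities by EM with deterministic percentile-based
initialisation.  An augmentation draw perturbs each component's mean and
standard deviation; applying it remaps every masked voxel by the
posterior-weighted blend of the per-component affine maps
(x - mu_k)/sd_k * sd'_k + mu'_k.  Geometry is untouched: labels, and hence
any label-derived volume, are exactly invariant.

Perturbation scale is a re-parameterisation of the published approach's
defaults: mean shifts are uniform in [-m, +m] times the smallest
inter-component mean gap, sd scales uniform in [1/(1+m), 1+m].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import LabelMap, Volume


@dataclass(frozen=True)
class IntensityGMM:
    """1-D mixture over brain-voxel intensities, components ordered by mean."""

    weights: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    log_likelihoods: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        w, m, s = (np.asarray(a, dtype=float) for a in (self.weights, self.means, self.sds))
        if not (len(w) == len(m) == len(s)):
            raise ValueError("component arrays must have equal length")
        if (w <= 0).any() or abs(w.sum() - 1) > 1e-6:
            raise ValueError("weights must be positive and sum to 1")
        if (s <= 0).any():
            raise ValueError("sds must be positive")
        if not (np.diff(m) >= 0).all():
            raise ValueError("components must be ordered by mean")
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "means", m)
        object.__setattr__(self, "sds", s)

    @property
    def n_components(self) -> int:
        return len(self.means)

    def posteriors(self, x: np.ndarray) -> np.ndarray:
        """(K, n) responsibilities for a flat intensity array."""
        x = np.asarray(x, dtype=np.float64)
        log_p = (
            np.log(self.weights)[:, None]
            - 0.5 * np.log(2 * np.pi * self.sds[:, None] ** 2)
            - 0.5 * ((x[None, :] - self.means[:, None]) / self.sds[:, None]) ** 2
        )
        log_p -= log_p.max(axis=0, keepdims=True)
        p = np.exp(log_p)
        return p / p.sum(axis=0, keepdims=True)


@dataclass(frozen=True)
class AugmentationDraw:
    """Per-component mean shifts and sd scale factors; magnitude 0 = identity."""

    mean_shifts: np.ndarray
    sd_scales: np.ndarray
    magnitude: float
    seed: int

    def __post_init__(self) -> None:
        if (np.asarray(self.sd_scales) <= 0).any():
            raise ValueError("sd scales must be > 0")

    @property
    def is_identity(self) -> bool:
        return bool(
            np.all(np.asarray(self.mean_shifts) == 0)
            and np.all(np.asarray(self.sd_scales) == 1)
        )


def fit_intensity_gmm(
    vol: Volume,
    mask: LabelMap | np.ndarray,
    n_components: int = 3,
    max_iter: int = 100,
    tol: float = 1e-7,
) -> IntensityGMM:
    """EM fit to masked intensities with percentile initialisation.

    Deterministic (no random restarts); the per-iteration log-likelihood
    trace is kept on the result and is non-decreasing.
    """
    if n_components < 1:
        raise ValueError("need K >= 1")
    m = mask.labels > 0 if isinstance(mask, LabelMap) else np.asarray(mask, dtype=bool)
    if not m.any():
        raise ValueError("empty mask")
    x = vol.data[m].astype(np.float64).ravel()
    if np.unique(x).size < n_components:
        raise ValueError("fewer distinct intensities than components")
    if x.std() == 0:
        raise ValueError("constant intensities inside mask")

    K = n_components
    pcts = (2 * np.arange(K) + 1) / (2 * K) * 100
    means = np.percentile(x, pcts)
    sds = np.full(K, max(x.std() / K, 1e-6))
    weights = np.full(K, 1.0 / K)

    lls: list[float] = []
    n = x.size
    for _ in range(max_iter):
        log_pdf = (
            np.log(weights)[:, None]
            - 0.5 * np.log(2 * np.pi * sds[:, None] ** 2)
            - 0.5 * ((x[None, :] - means[:, None]) / sds[:, None]) ** 2
        )
        mx = log_pdf.max(axis=0)
        ll = float((mx + np.log(np.exp(log_pdf - mx).sum(axis=0))).sum())
        lls.append(ll)
        r = np.exp(log_pdf - mx)
        r /= r.sum(axis=0, keepdims=True)
        nk = r.sum(axis=1)
        weights = nk / n
        means = (r * x[None, :]).sum(axis=1) / nk
        var = (r * (x[None, :] - means[:, None]) ** 2).sum(axis=1) / nk
        sds = np.sqrt(np.maximum(var, 1e-12))
        if len(lls) > 1 and abs(lls[-1] - lls[-2]) < tol * (abs(lls[-2]) + 1):
            break
    order = np.argsort(means)
    return IntensityGMM(
        weights=weights[order] / weights.sum(),
        means=means[order],
        sds=sds[order],
        log_likelihoods=tuple(lls),
    )


def sample_augmentation(
    gmm: IntensityGMM, magnitude: float, seed: int = 0
) -> AugmentationDraw:
    """Seeded draw of component perturbations bounded by ``magnitude``."""
    if magnitude < 0:
        raise ValueError("magnitude must be >= 0")
    K = gmm.n_components
    if magnitude == 0:
        return AugmentationDraw(np.zeros(K), np.ones(K), 0.0, seed)
    rng = np.random.default_rng(seed)
    gap = float(np.diff(gmm.means).min()) if K > 1 else float(gmm.sds[0])
    shifts = rng.uniform(-magnitude, magnitude, size=K) * gap
    scales = np.exp(rng.uniform(-np.log1p(magnitude), np.log1p(magnitude), size=K))
    return AugmentationDraw(shifts, scales, magnitude, seed)


def apply_augmentation(
    vol: Volume,
    mask: LabelMap | np.ndarray,
    gmm: IntensityGMM,
    draw: AugmentationDraw,
) -> Volume:
    """Remap masked intensities by the posterior-weighted per-component maps.

    Voxels outside the mask are untouched and labels are never modified, so
    region volumes are exactly preserved.  An identity draw returns the input
    values bit-for-bit.
    """
    m = mask.labels > 0 if isinstance(mask, LabelMap) else np.asarray(mask, dtype=bool)
    if m.shape != vol.shape:
        raise ValueError("mask grid does not match volume")
    out = vol.data.copy()
    if draw.is_identity:
        return Volume(data=out, affine=vol.affine.copy())
    x = vol.data[m].astype(np.float64)
    r = gmm.posteriors(x)
    new_means = gmm.means + np.asarray(draw.mean_shifts)
    new_sds = gmm.sds * np.asarray(draw.sd_scales)
    mapped = (
        r * (((x[None, :] - gmm.means[:, None]) / gmm.sds[:, None]) * new_sds[:, None]
             + new_means[:, None])
    ).sum(axis=0)
    out[m] = mapped.astype(out.dtype)
    return Volume(data=out, affine=vol.affine.copy())
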
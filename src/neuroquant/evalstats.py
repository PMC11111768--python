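"""Evaluation statistics: overlap and surface-distance metrics, test-retest
reproducibility, and ROC/Youden/DeLong diagnostic analysis.

Conventions
-----------
* Dice is reported as a percentage (0-100); two empty masks score 100 and
  one empty mask 0 (continuity).
* HD95 extracts 6-connectivity boundary voxels of each mask, computes both
  directed distance sets between boundary voxel centres in millimetres
  (anisotropy-aware), and returns the larger of the two directed 95th
  percentiles.
* Test-retest relative difference is 100*|V1 - V2| / denominator, with the
  within-pair mean as the default denominator (a cross-method mean can be
  supplied instead).
* The Wilcoxon signed-rank test uses exact enumeration for n <= 25 without
  ties and the tie- and continuity-corrected normal approximation otherwise.
* AUC is the Mann-Whitney concordant-pair fraction with ties counted 1/2;
  the operating point maximises the Youden index J = sens + spec - 1 with
  ties broken toward higher specificity; paired AUCs are compared with the
  DeLong placement-value test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats
from scipy.spatial import cKDTree


@dataclass(frozen=True)
class MetricResult:
    dsc: float        # percentage
    hd95_mm: float


@dataclass(frozen=True)
class RetestRecord:
    subject: str
    region: str
    v_test_ml: float
    v_retest_ml: float
    denominator_ml: float
    relative_difference_pct: float


@dataclass(frozen=True)
class DiagnosticResult:
    auc: float
    threshold: float
    sensitivity: float
    specificity: float
    accuracy: float


# ---------------------------------------------------------------------------
# Overlap / surface metrics


def dice_coefficient(a: np.ndarray, b: np.ndarray) -> float:
    """100 * 2|A∩B| / (|A|+|B|); both-empty -> 100, one-empty -> 0."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("masks must share a grid")
    na, nb = int(a.sum()), int(b.sum())
    if na == 0 and nb == 0:
        return 100.0
    inter = int(np.logical_and(a, b).sum())
    return 100.0 * 2.0 * inter / (na + nb)


def boundary_voxels(mask: np.ndarray) -> np.ndarray:
    """Indices (n, 3) of 6-connectivity surface voxels of a binary mask."""
    mask = np.asarray(mask, dtype=bool)
    core = ndimage.binary_erosion(
        mask, structure=ndimage.generate_binary_structure(3, 1), border_value=0
    )
    return np.argwhere(mask & ~core)


def hd95(a: np.ndarray, b: np.ndarray, spacing=(1.0, 1.0, 1.0)) -> float:
    """Robust Hausdorff distance: max of the two directed 95th percentiles of
    boundary-to-boundary distances (mm, anisotropy-aware)."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("masks must share a grid")
    if not a.any() or not b.any():
        raise ValueError("hd95 undefined for empty masks")
    spacing = np.asarray(spacing, dtype=float)
    pa = boundary_voxels(a) * spacing
    pb = boundary_voxels(b) * spacing
    d_ab = cKDTree(pb).query(pa, k=1)[0]
    d_ba = cKDTree(pa).query(pb, k=1)[0]
    return float(max(np.percentile(d_ab, 95), np.percentile(d_ba, 95)))


# ---------------------------------------------------------------------------
# Test-retest reproducibility


def retest_relative_difference(
    v_test: float, v_retest: float, denominator: float | None = None
) -> float:
    """100 * |V1 - V2| / denominator (default: within-pair mean)."""
    if denominator is None:
        denominator = 0.5 * (v_test + v_retest)
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    return 100.0 * abs(v_test - v_retest) / denominator


def wilcoxon_paired(
    x, y, alternative: str = "two-sided"
) -> tuple[float, dict[str, bool]]:
    """Paired signed-rank p-value plus significance flags at 0.01 and 0.001.

    Exact enumeration for n <= 25 with no ties among the nonzero absolute
    differences; tie/continuity-corrected normal approximation otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    d = x - y
    d = d[d != 0]
    if d.size == 0:
        raise ValueError("no nonzero differences")
    if d.size < 5:
        raise ValueError("need at least 5 nonzero differences")
    has_ties = np.unique(np.abs(d)).size < d.size
    method = "exact" if (d.size <= 25 and not has_ties) else "approx"
    res = stats.wilcoxon(d, alternative=alternative, method=method, correction=True)
    p = float(res.pvalue)
    return p, {"significant_0.01": p < 0.01, "significant_0.001": p < 0.001}


# ---------------------------------------------------------------------------
# ROC / Youden / DeLong


def _check_classes(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(labels).astype(bool)
    if labels.all() or (~labels).all():
        raise ValueError("both classes must be present")
    return labels, ~labels


def roc_auc(scores, labels) -> float:
    """Mann-Whitney AUC: concordant-pair fraction with ties counted 1/2."""
    scores = np.asarray(scores, dtype=float)
    pos, neg = _check_classes(labels)
    ranks = stats.rankdata(scores)
    n_pos, n_neg = int(pos.sum()), int(neg.sum())
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def youden_operating_point(scores, labels) -> DiagnosticResult:
    """Threshold maximising J = sensitivity + specificity - 1.

    Positive prediction is score >= threshold; candidate thresholds are the
    observed scores; ties in J are broken toward higher specificity.
    """
    scores = np.asarray(scores, dtype=float)
    pos, neg = _check_classes(labels)
    n_pos, n_neg = int(pos.sum()), int(neg.sum())
    best = None
    for thr in np.unique(scores):
        pred = scores >= thr
        sens = (pred & pos).sum() / n_pos
        spec = (~pred & neg).sum() / n_neg
        j = sens + spec - 1
        key = (j, spec)
        if best is None or key > best[0]:
            acc = ((pred & pos).sum() + (~pred & neg).sum()) / scores.size
            best = (key, DiagnosticResult(
                auc=roc_auc(scores, labels), threshold=float(thr),
                sensitivity=float(sens), specificity=float(spec),
                accuracy=float(acc),
            ))
    return best[1]


def _placements(scores: np.ndarray, pos: np.ndarray, neg: np.ndarray):
    """DeLong placement values V10 (per positive) and V01 (per negative)."""
    x = scores[pos]
    y = scores[neg]
    # psi(x_i, y_j): 1 if x>y, 0.5 if equal
    cmp = (x[:, None] > y[None, :]).astype(float) + 0.5 * (x[:, None] == y[None, :])
    return cmp.mean(axis=1), cmp.mean(axis=0), cmp.mean()


def delong_compare(scores1, scores2, labels) -> dict:
    """Paired DeLong test for the difference of two correlated AUCs.

    Returns dict with auc1, auc2, delta, variance, z, p (two-sided).
    Degenerate variance (identical placements) yields p = 1 with a flag.
    """
    scores1 = np.asarray(scores1, dtype=float)
    scores2 = np.asarray(scores2, dtype=float)
    if scores1.shape != scores2.shape:
        raise ValueError("paired scores must have equal length")
    pos, neg = _check_classes(labels)
    v10_1, v01_1, auc1 = _placements(scores1, pos, neg)
    v10_2, v01_2, auc2 = _placements(scores2, pos, neg)
    m, n = v10_1.size, v01_1.size
    s10 = np.cov(np.stack([v10_1, v10_2]), ddof=1)
    s01 = np.cov(np.stack([v01_1, v01_2]), ddof=1)
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + (
        s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]
    ) / n
    delta = auc1 - auc2
    if var <= 1e-15:
        return {"auc1": auc1, "auc2": auc2, "delta": delta, "variance": var,
                "z": 0.0, "p": 1.0, "degenerate": True}
    z = delta / np.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(z))
    return {"auc1": auc1, "auc2": auc2, "delta": float(delta),
            "variance": float(var), "z": float(z), "p": float(p),
            "degenerate": False}
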
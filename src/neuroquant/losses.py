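"""Per-task soft Dice + weighted categorical cross-entropy, combined as an
alpha-weighted total: total = a1*(wCE_1 + Dice_1) + a2*(wCE_2 + Dice_2) with
defaults a1 = 1 (tissue) and a2 = 10 (structural).

The Dice term averages over all classes of a task, background included, and
aggregates intersection/size counts summed over the batch (stabler for small
structures than per-sample averaging).  Cross-entropy class weights default
to inverse voxel frequency normalised to mean 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import softmax_channels


@dataclass(frozen=True)
class LossConfig:
    alpha_tissue: float = 1.0
    alpha_structural: float = 10.0
    dice_eps: float = 1e-5
    class_weights: dict[str, np.ndarray] | None = None

    def __post_init__(self) -> None:
        if self.alpha_tissue < 0 or self.alpha_structural < 0:
            raise ValueError("alpha weights must be >= 0")

    def alpha(self, task: str) -> float:
        return self.alpha_tissue if task == "tissue" else self.alpha_structural


@dataclass
class LossBreakdown:
    """Per-task components and the alpha-weighted total."""

    wce: dict[str, float]
    dice: dict[str, float]
    alphas: dict[str, float]

    @property
    def total(self) -> float:
        return float(
            sum(self.alphas[t] * (self.wce[t] + self.dice[t]) for t in self.wce)
        )


def one_hot(labels: np.ndarray, n_classes: int) -> np.ndarray:
    """(d, h, w) integer labels -> (C, d, h, w) one-hot float array."""
    if labels.ndim != 3:
        raise ValueError("expected 3-D label patch")
    return np.eye(n_classes, dtype=np.float32)[labels].transpose(3, 0, 1, 2)


def soft_dice_loss(probs: np.ndarray, target: np.ndarray, eps: float = 1e-5) -> float:
    """1 - mean over classes of (2*sum(p*g)+eps)/(sum(p)+sum(g)+eps).

    ``probs`` must sum to one per voxel over the leading class axis; the mean
    runs over every class of the task, background included.  Result in [0,1].
    """
    if probs.shape != target.shape:
        raise ValueError("probs/target shape mismatch")
    axes = tuple(range(1, probs.ndim))
    inter = (probs * target).sum(axis=axes, dtype=np.float64)
    sizes = probs.sum(axis=axes, dtype=np.float64) + target.sum(axis=axes, dtype=np.float64)
    dice = (2.0 * inter + eps) / (sizes + eps)
    return float(1.0 - dice.mean())


def weighted_cross_entropy(
    probs: np.ndarray, target: np.ndarray, class_weights: np.ndarray | None = None,
    eps: float = 1e-8,
) -> float:
    """Mean over voxels of w_c(v) * (-log p_c(v)(v)); probabilities clipped."""
    if probs.shape != target.shape:
        raise ValueError("probs/target shape mismatch")
    C = probs.shape[0]
    if class_weights is None:
        class_weights = np.ones(C, dtype=np.float32)
    class_weights = np.asarray(class_weights, dtype=np.float64)
    if (class_weights <= 0).any():
        raise ValueError("class weights must be > 0")
    p = np.clip(probs, eps, 1.0)
    w = class_weights[(...,) + (None,) * (probs.ndim - 1)]
    per_vox = -(target * np.log(p) * w).sum(axis=0)
    return float(per_vox.mean())


def total_loss(
    wce: dict[str, float], dice: dict[str, float], config: LossConfig | None = None
) -> LossBreakdown:
    """Combine per-task components with the alpha weights."""
    config = config or LossConfig()
    alphas = {t: config.alpha(t) for t in wce}
    return LossBreakdown(wce=dict(wce), dice=dict(dice), alphas=alphas)


def inverse_frequency_weights(label_maps, n_classes: int, cap: float = 10.0) -> np.ndarray:
    """Inverse voxel-frequency class weights, normalised to mean 1.

    Classes absent from the sample get the largest observed weight.  Weights
    are capped at ``cap`` times the mean before renormalisation, guarding
    against gradient spikes from extremely rare classes (for the default
    schemas the normalised weights stay well below the cap).
    """
    counts = np.zeros(n_classes, dtype=np.float64)
    for lm in label_maps:
        arr = lm.labels if hasattr(lm, "labels") else np.asarray(lm)
        counts += np.bincount(arr.ravel(), minlength=n_classes)[:n_classes]
    present = counts > 0
    inv = np.zeros(n_classes)
    inv[present] = 1.0 / counts[present]
    if (~present).any():
        inv[~present] = inv[present].max() if present.any() else 1.0
    w = inv / inv.mean()
    if cap is not None:
        w = np.minimum(w, cap)
        w = w / w.mean()
    return w.astype(np.float32)


# ---------------------------------------------------------------------------
# Batched loss + gradient for training (gradients w.r.t. head logits)


def batch_loss_and_grads(
    logits_batch: list[dict[str, np.ndarray]],
    targets_batch: list[dict[str, np.ndarray]],
    config: LossConfig | None = None,
) -> tuple[LossBreakdown, list[dict[str, np.ndarray]]]:
    """Loss breakdown and per-sample d(total)/d(logits) for one batch.

    Cross-entropy averages per voxel within each sample and then over the
    batch; Dice counts are summed over the batch before the ratio.
    """
    config = config or LossConfig()
    tasks = list(logits_batch[0].keys())
    B = len(logits_batch)
    probs_batch = [
        {t: softmax_channels(lg[t]) for t in tasks} for lg in logits_batch
    ]
    onehot_batch = [
        {t: one_hot(tg[t], logits_batch[i][t].shape[0]) for t in tasks}
        for i, tg in enumerate(targets_batch)
    ]

    wce: dict[str, float] = {}
    dice: dict[str, float] = {}
    grads: list[dict[str, np.ndarray]] = [dict() for _ in range(B)]
    eps = config.dice_eps
    for t in tasks:
        C = logits_batch[0][t].shape[0]
        cw = None if config.class_weights is None else config.class_weights.get(t)
        if cw is None:
            cw = np.ones(C, dtype=np.float32)
        # --- weighted CE + its logit gradient
        ce_vals = []
        for i in range(B):
            p, g = probs_batch[i][t], onehot_batch[i][t]
            ce_vals.append(weighted_cross_entropy(p, g, cw))
        wce[t] = float(np.mean(ce_vals))
        # --- batch-summed soft Dice
        inter = np.zeros(C)
        psum = np.zeros(C)
        gsum = np.zeros(C)
        axes = (1, 2, 3)
        for i in range(B):
            p, g = probs_batch[i][t], onehot_batch[i][t]
            inter += (p * g).sum(axis=axes)
            psum += p.sum(axis=axes)
            gsum += g.sum(axis=axes)
        denom = psum + gsum + eps
        numer = 2.0 * inter + eps
        dice[t] = float(1.0 - (numer / denom).mean())
        # --- gradients
        alpha = config.alpha(t)
        for i in range(B):
            p, g = probs_batch[i][t], onehot_batch[i][t]
            n_vox = p[0].size
            w_vox = (cw[:, None, None, None] * g).sum(axis=0, keepdims=True)
            dce_dz = w_vox * (p - g) / (n_vox * B)
            # dDice/dp then chain through softmax
            ddice_dp = -(
                2.0 * g / denom[:, None, None, None]
                - (numer / denom**2)[:, None, None, None]
            ) / C
            inner = (p * ddice_dp).sum(axis=0, keepdims=True)
            ddice_dz = p * (ddice_dp - inner)
            grads[i][t] = (alpha * (dce_dz + ddice_dz)).astype(np.float32)
    return total_loss(wce, dice, config), grads
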
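"""Training loop: subject-level splitting, Adam on the multi-task loss,
validation-based early stopping and checkpointing.

The validation set is held out at subject level (no subject contributes
patches to both sides), its loss is evaluated on a fixed per-subject patch
set each epoch and never used for weight updates; training stops when the
best validation loss has not improved by a relative tolerance for a given
number of epochs, and the best-validation parameters are retained.
"""

from __future__ import annotations

import logging
import time
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .augment import apply_augmentation, fit_intensity_gmm, sample_augmentation
from .core import LabelMap, Volume
from .losses import LossConfig, batch_loss_and_grads, inverse_frequency_weights
from .network import DualHeadUNet, ModelConfig, sample_patches
from .nn import Adam

logger = logging.getLogger("neuroquant")


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 1e-3
    val_fraction: float = 0.15
    batch_size: int = 2
    patches_per_volume: int = 2
    max_epochs: int = 100
    patience: int = 10
    tolerance: float = 1e-4          # relative improvement threshold
    val_patches_per_volume: int = 8  # fixed validation patch set size
    augment_magnitude: float = 0.0
    augment_probability: float = 0.5  # per subject-epoch
    balanced_fraction: float = 0.5    # structure-centred patch share
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.val_fraction < 1):
            raise ValueError("validation fraction must be in (0, 1)")
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be > 0")


@dataclass
class SubjectData:
    """One preprocessed scan with its per-task targets."""

    subject_id: str
    image: Volume
    targets: dict[str, LabelMap]


def split_dataset(subjects: list, fraction: float = 0.15, seed: int = 0):
    """Subject-level train/validation split; val size = round(fraction*n) >= 1."""
    if len(subjects) < 2:
        raise ValueError("need at least 2 subjects to split")
    n_val = max(1, round(fraction * len(subjects)))
    if n_val >= len(subjects):
        raise ValueError("validation fraction leaves no training subjects")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(subjects))
    val_idx = set(order[:n_val].tolist())
    train = [s for i, s in enumerate(subjects) if i not in val_idx]
    val = [s for i, s in enumerate(subjects) if i in val_idx]
    return train, val


def _epoch_patches(subject: SubjectData, cfg: TrainConfig, model_cfg: ModelConfig,
                   seed: int, augmented_image: Volume | None = None,
                   n: int | None = None):
    image = augmented_image or subject.image
    vol = Volume(data=image.data, affine=image.affine)
    return sample_patches(
        vol,
        subject.targets,
        n or cfg.patches_per_volume,
        model_cfg,
        seed=seed,
        balanced_task="structural" if "structural" in subject.targets else None,
        balanced_fraction=cfg.balanced_fraction,
    )


def train_model(
    subjects: list[SubjectData],
    model_config: ModelConfig,
    train_config: TrainConfig | None = None,
    loss_config: LossConfig | None = None,
    checkpoint_path=None,
) -> tuple[DualHeadUNet, pd.DataFrame]:
    """Train the dual-head network; returns best-validation model and log.

    The log has one row per epoch with the per-task Dice/CE components of the
    training loss, the total, and the validation total.
    """
    cfg = train_config or TrainConfig()
    train_subj, val_subj = split_dataset(subjects, cfg.val_fraction, cfg.seed)
    logger.info("training on %d subjects, validating on %d", len(train_subj), len(val_subj))

    if loss_config is None:
        weights = {
            task: inverse_frequency_weights(
                [s.targets[task] for s in train_subj], n_classes
            )
            for task, n_classes in model_config.heads
        }
        loss_config = LossConfig(class_weights=weights)

    net = DualHeadUNet(model_config, seed=cfg.seed)
    opt = Adam(lr=cfg.learning_rate)
    rng = np.random.default_rng(cfg.seed + 1)

    gmms = None
    if cfg.augment_magnitude > 0:
        gmms = {}
        for s in train_subj:
            brain = s.targets["tissue"].labels > 0
            gmms[s.subject_id] = fit_intensity_gmm(s.image, brain)

    # fixed validation patches: deterministic across epochs and processes
    val_sets = [
        _epoch_patches(s, cfg, model_config,
                       seed=zlib.crc32(s.subject_id.encode()) % (2**31),
                       n=cfg.val_patches_per_volume)
        for s in val_subj
    ]

    def evaluate_val() -> float:
        totals = []
        for patches in val_sets:
            for p in patches:
                logits = net.forward(p.image)
                bd, _ = batch_loss_and_grads([logits], [p.targets], loss_config)
                totals.append(bd.total)
        return float(np.mean(totals))

    rows = []
    best_val = np.inf
    best_state = None
    best_epoch = -1
    stall = 0
    for epoch in range(cfg.max_epochs):
        t0 = time.time()
        batch_inputs, batch_logits, batch_targets = [], [], []
        comps = {"wce": {}, "dice": {}}
        totals = []
        order = rng.permutation(len(train_subj))
        for si in order:
            s = train_subj[si]
            image = None
            if gmms is not None and rng.random() < cfg.augment_probability:
                draw = sample_augmentation(
                    gmms[s.subject_id], cfg.augment_magnitude,
                    seed=int(rng.integers(2**31)),
                )
                image = apply_augmentation(
                    s.image, s.targets["tissue"].labels > 0, gmms[s.subject_id], draw
                )
            patches = _epoch_patches(
                s, cfg, model_config, seed=int(rng.integers(2**31)),
                augmented_image=image,
            )
            for p in patches:
                batch_inputs.append(p.image)
                batch_logits.append(net.forward(p.image))
                batch_targets.append(p.targets)
                if len(batch_logits) == cfg.batch_size:
                    bd, grads = batch_loss_and_grads(batch_logits, batch_targets, loss_config)
                    net.zero_grad()
                    # layer caches hold only the most recent forward pass:
                    # backprop the last sample first, re-forward the others
                    for i_s in reversed(range(cfg.batch_size)):
                        if i_s != cfg.batch_size - 1:
                            net.forward(batch_inputs[i_s])
                        net.backward(grads[i_s])
                    opt.step(net.layers)
                    totals.append(bd.total)
                    for t in bd.wce:
                        comps["wce"].setdefault(t, []).append(bd.wce[t])
                        comps["dice"].setdefault(t, []).append(bd.dice[t])
                    batch_inputs, batch_logits, batch_targets = [], [], []
        val_total = evaluate_val()
        row = {"epoch": epoch, "train_total": float(np.mean(totals)),
               "val_total": val_total, "seconds": time.time() - t0}
        for t in comps["wce"]:
            row[f"wce_{t}"] = float(np.mean(comps["wce"][t]))
            row[f"dice_{t}"] = float(np.mean(comps["dice"][t]))
        rows.append(row)
        logger.info("epoch %d train %.4f val %.4f", epoch, row["train_total"], val_total)

        if val_total < best_val * (1 - cfg.tolerance):
            best_val = val_total
            best_state = {k: v.copy() for k, v in net.state_dict().items()}
            best_epoch = epoch
            stall = 0
        else:
            stall += 1
            if stall >= cfg.patience:
                logger.info("early stop at epoch %d (best %d)", epoch, best_epoch)
                break

    if best_state is not None:
        net.load_state_dict(best_state)
    log = pd.DataFrame(rows)
    log.attrs["best_epoch"] = best_epoch
    log.attrs["best_val"] = best_val
    if checkpoint_path is not None:
        net.save(checkpoint_path)
    return net, log
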
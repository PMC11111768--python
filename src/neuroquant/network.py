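"""Dual-head valid-convolution 3-D U-Net: geometry, patch sampling, tiling.

The backbone operates on cubic patches with no padding anywhere, so each
output voxel depends only on a fixed receptive field inside the input patch.
That buys two properties the pipeline relies on: no off-patch-center bias,
and exactly seam-free whole-volume inference by tiling with stride equal to
the output side (stitched tiles agree voxel-for-voxel regardless of offsets).

Default geometry follows the printed architecture: 3x3x3 valid convolutions
(two per resolution block), two stride-2 strided-convolution downsamplings,
transposed-convolution upsampling with center-cropped skip connections,
weight normalisation, leaky ReLU slope 0.20, and a 128-voxel input patch
yielding an 88-voxel output patch.  The two heads emit softmax maps over 4
tissue classes and 23 structural classes; the tasks are not mutually
exclusive and are predicted independently.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .core import LabelMap, LabelSchema, Volume
from .nn import (
    Conv1x1,
    ConvValid3,
    Layer,
    LeakyReLU,
    StridedConv2,
    TransposedConv2,
    center_crop,
    softmax_channels,
)

DEFAULT_HEADS = (("tissue", 4), ("structural", 23))


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyper-parameters; defaults give the 128 -> 88 geometry."""

    patch_side: int = 128
    convs_per_block: int = 2
    kernel_size: int = 3
    levels: int = 3              # i.e. two stride-2 downsamplings
    base_filters: int = 8
    leaky_slope: float = 0.2
    weight_norm: bool = True
    heads: tuple[tuple[str, int], ...] = DEFAULT_HEADS

    def __post_init__(self) -> None:
        if self.kernel_size != 3 or self.levels < 2:
            raise ValueError("supported geometry: 3x3x3 kernels, levels >= 2")
        compute_output_size(self.patch_side, self)

    @property
    def output_side(self) -> int:
        return compute_output_size(self.patch_side, self)

    @property
    def margin(self) -> int:
        return (self.patch_side - self.output_side) // 2


def geometry_trace(input_side: int, config: ModelConfig | None = None) -> list[tuple[str, int]]:
    """Spatial side after every stage of the valid-convolution recurrence.

    Each 3x3x3 valid convolution maps s -> s-2, a stride-2 downsampling
    s -> s/2 (s must be even), a transposed-convolution upsampling s -> 2s.
    Raises ValueError naming the first failing stage.
    """
    config = config or ModelConfig.__new__(ModelConfig)  # tolerate partial cfg
    convs = getattr(config, "convs_per_block", 2)
    levels = getattr(config, "levels", 3)
    red = 2 * convs
    trace: list[tuple[str, int]] = [("input", input_side)]
    s = input_side

    def conv_block(stage: str) -> None:
        nonlocal s
        s -= red
        trace.append((stage, s))
        if s < 1:
            raise ValueError(f"size {s} after {stage}: input side too small")

    for lvl in range(levels - 1):
        conv_block(f"encoder block {lvl + 1}")
        if s % 2:
            raise ValueError(
                f"odd size {s} reached at downsampling {lvl + 1}: cannot halve"
            )
        s //= 2
        trace.append((f"downsampling {lvl + 1}", s))
        if s < 1:
            raise ValueError(f"size {s} after downsampling {lvl + 1}")
    conv_block("bottleneck block")
    for lvl in range(levels - 1):
        s *= 2
        trace.append((f"upsampling {lvl + 1}", s))
        conv_block(f"decoder block {lvl + 1}")
    return trace


def compute_output_size(input_side: int, config: ModelConfig | None = None) -> int:
    """Output patch side for a given input side (128 -> 88 by default)."""
    return geometry_trace(input_side, config)[-1][1]


def admissible_sides(lo: int, hi: int, config: ModelConfig | None = None) -> list[int]:
    """Input sides in [lo, hi] that admit a valid forward pass."""
    out = []
    for s in range(lo, hi + 1):
        try:
            compute_output_size(s, config)
            out.append(s)
        except ValueError:
            pass
    return out


class DualHeadUNet:
    """Single-trunk, two-head 3-D U-Net over the numpy engine."""

    def __init__(self, config: ModelConfig, seed: int = 0) -> None:
        self.config = config
        self.seed = seed
        rng = np.random.default_rng(seed)
        f = config.base_filters
        wn = config.weight_norm
        L = config.levels
        act = lambda: LeakyReLU(config.leaky_slope)  # noqa: E731

        def block(cin: int, cout: int) -> list[Layer]:
            seq: list[Layer] = []
            for i in range(config.convs_per_block):
                seq += [ConvValid3(cin if i == 0 else cout, cout, rng, wn), act()]
            return seq

        # encoder level i carries f * 2^i channels
        self.enc_blocks = []
        for i in range(L - 1):
            cin = 1 if i == 0 else f * 2**i
            self.enc_blocks.append(block(cin, f * 2**i))
        self.downs = [
            [StridedConv2(f * 2**i, f * 2 ** (i + 1), rng, wn), act()]
            for i in range(L - 1)
        ]
        self.bottom = block(f * 2 ** (L - 1), f * 2 ** (L - 1))
        self.ups = []
        self.dec_blocks = []
        for i in reversed(range(L - 1)):
            ch = f * 2**i
            self.ups.append([TransposedConv2(ch * 2, ch, rng, wn), act()])
            self.dec_blocks.append(block(ch * 2, ch))
        self.head_layers: dict[str, list[Layer]] = {}
        for name, n_classes in config.heads:
            self.head_layers[name] = [Conv1x1(f, f, rng, wn), act(),
                                      Conv1x1(f, n_classes, rng, wn)]

    # -- plumbing -----------------------------------------------------------
    @property
    def layers(self) -> list[Layer]:
        out: list[Layer] = []
        for blk in self.enc_blocks:
            out += blk
        for d in self.downs:
            out += d
        out += self.bottom
        for u, dec in zip(self.ups, self.dec_blocks):
            out += u + dec
        for name, _ in self.config.heads:
            out += self.head_layers[name]
        return out

    def zero_grad(self) -> None:
        for layer in self.layers:
            layer.zero_grad()

    # -- forward / backward -------------------------------------------------
    @staticmethod
    def _run(seq: list[Layer], x: np.ndarray) -> np.ndarray:
        for layer in seq:
            x = layer.forward(x)
        return x

    @staticmethod
    def _run_back(seq: list[Layer], g: np.ndarray) -> np.ndarray:
        for layer in reversed(seq):
            g = layer.backward(g)
        return g

    def forward(self, x: np.ndarray) -> dict[str, np.ndarray]:
        """x: (s, s, s) or (1, s, s, s) -> per-head logits (N_k, t, t, t)."""
        if x.ndim == 3:
            x = x[None]
        x = x.astype(np.float32, copy=False)
        h = x
        self._skips: list[np.ndarray] = []
        for blk, down in zip(self.enc_blocks, self.downs):
            h = self._run(blk, h)
            self._skips.append(h)
            h = self._run(down, h)
        h = self._run(self.bottom, h)
        self._crop_pads: list[int] = []
        for u, dec, skip in zip(self.ups, self.dec_blocks, reversed(self._skips)):
            h = self._run(u, h)
            cropped = center_crop(skip, h.shape[1])
            self._crop_pads.append((skip.shape[1] - h.shape[1]) // 2)
            h = np.concatenate([cropped, h], axis=0)
            h = self._run(dec, h)
        self._trunk_out_channels = h.shape[0]
        return {name: self._run(self.head_layers[name], h)
                for name, _ in self.config.heads}

    def predict_probs(self, x: np.ndarray) -> dict[str, np.ndarray]:
        return {k: softmax_channels(v) for k, v in self.forward(x).items()}

    def backward(self, grad_logits: dict[str, np.ndarray]) -> None:
        g = None
        for name, _ in self.config.heads:
            gh = self._run_back(self.head_layers[name], grad_logits[name])
            g = gh if g is None else g + gh
        skip_grads: list[np.ndarray | None] = [None] * len(self._skips)
        for idx in reversed(range(len(self.dec_blocks))):
            dec, up = self.dec_blocks[idx], self.ups[idx]
            g = self._run_back(dec, g)
            skip = self._skips[len(self._skips) - 1 - idx]
            n_skip = skip.shape[0]
            g_skip, g_up = g[:n_skip], g[n_skip:]
            pad = self._crop_pads[idx]
            full = np.zeros_like(skip)
            s = g_skip.shape[1]
            full[:, pad:pad + s, pad:pad + s, pad:pad + s] = g_skip
            skip_grads[len(self._skips) - 1 - idx] = full
            g = self._run_back(up, g_up)
        g = self._run_back(self.bottom, g)
        for i in reversed(range(len(self.enc_blocks))):
            g = self._run_back(self.downs[i], g)
            g = g + skip_grads[i]
            g = self._run_back(self.enc_blocks[i], g)

    def with_patch_side(self, patch_side: int) -> "DualHeadUNet":
        """Same parameters on a different patch geometry.

        The network is fully convolutional, so weights trained at one patch
        side apply unchanged at any admissible side; larger inference patches
        mean fewer tiles for the same stitched (identical) result.
        """
        from dataclasses import replace as _replace

        cfg = _replace(self.config, patch_side=patch_side)
        net = DualHeadUNet(cfg, seed=self.seed)
        net.load_state_dict(self.state_dict())
        return net

    # -- checkpointing ------------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        out = {}
        for i, layer in enumerate(self.layers):
            for k, v in layer.params.items():
                out[f"{i}.{k}"] = v
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i, layer in enumerate(self.layers):
            for k in layer.params:
                layer.params[k] = np.array(state[f"{i}.{k}"], dtype=np.float32)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        meta = {"config": asdict(self.config), "seed": self.seed,
                "format_version": 1}
        np.savez(path, __meta__=json.dumps(meta), **self.state_dict())

    @classmethod
    def load(cls, path: str | Path) -> "DualHeadUNet":
        with np.load(Path(path) if str(path).endswith(".npz") else f"{path}",
                     allow_pickle=False) as data:
            meta = json.loads(str(data["__meta__"]))
            cfg = meta["config"]
            cfg["heads"] = tuple(tuple(h) for h in cfg["heads"])
            net = cls(ModelConfig(**cfg), seed=meta["seed"])
            net.load_state_dict({k: data[k] for k in data.files if k != "__meta__"})
        return net


# ---------------------------------------------------------------------------
# Patch sampling


@dataclass
class PatchPair:
    """One training example: input patch and per-task target label patches
    cropped to the centred output footprint."""

    image: np.ndarray                     # (s, s, s)
    targets: dict[str, np.ndarray]        # task -> (t, t, t) integer labels
    origin: tuple[int, int, int]          # output-footprint origin in volume


def _reflect_pad(data: np.ndarray, margin: int) -> np.ndarray:
    return np.pad(data, margin, mode="reflect")


def sample_patches(
    vol: Volume,
    targets: dict[str, LabelMap],
    n: int,
    config: ModelConfig,
    seed: int = 0,
    balanced_task: str | None = None,
    balanced_fraction: float = 0.5,
) -> list[PatchPair]:
    """Sample patch pairs with output footprints inside the volume.

    The input window extends ``margin`` voxels beyond the footprint on every
    side and is read from a reflect-padded copy of the volume, so footprint
    origins are sampled uniformly over all positions where the *output* tile
    fits.  With ``balanced_task`` set, roughly ``balanced_fraction`` of
    patches are centred on a random foreground voxel of that task instead.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    out_side = config.output_side
    margin = config.margin
    shape = vol.shape
    if any(dim < out_side for dim in shape):
        raise ValueError("volume smaller than one output tile")
    rng = np.random.default_rng(seed)
    padded = _reflect_pad(vol.data.astype(np.float32), margin)
    fg = None
    if balanced_task is not None:
        fg = np.argwhere(targets[balanced_task].labels > 0)
    pairs = []
    for _ in range(n):
        if fg is not None and len(fg) and rng.random() < balanced_fraction:
            c = fg[rng.integers(len(fg))]
            origin = np.clip(c - out_side // 2, 0,
                             np.array(shape) - out_side)
        else:
            origin = np.array([rng.integers(0, dim - out_side + 1) for dim in shape])
        oz, oy, ox = (int(v) for v in origin)
        img = padded[oz:oz + config.patch_side,
                     oy:oy + config.patch_side,
                     ox:ox + config.patch_side]
        tg = {task: lm.labels[oz:oz + out_side, oy:oy + out_side, ox:ox + out_side]
              for task, lm in targets.items()}
        pairs.append(PatchPair(image=img.copy(), targets=tg, origin=(oz, oy, ox)))
    return pairs


# ---------------------------------------------------------------------------
# Whole-volume inference


def predict_full_volume(
    vol: Volume,
    net: DualHeadUNet,
    schemas: dict[str, LabelSchema] | None = None,
    return_probs: bool = False,
    tile_origins: list[tuple[int, int, int]] | None = None,
):
    """Seam-free tiled inference over an arbitrary-size volume.

    The volume is reflect-padded by the valid-convolution margin and tiled
    with stride equal to the output side; edge tiles are shifted inward to
    fit, which is safe because valid convolutions make every output voxel a
    pure function of its receptive field (overlapping tiles agree exactly).

    Returns ``{task: LabelMap}`` (or plain argmax arrays when ``schemas`` is
    None), plus ``{task: (N_k, ...) probability array}`` when requested.
    """
    cfg = net.config
    out_side = cfg.output_side
    stride_align = 2 ** (cfg.levels - 1)  # product of the stride-2 downsamplings
    shape = vol.shape
    if any(dim < out_side for dim in shape):
        raise ValueError("volume smaller than one output tile")
    # strided downsamplings make the network shift-equivariant only for
    # offsets that are multiples of the total stride product; the output side
    # is always such a multiple, so tiling on an out_side-aligned grid (with
    # far-side padding cropped afterwards) keeps stitching exactly seam-free.
    n_tiles = [int(np.ceil(dim / out_side)) for dim in shape]
    canvas = tuple(n * out_side for n in n_tiles)
    extra = [c - dim for c, dim in zip(canvas, shape)]
    padded = np.pad(
        vol.data.astype(np.float32),
        [(cfg.margin, cfg.margin + e) for e in extra],
        mode="reflect",
    )
    if tile_origins is None:
        tile_origins = [
            (z * out_side, y * out_side, x * out_side)
            for z in range(n_tiles[0])
            for y in range(n_tiles[1])
            for x in range(n_tiles[2])
        ]
    else:
        for o in tile_origins:
            if any(v % stride_align for v in o):
                raise ValueError(
                    f"tile origins must be multiples of {stride_align} "
                    "(stride alignment of the downsampling path)"
                )
            if any(v < 0 or v > c - out_side for v, c in zip(o, canvas)):
                raise ValueError(f"tile origin {o} outside the padded canvas")

    probs = {name: np.zeros((k,) + canvas, dtype=np.float32) for name, k in cfg.heads}
    covered = np.zeros(canvas, dtype=bool)
    for oz, oy, ox in tile_origins:
        patch = padded[oz:oz + cfg.patch_side,
                       oy:oy + cfg.patch_side,
                       ox:ox + cfg.patch_side]
        out = net.predict_probs(patch)
        for name, _ in cfg.heads:
            probs[name][:, oz:oz + out_side, oy:oy + out_side, ox:ox + out_side] = out[name]
        covered[oz:oz + out_side, oy:oy + out_side, ox:ox + out_side] = True
    if not covered[: shape[0], : shape[1], : shape[2]].all():
        raise ValueError("tile origins do not cover the volume")
    probs = {name: p[:, : shape[0], : shape[1], : shape[2]] for name, p in probs.items()}
    labels = {name: p.argmax(axis=0).astype(np.int16) for name, p in probs.items()}
    if schemas is not None:
        labels = {
            name: LabelMap(labels=arr, schema=schemas[name], affine=vol.affine.copy())
            for name, arr in labels.items()
        }
    if return_probs:
        return labels, probs
    return labels
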
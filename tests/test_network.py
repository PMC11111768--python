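"""Valid-convolution geometry, dual-head forward pass, sampling, tiling."""

import numpy as np
import pytest

from neuroquant.core import Volume
from neuroquant.network import (
    DualHeadUNet,
    ModelConfig,
    admissible_sides,
    compute_output_size,
    geometry_trace,
    predict_full_volume,
    sample_patches,
)
from neuroquant.phantom import PhantomSpec, make_phantom

TINY = ModelConfig(patch_side=52, base_filters=2, heads=(("tissue", 4), ("structural", 23)))


class TestGeometry:
    def test_printed_default_geometry(self):
        assert compute_output_size(128, ModelConfig()) == 88

    def test_hand_unrolled_recurrence(self):
        trace = [s for _, s in geometry_trace(68, ModelConfig())]
        assert trace == [68, 64, 32, 28, 14, 10, 20, 16, 32, 28]

    def test_odd_halving_error_names_stage(self):
        with pytest.raises(ValueError, match="downsampling 2"):
            compute_output_size(50, ModelConfig())
        with pytest.raises(ValueError, match="downsampling 1"):
            compute_output_size(127, ModelConfig())

    def test_too_small_input_rejected(self):
        with pytest.raises(ValueError):
            compute_output_size(16, ModelConfig())

    def test_margin_is_twenty(self):
        assert ModelConfig().margin == 20

    def test_geometry_matches_forward_shapes_for_admissible_sides(self):
        cfg1 = ModelConfig(patch_side=52, base_filters=1)
        sides = admissible_sides(52, 160, cfg1)
        assert sides == list(range(52, 161, 4))
        # forward-pass confirmation on a spread of sides (shape-only, 1 filter)
        for side in (52, 68, 88, 128, 160):
            net = DualHeadUNet(
                ModelConfig(patch_side=side, base_filters=1,
                            heads=(("tissue", 2),)), seed=0)
            out = net.forward(np.zeros((side,) * 3, np.float32))
            assert out["tissue"].shape[1] == compute_output_size(side, cfg1)


class TestBuild:
    def test_default_head_shapes_and_softmax(self):
        # 128-patch forward: tissue head (4, 88^3), structural head (23, 88^3)
        net = DualHeadUNet(ModelConfig(base_filters=2), seed=0)
        x = np.random.default_rng(0).standard_normal((128,) * 3).astype(np.float32)
        probs = net.predict_probs(x)
        assert probs["tissue"].shape == (4, 88, 88, 88)
        assert probs["structural"].shape == (23, 88, 88, 88)
        for p in probs.values():
            np.testing.assert_allclose(p.sum(axis=0), 1.0, atol=1e-5)

    def test_seeded_init_identical(self):
        a = DualHeadUNet(TINY, seed=3).state_dict()
        b = DualHeadUNet(TINY, seed=3).state_dict()
        for k in a:
            np.testing.assert_array_equal(a[k], b[k])

    def test_checkpoint_round_trip(self, tmp_path):
        net = DualHeadUNet(TINY, seed=1)
        path = tmp_path / "model.npz"
        net.save(path)
        back = DualHeadUNet.load(path)
        x = np.random.default_rng(1).standard_normal((52,) * 3).astype(np.float32)
        np.testing.assert_array_equal(net.forward(x)["tissue"],
                                      back.forward(x)["tissue"])


@pytest.fixture(scope="module")
def phantom64():
    vol, tissue, structural = make_phantom(PhantomSpec.small(64, seed=5))
    return vol, {"tissue": tissue, "structural": structural}


class TestSampling:
    def test_single_center_when_volume_equals_output(self, phantom64):
        vol, targets = phantom64
        cfg = ModelConfig(patch_side=104, base_filters=2)  # output 64
        assert cfg.output_side == 64
        pairs = sample_patches(vol, targets, 5, cfg, seed=0)
        assert all(p.origin == (0, 0, 0) for p in pairs)

    def test_patch_shapes(self, phantom64):
        vol, targets = phantom64
        pairs = sample_patches(vol, targets, 4, TINY, seed=1)
        for p in pairs:
            assert p.image.shape == (52, 52, 52)
            for t in p.targets.values():
                assert t.shape == (12, 12, 12)

    def test_balanced_sampling_hits_structures(self, phantom64):
        vol, targets = phantom64
        pairs = sample_patches(vol, targets, 40, TINY, seed=2,
                               balanced_task="structural")
        frac = np.mean([(p.targets["structural"] > 0).any() for p in pairs])
        assert frac >= 0.30

    def test_nonpositive_n_rejected(self, phantom64):
        vol, targets = phantom64
        with pytest.raises(ValueError):
            sample_patches(vol, targets, 0, TINY)

    def test_seeded_determinism(self, phantom64):
        vol, targets = phantom64
        a = sample_patches(vol, targets, 6, TINY, seed=9)
        b = sample_patches(vol, targets, 6, TINY, seed=9)
        assert [p.origin for p in a] == [p.origin for p in b]


class TestInference:
    def test_single_tile_equals_direct_patch(self):
        vol, _, _ = make_phantom(PhantomSpec.small(64, seed=6))
        cfg = ModelConfig(patch_side=104, base_filters=2)  # one 64-voxel tile
        net = DualHeadUNet(cfg, seed=0)
        labels, probs = predict_full_volume(vol, net, return_probs=True)
        padded = np.pad(vol.data, cfg.margin, mode="reflect")
        direct = net.predict_probs(padded)
        np.testing.assert_array_equal(probs["tissue"], direct["tissue"])

    def test_receptive_field_confined_to_tile_input(self):
        # a tile's stitched output equals the forward pass of its input
        # window alone: no dependence on intensities outside the window
        vol, _, _ = make_phantom(PhantomSpec.small(64, seed=7))
        net = DualHeadUNet(TINY, seed=0)
        cfg = net.config
        _, probs = predict_full_volume(vol, net, return_probs=True)
        padded = np.pad(vol.data.astype(np.float32), cfg.margin, mode="reflect")
        oz, oy, ox = 12, 24, 36  # interior tile origin (output coordinates)
        window = padded[oz:oz + 52, oy:oy + 52, ox:ox + 52]
        direct = net.predict_probs(window)["tissue"]
        out = cfg.output_side
        np.testing.assert_array_equal(
            probs["tissue"][:, oz:oz + out, oy:oy + out, ox:ox + out], direct
        )

    def test_argmax_labels_within_schema(self):
        vol, _, _ = make_phantom(PhantomSpec.small(64, seed=8))
        net = DualHeadUNet(TINY, seed=0)
        labels = predict_full_volume(vol, net)
        assert labels["tissue"].max() <= 3
        assert labels["structural"].max() <= 22

    def test_volume_smaller_than_tile_rejected(self):
        net = DualHeadUNet(TINY, seed=0)
        tiny = Volume(data=np.zeros((8, 8, 8), np.float32), affine=np.eye(4))
        with pytest.raises(ValueError, match="smaller"):
            predict_full_volume(tiny, net)

    def test_tiling_offsets_agree(self):
        # two different tilings of the same volume stitch identically
        vol, _, _ = make_phantom(PhantomSpec.small(64, seed=9))
        net = DualHeadUNet(TINY, seed=0)  # output side 12
        labels_a, probs_a = predict_full_volume(vol, net, return_probs=True)
        # origins must sit on the downsampling stride grid (multiples of 4)
        starts = [0, 4, 16, 28, 40, 52, 60]
        origins = [(z, y, x) for z in starts for y in starts for x in starts]
        labels_b, probs_b = predict_full_volume(
            vol, net, return_probs=True, tile_origins=origins
        )
        np.testing.assert_array_equal(probs_a["tissue"], probs_b["tissue"])
        np.testing.assert_array_equal(labels_a["structural"], labels_b["structural"])
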
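"""Spatial encoder: patch decomposition, tile fusion, video embedding."""

import numpy as np
import pytest

from painfusion.spatial import (SpatialConfig, SpatialEncoder, frame_fuse,
                                patchify, spatial_attention_map,
                                video_forward)
from tests.conftest import TINY_SPATIAL


class TestPatchify:
    def test_counts_196_patches_16_subpatches(self, rng):
        img = rng.integers(0, 255, (224, 224, 3)).astype(np.uint8)
        dec = patchify(img)
        assert dec.patches.shape == (196, 16, 16, 3)
        assert dec.sub_patches.shape == (196, 16, 4, 4, 3)

    def test_patch_row0_col1_is_exact_slice(self, rng):
        img = rng.integers(0, 255, (224, 224, 3)).astype(np.uint8)
        dec = patchify(img)
        assert np.array_equal(dec.patches[1], img[0:16, 16:32])
        # sub-patch (0, 1) of patch 0 is the next 4-pixel column block
        assert np.array_equal(dec.sub_patches[0, 1], img[0:4, 4:8])

    def test_constant_image_gives_identical_patches(self):
        dec = patchify(np.full((224, 224, 3), 9, np.uint8))
        assert np.all(dec.patches == dec.patches[0])

    def test_wrong_size_rejected(self):
        with pytest.raises(ValueError):
            patchify(np.zeros((200, 224, 3), np.uint8))


class TestFrameFuse:
    def test_zero_coefficient_keeps_full_frame_only(self, rng):
        parts = rng.normal(size=(5, 100))
        assert np.allclose(frame_fuse(parts, c=0.0).D, parts[0])

    def test_unit_coefficient_with_equal_parts(self, rng):
        v = rng.normal(size=100)
        fused = frame_fuse(np.tile(v, (5, 1)), c=1.0)
        assert np.allclose(fused.D, 5 * v)

    def test_matches_formula_oracle(self, rng):
        parts = rng.normal(size=(5, 100))
        fused = frame_fuse(parts, c=0.1)
        ref = parts[0] + 0.1 * (parts[1] + parts[2] + parts[3] + parts[4])
        assert np.allclose(fused.D, ref)

    def test_linearity_in_coefficient(self, rng):
        parts = rng.normal(size=(5, 16))
        d0 = frame_fuse(parts, c=0.0).D
        d1 = frame_fuse(parts, c=1.0).D
        dmid = frame_fuse(parts, c=0.3).D
        assert np.allclose(dmid, d0 + 0.3 * (d1 - d0))

    def test_wrong_arity_rejected(self, rng):
        with pytest.raises(ValueError):
            frame_fuse(rng.normal(size=(4, 100)))


class TestEncoder:
    def test_default_config_embeds_to_100(self, rng):
        model = SpatialEncoder(seed=0)
        img = rng.integers(0, 255, (1, 224, 224, 3)).astype(np.uint8)
        emb = model.embed(img)
        assert emb.shape == (1, 100)

    def test_parameter_budget(self):
        assert SpatialEncoder(seed=0).n_parameters() == 2566064

    def test_eval_determinism(self, tiny_spatial, rng):
        img = rng.integers(0, 255, (2, 224, 224, 3)).astype(np.uint8)
        assert np.array_equal(tiny_spatial.embed(img), tiny_spatial.embed(img))

    def test_attention_rows_stochastic_in_both_encoders(self, tiny_spatial, rng):
        img = rng.integers(0, 255, (1, 224, 224, 3)).astype(np.uint8)
        tiny_spatial.embed(img)
        for block in tiny_spatial.blocks:
            for attn in (block.inner.attn, block.outer.attn):
                assert np.allclose(attn.last_weights.sum(axis=-1), 1.0,
                                   atol=1e-5)

    def test_invariants_of_config(self):
        cfg = SpatialConfig()
        assert (224 // cfg.patch_size) ** 2 == 196
        assert (cfg.patch_size // cfg.sub_patch_size) ** 2 == 16
        with pytest.raises(ValueError):
            SpatialConfig(patch_size=15)


class TestVideoForward:
    def test_embedding_length_is_d_times_f(self, tiny_spatial, rng):
        frames = rng.integers(0, 255, (3, 448, 448, 3)).astype(np.uint8)
        emb = video_forward(list(frames), tiny_spatial)
        assert len(emb.VD) == tiny_spatial.cfg.embed_dim * 3

    def test_single_frame_video_equals_frame_embedding(self, tiny_spatial, rng):
        frame = rng.integers(0, 255, (448, 448, 3)).astype(np.uint8)
        emb = video_forward([frame], tiny_spatial)
        from painfusion.video import FaceCrop, make_tileset
        ts = make_tileset(FaceCrop(frame))
        parts = tiny_spatial.embed(np.stack([np.asarray(im, float)
                                             for im in ts.images]))
        ref = frame_fuse(parts, cfg=tiny_spatial.cfg).D
        assert np.allclose(emb.VD, ref)

    def test_frame_permutation_permutes_blocks(self, tiny_spatial, rng):
        frames = [rng.integers(0, 255, (448, 448, 3)).astype(np.uint8)
                  for _ in range(3)]
        d = tiny_spatial.cfg.embed_dim
        vd = video_forward(frames, tiny_spatial).VD
        perm = [2, 0, 1]
        vd_perm = video_forward([frames[i] for i in perm], tiny_spatial).VD
        blocks = vd.reshape(3, d)
        assert np.allclose(vd_perm.reshape(3, d), blocks[perm])

    def test_empty_input_rejected(self, tiny_spatial):
        with pytest.raises(ValueError):
            video_forward([], tiny_spatial)


class TestAttentionMap:
    def test_map_size_and_bounds(self, tiny_spatial, rng):
        img = rng.integers(0, 255, (224, 224, 3)).astype(np.uint8)
        amap = spatial_attention_map(img, tiny_spatial)
        assert amap.shape == (224, 224)
        assert amap.min() >= 0.0 and amap.max() <= 1.0

    def test_constant_readout_weights_give_constant_map(self, rng):
        model = SpatialEncoder(TINY_SPATIAL, seed=1)
        model.readout.weight.data[:] = 0.37
        img = rng.integers(0, 255, (224, 224, 3)).astype(np.uint8)
        amap = spatial_attention_map(img, model)
        assert np.allclose(amap, amap.flat[0])
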
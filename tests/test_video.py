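"""Face cropping (no alignment) and lossless tile decomposition."""

import numpy as np
import pytest

from painfusion.resample import bicubic_resize
from painfusion.video import (FaceCrop, NoFaceError, PassthroughDetector,
                              crop_session, detect_and_crop, make_tileset)


class _FixedBoxDetector:
    def __init__(self, box, conf=0.9):
        self.box, self.conf = box, conf

    def detect(self, frame):
        return [(self.box, self.conf)]


class _FlakyDetector:
    """Fails on even frame indices after the first call."""

    def __init__(self):
        self.calls = 0

    def detect(self, frame):
        self.calls += 1
        if self.calls > 1 and self.calls % 2 == 0:
            return []
        h, w = frame.shape[:2]
        return [((0, 0, w, h), 1.0)]


class TestDetectAndCrop:
    def test_passthrough_on_448_frame_is_identity(self, rng):
        frame = rng.integers(0, 255, (448, 448, 3)).astype(np.uint8)
        crop = detect_and_crop(frame, PassthroughDetector())
        assert np.array_equal(crop.image, frame)

    def test_small_box_is_square_cropped_and_resized(self, rng):
        frame = rng.integers(0, 255, (600, 600, 3)).astype(np.uint8)
        crop = detect_and_crop(frame, _FixedBoxDetector((100, 100, 200, 250)))
        # bounding square of the 100x150 box, side 150, centred on the box
        expected_square = frame[100:250, 75:225]
        expected = np.clip(bicubic_resize(expected_square.astype(float),
                                          448, 448), 0, 255).astype(np.uint8)
        assert np.array_equal(crop.image, expected)

    def test_highest_confidence_box_wins(self, rng):
        frame = rng.integers(0, 255, (448, 448, 3)).astype(np.uint8)

        class TwoBox:
            def detect(self, fr):
                return [((0, 0, 100, 100), 0.4), ((0, 0, 448, 448), 0.95)]

        crop = detect_and_crop(frame, TwoBox())
        assert np.array_equal(crop.image, frame)

    def test_no_alignment_rotation_equivariance(self, rng):
        frame = rng.integers(0, 255, (448, 448, 3)).astype(np.uint8)
        straight = detect_and_crop(frame, PassthroughDetector()).image
        rotated = detect_and_crop(np.rot90(frame).copy(),
                                  PassthroughDetector()).image
        assert np.array_equal(rotated, np.rot90(straight))

    def test_no_face_raises_with_frame_index(self):
        class Nothing:
            def detect(self, fr):
                return []

        with pytest.raises(NoFaceError) as err:
            detect_and_crop(np.zeros((448, 448, 3), np.uint8), Nothing(),
                            frame_index=17)
        assert err.value.frame_index == 17


class TestMakeTileset:
    def test_five_images_of_224(self, rng):
        crop = FaceCrop(rng.integers(0, 255, (448, 448, 3)).astype(np.uint8))
        ts = make_tileset(crop)
        assert len(ts.images) == 5
        for im in ts.images:
            assert im.shape[:2] == (224, 224)

    def test_quadrants_are_exact_slices_and_reassemble(self, rng):
        img = rng.integers(0, 255, (448, 448, 3)).astype(np.uint8)
        ts = make_tileset(FaceCrop(img))
        assert np.array_equal(ts.tiles[0], img[:224, :224])   # TL
        assert np.array_equal(ts.tiles[1], img[:224, 224:])   # TR
        assert np.array_equal(ts.tiles[2], img[224:, :224])   # BL
        assert np.array_equal(ts.tiles[3], img[224:, 224:])   # BR
        top = np.concatenate([ts.tiles[0], ts.tiles[1]], axis=1)
        bottom = np.concatenate([ts.tiles[2], ts.tiles[3]], axis=1)
        assert np.array_equal(np.concatenate([top, bottom], axis=0), img)

    def test_constant_crop_gives_constant_images(self):
        crop = FaceCrop(np.full((448, 448, 3), 77, np.uint8))
        ts = make_tileset(crop)
        for im in ts.images:
            assert np.all(np.asarray(im, dtype=float) == 77)

    def test_wrong_size_rejected(self):
        with pytest.raises(ValueError):
            FaceCrop(np.zeros((224, 224, 3), np.uint8))


class TestCropSession:
    def test_flaky_detector_reuses_last_box(self, rng):
        frames = [rng.integers(0, 255, (448, 448, 3)).astype(np.uint8)
                  for _ in range(4)]
        crops = crop_session(frames, _FlakyDetector())
        assert len(crops) == 4

    def test_all_misses_fail_the_session(self):
        class Nothing:
            def detect(self, fr):
                return []

        with pytest.raises(NoFaceError):
            crop_session([np.zeros((448, 448, 3), np.uint8)] * 3, Nothing())


class TestResampleOracle:
    def test_upscale_matches_pillow_in_the_interior(self, rng):
        from PIL import Image
        a = rng.normal(size=(16, 24))
        mine = bicubic_resize(a, 32, 48)
        ref = np.asarray(Image.fromarray(a.astype(np.float32), mode="F")
                         .resize((48, 32), Image.BICUBIC))
        # edge columns differ: Pillow renormalises boundary taps, this
        # package replicates the edge sample
        assert np.abs(mine - ref)[4:-4, 4:-4].max() < 1e-5

    def test_constant_preservation(self):
        out = bicubic_resize(np.full((8, 8), 2.5), 19, 23)
        assert np.allclose(out, 2.5)
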
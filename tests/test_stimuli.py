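"""Synthetic stimulus generator: shapes, backgrounds, composition."""

import numpy as np
import pytest

from earlyvis import stimuli as st


class TestShapeStats:
    @pytest.mark.parametrize(
        "mask_fn, expected",
        [
            (lambda: np.ones((256, 256)), (1.0, 1.0)),
            (lambda: np.pad(np.ones((128, 256)), ((64, 64), (0, 0))), (0.5, 2.0)),
            (lambda: _single(), (1 / 65536, 1.0)),
        ],
    )
    def test_known_masks(self, mask_fn, expected):
        alpha = mask_fn()
        fg = st.AlphaImage(pixels=np.full((256, 256), 100.0), alpha=alpha)
        frac, elong = st.shape_stats(fg)
        assert frac == pytest.approx(expected[0])
        assert elong == pytest.approx(expected[1])

    def test_empty_mask_rejected(self):
        fg = st.AlphaImage(pixels=np.zeros((256, 256)), alpha=np.zeros((256, 256)))
        with pytest.raises(ValueError):
            st.shape_stats(fg)


def _single():
    a = np.zeros((256, 256))
    a[10, 17] = 1.0
    return a


N_SHAPE_SEEDS = 500


@pytest.fixture(scope="module")
def face_stats():
    return np.array([st.shape_stats(st.gen_foreground("face", i))
                     for i in range(N_SHAPE_SEEDS)])


@pytest.fixture(scope="module")
def nonface_stats():
    return np.array([st.shape_stats(st.gen_foreground("nonface", i))
                     for i in range(N_SHAPE_SEEDS)])


class TestForegrounds:
    def test_face_class_shape_calibration(self, face_stats):
        """Faces: narrow shape distribution, fill ~0.56, elongation ~1.66."""
        assert face_stats[:, 0].mean() == pytest.approx(0.56, abs=0.05)
        assert face_stats[:, 1].mean() == pytest.approx(1.66, abs=0.15)

    def test_nonface_elongation_calibration(self, nonface_stats):
        assert nonface_stats[:, 1].mean() == pytest.approx(2.51, abs=0.3)

    def test_nonface_shape_variance_exceeds_face(self, face_stats, nonface_stats):
        assert nonface_stats[:, 1].var() > face_stats[:, 1].var()

    def test_bounding_box_longest_side(self):
        for cls in ("face", "nonface"):
            fg = st.gen_foreground(cls, 3)
            mask = fg.mask
            rows = np.flatnonzero(mask.any(axis=1))
            cols = np.flatnonzero(mask.any(axis=0))
            longest = max(rows[-1] - rows[0] + 1, cols[-1] - cols[0] + 1)
            assert longest == 246

    def test_deterministic_per_seed(self):
        a = st.gen_foreground("face", 7)
        b = st.gen_foreground("face", 7)
        assert np.array_equal(a.pixels, b.pixels)
        assert np.array_equal(a.alpha, b.alpha)

    def test_unknown_class_rejected(self):
        with pytest.raises(ValueError, match="class"):
            st.gen_foreground("house", 0)


class TestScenes:
    def test_high_contrast_by_construction(self):
        for seed in range(5):
            sc = st.gen_scene(seed)
            assert sc.pixels.min() <= 10
            assert sc.pixels.max() >= 245

    def test_deterministic_and_distinct(self):
        assert np.array_equal(st.gen_scene(4).pixels, st.gen_scene(4).pixels)
        imgs = [st.gen_scene(i).pixels for i in range(100)]
        # pairwise distinct: all per-image checksums differ
        sums = {arr.tobytes() for arr in imgs}
        assert len(sums) == 100

    def test_degrade_halves_rms_then_blurs(self):
        sc = st.gen_scene(0)
        m = sc.pixels.mean()
        half = st.GrayImage(pixels=m + 0.5 * (sc.pixels - m))
        assert st.rms_contrast(half.pixels) == pytest.approx(
            0.5 * st.rms_contrast(sc.pixels))
        out = st.degrade_scene(sc)
        # blur can only further reduce RMS contrast
        assert st.rms_contrast(out.pixels) <= 0.5 * st.rms_contrast(sc.pixels) + 1e-9
        assert abs(out.pixels.mean() - sc.pixels.mean()) < 0.5

    def test_degrade_uniform_is_identity(self):
        u = st.GrayImage(pixels=np.full((340, 340), 77.0))
        out = st.degrade_scene(u)
        assert np.allclose(out.pixels, 77.0)


@pytest.fixture(scope="module")
def fg():
    return st.gen_foreground("face", 0)


@pytest.fixture(scope="module")
def gray_bg():
    return st.gen_background(st.BackgroundKind.MID_GRAY)


class TestBackgrounds:
    def test_mid_gray(self):
        bg = st.gen_background(st.BackgroundKind.MID_GRAY)
        assert np.all(bg.pixels == 128.0)

    def test_matched_gray_equals_opaque_mean(self, fg):
        bg = st.gen_background(st.BackgroundKind.MATCHED_GRAY, fg=fg)
        assert np.allclose(bg.pixels, fg.opaque_values().mean())

    def test_binary_block_noise_structure(self):
        bg = st.gen_background(st.BackgroundKind.BINARY_BLOCK_NOISE, seed=5)
        assert set(np.unique(bg.pixels)) <= {0.0, 255.0}
        blocks = bg.pixels.reshape(85, 4, 85, 4)
        assert np.all(blocks == blocks[:, :1, :, :1])

    def test_white_block_noise_structure(self):
        bg = st.gen_background(st.BackgroundKind.WHITE_BLOCK_NOISE, seed=5)
        blocks = bg.pixels.reshape(85, 4, 85, 4)
        assert np.all(blocks == blocks[:, :1, :, :1])
        assert bg.pixels.min() >= 0 and bg.pixels.max() <= 255

    def test_sampled_block_noise_uses_foreground_histogram(self, fg):
        bg = st.gen_background(st.BackgroundKind.SAMPLED_BLOCK_NOISE, fg=fg, seed=2)
        assert set(np.unique(bg.pixels)) <= set(np.unique(fg.opaque_values()))

    def test_pink_noise_statistics(self):
        bg = st.gen_background(st.BackgroundKind.PINK_NOISE, seed=9)
        assert bg.pixels.mean() == pytest.approx(128.0, abs=2.0)
        assert st.rms_contrast(bg.pixels) == pytest.approx(41.5, abs=1.5)

    def test_missing_requirements_raise(self):
        with pytest.raises(ValueError):
            st.gen_background(st.BackgroundKind.MATCHED_GRAY)
        with pytest.raises(ValueError):
            st.gen_background(st.BackgroundKind.SCENE)


class TestCompose:
    def test_identity_transform_centers_foreground(self, fg, gray_bg):
        draw = st.TransformDraw(scale=1.0, rotation=0.0, jitter=(0, 0))
        img, used = st.transform_and_compose(fg, gray_bg, st.TransformSpec(), draw=draw)
        assert img.pixels.shape == (340, 340)
        for r, c in [(0, 0), (0, 339), (339, 0), (339, 339)]:
            assert img.pixels[r, c] == 128.0
        assert used.jitter == (0, 0)

    def test_background_shows_exactly_outside_alpha(self, fg):
        bg = st.GrayImage(pixels=np.full((340, 340), 200.0))
        draw = st.TransformDraw(scale=0.8, rotation=30.0, jitter=(10, -5))
        img, _ = st.transform_and_compose(fg, bg, st.TransformSpec(), draw=draw)
        _, alpha = st._warp_foreground(fg, draw)
        outside = alpha < 0.5
        assert np.all(img.pixels[outside] == 200.0)

    def test_half_scale_quarters_opaque_area(self, fg, gray_bg):
        full, _ = st.transform_and_compose(
            fg, gray_bg, st.TransformSpec(),
            draw=st.TransformDraw(1.0, 0.0, (0, 0)))
        half, _ = st.transform_and_compose(
            fg, gray_bg, st.TransformSpec(),
            draw=st.TransformDraw(0.5, 0.0, (0, 0)))
        n_full = np.sum(st._warp_foreground(fg, st.TransformDraw(1.0, 0.0, (0, 0)))[1] >= 0.5)
        n_half = np.sum(st._warp_foreground(fg, st.TransformDraw(0.5, 0.0, (0, 0)))[1] >= 0.5)
        assert n_half == pytest.approx(0.25 * n_full, rel=0.03)

    def test_jitter_translates_centroid(self, fg, gray_bg):
        def centroid(draw):
            alpha = st._warp_foreground(fg, draw)[1] >= 0.5
            rr, cc = np.nonzero(alpha)
            return rr.mean(), cc.mean()

        r0, c0 = centroid(st.TransformDraw(1.0, 0.0, (0, 0)))
        r1, c1 = centroid(st.TransformDraw(1.0, 0.0, (42, 0)))
        assert c1 - c0 == pytest.approx(42, abs=0.5)
        assert r1 - r0 == pytest.approx(0, abs=0.5)

    def test_offcanvas_jitter_is_clipped(self, fg, gray_bg):
        draw = st.TransformDraw(scale=1.0, rotation=0.0, jitter=(500, -500))
        img, used = st.transform_and_compose(fg, gray_bg, st.TransformSpec(), draw=draw)
        assert abs(used.jitter[0]) < 500 and abs(used.jitter[1]) < 500
        alpha = st._warp_foreground(fg, used)[1] >= 0.5
        rr, cc = np.nonzero(alpha)
        assert rr.min() >= 0 and rr.max() <= 339
        assert cc.min() >= 0 and cc.max() <= 339

    def test_deterministic_given_rng_seed(self, fg, gray_bg):
        from earlyvis.rng import substream
        spec = st.TransformSpec(scale_min=0.5, rot_max=90.0)
        a, da = st.transform_and_compose(fg, gray_bg, spec, rng=substream(5, "t"))
        b, db = st.transform_and_compose(fg, gray_bg, spec, rng=substream(5, "t"))
        assert da == db
        assert np.array_equal(a.pixels, b.pixels)


class TestMatchLuminance:
    def test_constant_image_scaled_15_percent(self):
        alpha = np.ones((256, 256))
        im = st.AlphaImage(pixels=np.full((256, 256), 100.0), alpha=alpha)
        ref = st.AlphaImage(pixels=np.full((256, 256), 100.0), alpha=alpha)
        adjusted, _ = st.match_luminance([ref], [im])
        assert np.allclose(adjusted[0].pixels, 115.0)

    def test_clipping_at_255(self):
        alpha = np.ones((256, 256))
        px = np.full((256, 256), 250.0)
        im = st.AlphaImage(pixels=px, alpha=alpha)
        adjusted, _ = st.match_luminance([im], [im])
        assert np.all(adjusted[0].pixels == 255.0)

    def test_calibrated_sets_match_within_two_gray_levels(self):
        faces = [st.gen_foreground("face", i) for i in range(150)]
        nonfaces = [st.gen_foreground("nonface", i) for i in range(150)]
        adjusted, summary = st.match_luminance(faces, nonfaces)
        a = summary["after"]
        assert abs(a["set_a"]["mean_luminance"] - a["set_b"]["mean_luminance"]) < 2.0

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            st.match_luminance([], [])


class TestPngRoundtrip:
    def test_foreground_and_stimulus_io(self, tmp_path):
        fg = st.gen_foreground("nonface", 2)
        st.save_png(fg, tmp_path / "fg.png")
        back = st.load_foreground_png(tmp_path / "fg.png")
        assert np.allclose(back.mask, fg.mask)
        assert np.abs(back.pixels[back.mask] - fg.pixels[fg.mask]).max() <= 0.5

        sc = st.gen_scene(1)
        st.save_png(sc, tmp_path / "sc.png")
        back2 = st.load_gray_png(tmp_path / "sc.png")
        assert np.abs(back2.pixels - sc.pixels).max() <= 0.5
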
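import numpy as np
import pytest
import tifffile
from skimage.draw import disk

from contractionmodes import imaging as im
from contractionmodes import synthetic as sy
from contractionmodes.containers import (
    FrameStack,
    IntensityMatrix,
    InputError,
    MorphologyError,
    OrganismMask,
    ParameterError,
    SegmentationError,
)


class TestLoadFrames:
    def test_tiff_round_trip(self, tmp_path):
        data = np.arange(3 * 8 * 9, dtype=np.uint16).reshape(3, 8, 9)
        path = tmp_path / "stack.tif"
        tifffile.imwrite(path, data, photometric="minisblack")
        stack = im.load_frames(path, dt=3.0)
        assert stack.n_frames == 3 and stack.dt == 3.0
        np.testing.assert_array_equal(stack.frames, data.astype(float))

    def test_directory_numeric_ordering(self, tmp_path):
        import imageio.v3 as iio

        for i in range(10):
            img = np.full((5, 5), i, dtype=np.uint8)
            iio.imwrite(tmp_path / f"frame_{i}.png", img)
        stack = im.load_frames(tmp_path, dt=1.0)
        # frame_2 must come before frame_10-like names
        assert [int(f[0, 0]) for f in stack.frames] == list(range(10))

    def test_generator_output_loads_exactly(self, tmp_path):
        coords = np.column_stack([np.full(40, 30), np.arange(20, 60)])
        thick = 1 + 0.1 * np.sin(np.arange(5))[None, :] * np.ones((40, 1))
        path = tmp_path / "synth.tif"
        stack = sy.synth_frames(thick, coords, shape=(60, 90), seed=7, out_path=path)
        loaded = im.load_frames(path, dt=3.0)
        np.testing.assert_array_equal(loaded.frames, stack.frames)

    def test_missing_path_errors(self, tmp_path):
        with pytest.raises(InputError):
            im.load_frames(tmp_path / "nope.tif", dt=3.0)


class TestSegmentation:
    def test_bright_disk_on_dark_background(self):
        frames = np.zeros((2, 64, 64))
        rr, cc = disk((32, 32), 10)
        frames[:, rr, cc] = 100.0
        masks = im.segment_organism(FrameStack(frames=frames, dt=1.0))
        truth = np.zeros((64, 64), bool)
        truth[rr, cc] = True
        inter = (masks.masks[0] & truth).sum()
        union = (masks.masks[0] | truth).sum()
        assert inter / union > 0.95

    def test_flat_frame_errors(self):
        frames = np.zeros((2, 16, 16))
        with pytest.raises(SegmentationError):
            im.segment_organism(FrameStack(frames=frames, dt=1.0))

    def test_scale_invariance_of_mask(self):
        frames = np.zeros((2, 64, 64))
        rr, cc = disk((32, 32), 12)
        frames[:, rr, cc] = 50.0
        m1 = im.segment_organism(FrameStack(frames=frames, dt=1.0))
        m2 = im.segment_organism(FrameStack(frames=3.0 * frames + 17.0, dt=1.0))
        np.testing.assert_array_equal(m1.masks, m2.masks)

    def test_rendered_network_jaccard(self):
        mat, skel, _ = sy.synth_network_dataset(n_frames=3, seed=0)
        shift = skel.pixels + 8  # margin for rendering
        thick = np.ones((len(shift), 3))
        H = shift[:, 0].max() + 9
        W = shift[:, 1].max() + 9
        stack = sy.synth_frames(
            thick, shift, shape=(H, W), tube_width=5.0, noise_sigma=80.0, seed=1
        )
        masks = im.segment_organism(stack)
        truth = np.zeros((H, W), bool)
        from scipy import ndimage

        truth[shift[:, 0], shift[:, 1]] = True
        truth = ndimage.binary_dilation(truth, iterations=2)
        inter = (masks.masks[0] & truth).sum()
        union = (masks.masks[0] | truth).sum()
        assert inter / union > 0.7  # rasterized band vs dilated skeleton


class TestSkeleton:
    def test_bar_skeleton_is_midline(self):
        mask = np.zeros((9, 105), bool)
        mask[2:7, 2:103] = True
        skel = im.extract_skeleton(mask)
        assert 93 <= skel.n_pixels <= 103
        rows = np.unique(skel.pixels[:, 0])
        assert set(rows) <= {3, 4, 5}

    def test_y_network_topology(self):
        mask = np.zeros((80, 80), bool)
        for r0, c0, r1, c1 in [(10, 40, 40, 40), (40, 40, 70, 15), (40, 40, 70, 65)]:
            from skimage.draw import line

            rr, cc = line(r0, c0, r1, c1)
            for dr in (-2, -1, 0, 1, 2):
                for dc in (-2, -1, 0, 1, 2):
                    mask[np.clip(rr + dr, 0, 79), np.clip(cc + dc, 0, 79)] = True
        skel = im.extract_skeleton(mask)
        degrees = np.array([len(a) for a in skel.adjacency])
        assert (degrees == 1).sum() == 3  # three endpoints
        assert (degrees >= 3).sum() >= 1  # at least one junction cluster

    def test_disk_skeleton_is_tiny(self):
        mask = np.zeros((41, 41), bool)
        rr, cc = disk((20, 20), 12)
        mask[rr, cc] = True
        skel = im.extract_skeleton(mask)
        assert skel.n_pixels <= 10

    def test_empty_mask_errors(self):
        with pytest.raises(MorphologyError):
            im.extract_skeleton(np.zeros((10, 10), bool))

    def test_index_bijection(self):
        mask = np.zeros((9, 50), bool)
        mask[3:6, 2:48] = True
        skel = im.extract_skeleton(mask)
        for k, p in enumerate(skel.pixels):
            assert skel.index(tuple(p)) == k


class TestSampling:
    def test_radius_zero_constant_frame(self):
        frames = np.full((2, 10, 10), 7.0)
        frames[:, 0, 0] = 9.0  # make max 9 so polarity flip is defined
        stack = FrameStack(frames=frames, dt=1.0)
        skel = im.extract_skeleton(np.pad(np.ones((1, 5), bool), ((4, 5), (2, 3))))
        mat = im.sample_intensities(stack, skel, radius=0, invert_polarity=False)
        assert np.all(mat.values == 7.0)

    def test_polarity_flip_makes_thick_bright(self):
        frames = np.full((2, 10, 10), 100.0)
        frames[:, 5, 5] = 20.0  # dark = thick tube
        stack = FrameStack(frames=frames, dt=1.0)
        skel = im.extract_skeleton(
            np.eye(10, dtype=bool) * 0 + (np.arange(100).reshape(10, 10) // 10 == 5)
        )
        mat = im.sample_intensities(stack, skel, radius=0)
        k = skel.index((5, 5))
        assert mat.values[k, 0] == mat.values.max()

    def test_mask_restricted_mean(self):
        frames = np.full((2, 10, 10), 1.0)
        frames[:, :, 5:] = 100.0  # out-of-mask region is bright
        stack = FrameStack(frames=frames, dt=1.0)
        masks = np.zeros((2, 10, 10), bool)
        masks[:, :, :5] = True
        skel_mask = np.zeros((10, 10), bool)
        skel_mask[5, 1:5] = True
        skel = im.extract_skeleton(skel_mask)
        mat = im.sample_intensities(
            stack, skel, radius=2, mask=OrganismMask(masks=masks), invert_polarity=False
        )
        assert np.all(mat.values == 1.0)

    def test_negative_radius_errors(self):
        frames = np.ones((2, 10, 10))
        frames[:, 0, 0] = 2
        stack = FrameStack(frames=frames, dt=1.0)
        skel = im.extract_skeleton(np.pad(np.ones((1, 5), bool), ((4, 5), (2, 3))))
        with pytest.raises(ParameterError):
            im.sample_intensities(stack, skel, radius=-1)


class TestDetrend:
    def test_trend_plus_cosine(self):
        dt, T = 3.0, 500
        t = np.arange(T) * dt
        om = 2 * np.pi / 100
        s = 5 + np.cos(om * t)
        mat = IntensityMatrix(values=np.vstack([s, s]), dt=dt, stage="raw")
        d = im.detrend_normalize(mat, trend_window=400.0)
        target = np.cos(om * t) - np.cos(om * t).mean()
        assert np.abs(d.values[0] - target).max() < 0.05
        assert d.stage == "detrended"

    def test_constant_series_goes_to_zero(self):
        mat = IntensityMatrix(values=np.full((3, 50), 4.2), dt=1.0, stage="raw")
        d = im.detrend_normalize(mat, trend_window=10.0)
        np.testing.assert_allclose(d.values, 0.0, atol=1e-12)

    def test_ramp_preserves_interior_oscillation(self):
        dt, T = 3.0, 600
        t = np.arange(T) * dt
        om = 2 * np.pi / 100
        s = 0.01 * t + np.cos(om * t)
        mat = IntensityMatrix(values=np.vstack([s, s]), dt=dt, stage="raw")
        d = im.detrend_normalize(mat, trend_window=400.0)
        w = int(400 / dt)
        amp_ratio = d.values[0][w:-w].std() / np.cos(om * t)[w:-w].std()
        assert abs(amp_ratio - 1.0) < 0.05

    def test_idempotent(self, rng):
        mat = IntensityMatrix(values=rng.normal(size=(4, 300)), dt=1.0, stage="raw")
        d1 = im.detrend_normalize(mat, trend_window=50.0)
        d2 = im.detrend_normalize(d1, trend_window=50.0)
        assert np.abs(d2.values - d1.values).max() < 1e-8 * d1.values.std()

    def test_short_window_errors(self):
        mat = IntensityMatrix(values=np.ones((2, 50)), dt=3.0, stage="raw")
        with pytest.raises(ParameterError):
            im.detrend_normalize(mat, trend_window=3.0)


class TestTubeAxis:
    def test_straight_line_unit_steps(self):
        mask = np.zeros((9, 56), bool)
        mask[4, 2:52] = True  # already one pixel wide
        axis = im.parameterize_tube(mask)
        np.testing.assert_allclose(np.diff(axis.arclength), 1.0)
        assert axis.arclength[-1] == 49.0

    def test_l_shape_total_length(self):
        mask = np.zeros((60, 60), bool)
        mask[5:50, 5:10] = True
        mask[45:50, 5:50] = True
        axis = im.parameterize_tube(mask)
        expected = (50 - 5 - 5) + (50 - 10 - 5)  # two legs, corner shared
        assert abs(axis.arclength[-1] - expected) < 8  # skeleton shortens ends

    def test_y_shape_rejected(self):
        mask = np.zeros((80, 80), bool)
        from skimage.draw import line

        for r0, c0, r1, c1 in [(10, 40, 40, 40), (40, 40, 70, 15), (40, 40, 70, 65)]:
            rr, cc = line(r0, c0, r1, c1)
            for d in (-1, 0, 1):
                mask[np.clip(rr + d, 0, 79), cc] = True
                mask[rr, np.clip(cc + d, 0, 79)] = True
        with pytest.raises(MorphologyError):
            im.parameterize_tube(mask)


def test_full_ingest_round_trip_recovers_axis_dynamics():
    """Render -> load -> segment -> skeletonize -> sample recovers the
    imposed axis thickness dynamics within 5% relative RMS."""
    P, T = 80, 30
    coords = np.column_stack([np.full(P, 40), np.arange(20, 20 + P)])
    t = np.arange(T)
    thick = 1 + 0.1 * np.sin(2 * np.pi * t / 10)[None, :] * np.ones((P, 1))
    # noise at 2% of the rendered oscillation amplitude (contrast * 0.1)
    stack = sy.synth_frames(thick, coords, shape=(80, 120), noise_sigma=16.0, seed=3)
    masks = im.segment_organism(stack)
    skel = im.extract_skeleton(masks.consensus())
    mat = im.sample_intensities(stack, skel, radius=2, mask=masks)
    mid = mat.values[skel.n_pixels // 2]
    rel = (mid - mid.mean()) / mid.mean()
    imp = (thick[0] - thick[0].mean()) / thick[0].mean()
    rms = np.sqrt(np.mean((rel - imp) ** 2)) / np.sqrt(np.mean(imp**2))
    assert rms < 0.05
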
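import numpy as np
import pandas as pd
import pytest
from scipy import ndimage

from xpct.segment import (
    MaskKeyframes,
    compute_features,
    detect_seeds,
    filter_blobs,
    interpolate_mask,
    region_grow,
    watershed_split,
)


def _disk(shape, center, r):
    yy, xx = np.indices(shape)
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= r**2


class TestMaskInterpolation:
    def test_identical_keyframes_constant(self):
        region = _disk((40, 40), (20, 20), 8)
        kf = MaskKeyframes({0: region, 10: region.copy()})
        mask = interpolate_mask(kf, 11)
        assert all(np.array_equal(mask[z], region) for z in range(11))

    def test_concentric_circles_interpolate_radius(self):
        kf = MaskKeyframes({0: _disk((64, 64), (32, 32), 10),
                            10: _disk((64, 64), (32, 32), 20)})
        mask = interpolate_mask(kf, 11)
        area5 = mask[5].sum()
        r5 = np.sqrt(area5 / np.pi)
        assert r5 == pytest.approx(15.0, abs=1.0)

    def test_single_keyframe_extends_everywhere(self):
        region = _disk((32, 32), (16, 16), 6)
        mask = interpolate_mask(MaskKeyframes({4: region}), 9)
        assert all(np.array_equal(mask[z], region) for z in range(9))

    def test_keyframes_reproduced_exactly(self):
        kf = MaskKeyframes({2: _disk((32, 32), (10, 10), 5),
                            8: _disk((32, 32), (20, 20), 7)})
        mask = interpolate_mask(kf, 12)
        assert np.array_equal(mask[2], kf.regions[2])
        assert np.array_equal(mask[8], kf.regions[8])

    def test_empty_keyframe_rejected(self):
        with pytest.raises(ValueError):
            MaskKeyframes({0: np.zeros((8, 8), bool)})


class TestSeedDetection:
    def test_single_gaussian_blob_one_seed(self):
        zz, yy, xx = np.indices((40, 40, 40))
        vol = np.exp(-((zz - 18) ** 2 + (yy - 22) ** 2 + (xx - 20) ** 2)
                     / (2 * 4.0**2))
        seeds = detect_seeds(vol, (3.0, 10.0), threshold=0.05)
        assert len(seeds) == 1
        assert abs(seeds.z[0] - 18) <= 1
        assert abs(seeds.y[0] - 22) <= 1

    def test_constant_volume_no_seeds(self):
        seeds = detect_seeds(np.ones((16, 16, 16)), (2.0, 4.0),
                             threshold=0.01)
        assert len(seeds) == 0

    def test_empty_scale_range_rejected(self):
        with pytest.raises(ValueError):
            detect_seeds(np.ones((8, 8, 8)), (4.0, 2.0), 0.1)

    def test_deterministic_ordering(self, rng):
        vol = ndimage.gaussian_filter(rng.normal(size=(32, 32, 32)), 2)
        a = detect_seeds(vol, (2.0, 5.0), threshold=0.0)
        b = detect_seeds(vol, (2.0, 5.0), threshold=0.0)
        assert a.equals(b)
        assert (a.response.diff().dropna() <= 1e-12).all()


class TestWatershed:
    def test_touching_spheres_split_near_midplane(self):
        zz, yy, xx = np.indices((40, 60, 40))
        s1 = (zz - 20) ** 2 + (yy - 20) ** 2 + (xx - 20) ** 2 <= 100
        s2 = (zz - 20) ** 2 + (yy - 40) ** 2 + (xx - 20) ** 2 <= 100
        fg = s1 | s2
        intensity = (np.exp(-((yy - 20.0) ** 2) / 80)
                     + np.exp(-((yy - 40.0) ** 2) / 80))
        labels = watershed_split(fg, intensity,
                                 np.array([[20, 20, 20], [20, 40, 20]]))
        assert set(np.unique(labels[fg])) == {1, 2}
        interface = np.argwhere(labels[20, :, 20] == 1).max()
        assert abs(interface - 30) <= 2

    def test_single_seed_labels_whole_foreground(self):
        fg = np.zeros((16, 16, 16), bool)
        fg[4:12, 4:12, 4:12] = True
        labels = watershed_split(fg, np.ones(fg.shape),
                                 np.array([[8, 8, 8]]))
        assert np.array_equal(labels > 0, fg)
        assert set(np.unique(labels[fg])) == {1}

    def test_labels_partition_foreground(self, rng):
        fg = ndimage.gaussian_filter(rng.normal(size=(24, 24, 24)), 2) > 0
        pts = np.argwhere(fg)[::200][:4]
        labels = watershed_split(fg, rng.normal(size=fg.shape), pts)
        assert (labels[fg] > 0).all()
        assert (labels[~fg] == 0).all()

    def test_seed_outside_foreground_rejected(self):
        fg = np.zeros((8, 8, 8), bool)
        fg[2:6, 2:6, 2:6] = True
        with pytest.raises(ValueError, match="outside"):
            watershed_split(fg, np.ones(fg.shape), np.array([[0, 0, 0]]))


class TestFeatures:
    def test_digital_ball_sphericity_and_volume(self):
        n = 44
        zz, yy, xx = np.indices((n, n, n))
        ball = (((zz - 22) ** 2 + (yy - 22) ** 2 + (xx - 22) ** 2)
                <= 10**2).astype(np.int32)
        t = compute_features(ball, 1e-6)
        assert t.sphericity[0] == pytest.approx(1.0, abs=0.05)
        assert t.volume_um3[0] == pytest.approx(4 / 3 * np.pi * 1000,
                                                rel=0.02)

    def test_cube_sphericity_analytic(self):
        n = 72
        cube = np.zeros((n, n, n), np.int32)
        cube[4:68, 4:68, 4:68] = 1
        t = compute_features(cube, 1e-6)
        expected = np.pi ** (1 / 3) * 6.0 ** (2 / 3) / 6.0   # 0.8060
        assert t.sphericity[0] == pytest.approx(expected, abs=0.02)

    def test_single_voxel_volume_exact(self):
        vol = np.zeros((5, 5, 5), np.int32)
        vol[2, 2, 2] = 1
        t = compute_features(vol, 2e-6)
        assert t.volume_um3[0] == pytest.approx(8.0, rel=1e-12)


class TestFilter:
    def test_unbounded_ranges_keep_all(self):
        table = pd.DataFrame({"id": [1, 2], "volume_um3": [5.0, 50.0],
                              "sphericity": [0.3, 0.9]})
        out = filter_blobs(table)
        assert (out.blob_class == "SGN").all()

    def test_empty_table(self):
        out = filter_blobs(pd.DataFrame(columns=["id", "volume_um3",
                                                 "sphericity"]))
        assert out.empty

    def test_spheres_kept_distractors_rejected(self):
        # 40 digital balls and 15 elongated rods in one label volume
        n = 160
        labels = np.zeros((60, n, n), np.int32)
        rng = np.random.default_rng(4)
        lab = 0
        truth = {}
        for i in range(40):
            lab += 1
            c = rng.integers(12, [48, n - 12, n - 12])
            zz, yy, xx = np.ogrid[-c[0]:60 - c[0], -c[1]:n - c[1],
                                  -c[2]:n - c[2]]
            m = (zz**2 + yy**2 + xx**2) <= 5**2
            if (labels[m] != 0).any():
                lab -= 1
                continue
            labels[m] = lab
            truth[lab] = "sphere"
        for i in range(15):
            lab += 1
            c = rng.integers(12, [48, n - 12, n - 12])
            zz, yy, xx = np.ogrid[-c[0]:60 - c[0], -c[1]:n - c[1],
                                  -c[2]:n - c[2]]
            m = (zz**2 + (yy / 6.0) ** 2 + xx**2) <= 3**2   # long rod
            if (labels[m] != 0).any():
                lab -= 1
                continue
            labels[m] = lab
            truth[lab] = "rod"
        table = compute_features(labels, 1e-6)
        out = filter_blobs(table, sphericity_range=(0.8, np.inf))
        merged = out.set_index("id").blob_class
        spheres = [k for k, v in truth.items() if v == "sphere"]
        rods = [k for k, v in truth.items() if v == "rod"]
        kept = (merged.loc[spheres] == "SGN").mean()
        rejected = (merged.loc[rods] == "non_SGN").mean()
        assert kept >= 0.95
        assert rejected >= 0.90


class TestRegionGrow:
    def test_two_level_phantom_exact_component(self):
        vol = np.zeros((20, 20, 20))
        vol[5:15, 5:15, 5:15] = 10.0
        vol[0:3, 0:3, 0:3] = 10.0    # disconnected same-value block
        mask = region_grow(vol, [(10, 10, 10)], tolerance=1.0)
        expected = np.zeros_like(vol, dtype=bool)
        expected[5:15, 5:15, 5:15] = True
        assert np.array_equal(mask, expected)

    def test_tolerance_monotonicity(self, rng):
        vol = ndimage.gaussian_filter(rng.normal(size=(24, 24, 24)), 2)
        seed = [(12, 12, 12)]
        prev = None
        for tol in (0.01, 0.05, 0.1, 0.3):
            mask = region_grow(vol, seed, tol)
            if prev is not None:
                assert np.all(prev <= mask)   # inclusion
            prev = mask

    def test_helical_implant_recovered(self):
        # dense helical electrode in a noisy background volume
        n = 64
        rng = np.random.default_rng(6)
        vol = rng.normal(0.0, 0.05, (n, n, n))
        t = np.linspace(0, 4 * np.pi, 400)
        zs = (8 + t / (4 * np.pi) * 48).astype(int)
        ys = (n // 2 + 18 * np.sin(t)).astype(int)
        xs = (n // 2 + 18 * np.cos(t)).astype(int)
        implant = np.zeros((n, n, n), bool)
        for z, y, x in zip(zs, ys, xs):
            implant[max(z - 1, 0):z + 2, max(y - 1, 0):y + 2,
                    max(x - 1, 0):x + 2] = True
        vol[implant] = 5.0 + rng.normal(0, 0.05, implant.sum())
        seed = tuple(np.argwhere(implant)[0])
        mask = region_grow(vol, [seed], tolerance=1.0)
        dice = 2 * (mask & implant).sum() / (mask.sum() + implant.sum())
        assert dice >= 0.95

    def test_seed_out_of_bounds(self):
        with pytest.raises(ValueError):
            region_grow(np.zeros((4, 4, 4)), [(5, 0, 0)], 1.0)
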
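"""Projection, thresholding, skeleton metrics, grid and Sholl analyses."""

import numpy as np
import pytest
from skimage.morphology import skeletonize

from micromorph import spatial as sp
from micromorph import synthetic as syn
from micromorph.errors import GeometryError, ParameterError
from micromorph.spatial import SkeletonMask
from micromorph.tracing import ImageStack


def random_skeleton(rng, shape=(300, 300), pixel_size=0.5) -> SkeletonMask:
    seeds = rng.random(shape) < 0.003
    from scipy.ndimage import binary_dilation

    blob = binary_dilation(seeds, iterations=3)
    return SkeletonMask(skeletonize(blob), pixel_size)


class TestMaxProjection:
    def test_single_plane_identity(self, rng):
        img = rng.random((1, 30, 30))
        s = ImageStack(img, (1.0, 1.0, 1.0))
        np.testing.assert_array_equal(sp.max_projection(s), img[0])

    def test_two_disjoint_planes_union(self):
        img = np.zeros((2, 10, 10))
        img[0, 2, 2] = 5.0
        img[1, 7, 7] = 3.0
        proj = sp.max_projection(ImageStack(img, (1, 1, 1)))
        assert proj[2, 2] == 5.0 and proj[7, 7] == 3.0

    def test_matches_exhaustive_loop(self, rng):
        img = rng.random((4, 12, 11))
        proj = sp.max_projection(ImageStack(img, (1, 1, 1)))
        for y in range(12):
            for x in range(11):
                assert proj[y, x] == max(img[z, y, x] for z in range(4))


class TestThreshold:
    def test_otsu_separates_bimodal(self, rng):
        img = np.where(rng.random((50, 50)) < 0.3, 200.0, 10.0)
        mask, t = sp.threshold_binarize(img, method="otsu")
        np.testing.assert_array_equal(mask, img == 200.0)
        assert 10.0 < t <= 200.0

    def test_fixed_above_max_rejected(self, rng):
        img = rng.random((10, 10))
        with pytest.raises(ParameterError):
            sp.threshold_binarize(img, method=("fixed", 2.0))

    def test_fixed_threshold_applied_and_logged(self, rng):
        img = rng.random((10, 10))
        mask, t = sp.threshold_binarize(img, method="fixed:0.5")
        assert t == 0.5
        np.testing.assert_array_equal(mask, img >= 0.5)


class TestSkeletonize:
    def test_wide_bar_thins_to_line(self):
        mask = np.zeros((30, 60), bool)
        mask[12:17, 5:55] = True
        sk = sp.skeletonize_mask(mask, 1.0)
        rows = np.unique(np.nonzero(sk.pixels)[0])
        assert len(rows) == 1
        n = sk.pixels.sum()
        assert abs(n - 50) <= 2

    def test_empty_mask_gives_empty_skeleton(self):
        sk = sp.skeletonize_mask(np.zeros((10, 10), bool), 1.0)
        assert not sk.pixels.any()

    def test_skeleton_never_larger_than_mask(self, rng):
        for _ in range(100):
            mask = rng.random((40, 40)) < 0.3
            sk = sp.skeletonize_mask(mask, 1.0)
            assert sk.pixels.sum() <= mask.sum()


class TestSkeletonLength:
    def test_horizontal_run(self):
        px = np.zeros((5, 15), bool)
        px[2, 2:13] = True  # 11 pixels, 10 steps
        assert sp.skeleton_length(SkeletonMask(px, 0.5)) == pytest.approx(5.0)

    def test_diagonal_run(self):
        px = np.zeros((15, 15), bool)
        for i in range(11):
            px[i + 1, i + 1] = True
        L = sp.skeleton_length(SkeletonMask(px, 0.5))
        assert L == pytest.approx(10 * np.sqrt(2) * 0.5)

    def test_isolated_pixel_counts_one_pixel_size(self):
        px = np.zeros((5, 5), bool)
        px[2, 2] = True
        assert sp.skeleton_length(SkeletonMask(px, 0.7)) == pytest.approx(0.7)

    def test_partition_additivity(self, rng):
        sk = random_skeleton(rng)
        total = sp.skeleton_length(sk)
        split = rng.random(sk.pixels.shape) < 0.5
        assert sp.skeleton_length(sk, split) + sp.skeleton_length(
            sk, ~split
        ) == pytest.approx(total, rel=1e-12)


class TestGrid:
    def test_spanning_horizontal_line(self):
        px = np.zeros((680, 680), bool)
        px[340, :] = True
        g = sp.grid_analysis(SkeletonMask(px, 0.25))
        row = g.lengths[g.lengths.sum(axis=1) > 0][0]
        np.testing.assert_allclose(row, 5.0)
        assert g.lengths.sum() == pytest.approx(160.0)

    def test_empty_skeleton_fully_vacant(self):
        g = sp.grid_analysis(SkeletonMask(np.zeros((680, 680), bool), 0.25))
        assert g.vacant_percent == 100.0
        assert g.lengths.sum() == 0.0

    def test_conservation_against_window_oracle(self, rng):
        for _ in range(5):
            sk = random_skeleton(rng, shape=(700, 700), pixel_size=0.25)
            g = sp.grid_analysis(sk)
            H, W = sk.pixels.shape
            x0, y0 = g.window_origin
            ys, xs = np.mgrid[0:H, 0:W]
            cx, cy = (xs + 0.5) * 0.25, (ys + 0.5) * 0.25
            region = (cx >= x0) & (cx < x0 + 160) & (cy >= y0) & (cy < y0 + 160)
            assert g.lengths.sum() == pytest.approx(
                sp.skeleton_length(sk, region), rel=1e-6
            )

    def test_histogram_counts_all_squares(self, rng):
        sk = random_skeleton(rng, shape=(700, 700), pixel_size=0.25)
        g = sp.grid_analysis(sk)
        assert g.histogram["count"].sum() == 32 * 32

    def test_small_field_rejected(self):
        with pytest.raises(GeometryError):
            sp.grid_analysis(SkeletonMask(np.zeros((100, 100), bool), 0.25))


def star_skeleton(n_rays=12, pixel_size=0.5, size=640, phase=0.13):
    px = np.zeros((size, size), bool)
    c = size * pixel_size / 2.0
    for k in range(n_rays):
        th = 2 * np.pi * k / n_rays + phase
        for rr in np.arange(0.0, c - 5.0, pixel_size / 5.0):
            x = int((c + rr * np.cos(th)) / pixel_size)
            y = int((c + rr * np.sin(th)) / pixel_size)
            if 0 <= x < size and 0 <= y < size:
                px[y, x] = True
    return SkeletonMask(px, pixel_size), (c, c)


class TestSholl:
    def test_twelve_ray_star_counts_and_normalization(self):
        sk, center = star_skeleton()
        prof = sp.sholl_profile(sk, center)
        assert (prof.raw_counts == 12).all()
        # Î(40 μm) = 12 / (2π·0.040 mm) ≈ 47.7 per mm, decaying as 1/r
        assert prof.normalized[0] == pytest.approx(12 / (2 * np.pi * 0.040), rel=1e-6)
        np.testing.assert_allclose(
            prof.normalized, 12.0 / (2 * np.pi * prof.radii / 1000.0), rtol=1e-6
        )

    def test_empty_skeleton_all_zero(self):
        sk = SkeletonMask(np.zeros((640, 640), bool), 0.5)
        prof = sp.sholl_profile(sk, (160.0, 160.0))
        assert (prof.raw_counts == 0).all()

    def test_bad_radii_rejected(self):
        sk = SkeletonMask(np.zeros((640, 640), bool), 0.5)
        with pytest.raises(ParameterError):
            sp.sholl_profile(sk, (160.0, 160.0), r_min=100, r_max=50)

    def test_parallel_chords_match_analytic_oracle(self, rng):
        # chords at signed perpendicular offsets from the centre cross each
        # circle of radius r exactly twice iff |offset| < r
        size, p = 420, 1.0
        c = size * p / 2.0
        for rep in range(3):
            th = rng.uniform(0, np.pi)
            u = np.array([np.cos(th), np.sin(th)])     # chord direction
            nvec = np.array([-u[1], u[0]])
            # distinct chords crossing every circle transversally: stay
            # ≥ 4 px from tangency and ≥ 4 px from one another
            offsets = []
            while len(offsets) < 8:
                o = rng.uniform(-130, 130)
                if min(abs(abs(o) - r) for r in range(40, 145, 5)) > 4.0 and all(
                    abs(o - q) > 4.0 for q in offsets
                ):
                    offsets.append(o)
            px = np.zeros((size, size), bool)
            for o in offsets:
                base = np.array([c, c]) + o * nvec
                for t in np.arange(-c * 1.5, c * 1.5, p / 4.0):
                    x, y = base + t * u
                    i, j = int(y / p), int(x / p)
                    if 0 <= i < size and 0 <= j < size:
                        px[i, j] = True
            sk = SkeletonMask(px, p)
            prof = sp.sholl_profile(sk, (c, c), clip_to_field=False)
            # each intersection point sits at distance r ≤ 140 < c from the
            # centre, so no crossing is ever clipped by the image border
            for r, count in zip(prof.radii, prof.raw_counts):
                expect = 2 * sum(1 for o in offsets if abs(o) < r)
                assert abs(count - expect) <= 1


class TestHeatmap:
    def test_uniform_mask_is_one(self):
        m = np.ones((60, 60), bool)
        h = sp.density_heatmap(m, kernel_radius_px=5)
        np.testing.assert_allclose(h, 1.0)

    def test_empty_mask_is_zero(self):
        h = sp.density_heatmap(np.zeros((60, 60), bool), kernel_radius_px=5)
        np.testing.assert_allclose(h, 0.0)

    def test_integral_tracks_foreground_count(self, rng):
        m = rng.random((120, 120)) < 0.2
        h = sp.density_heatmap(m, kernel_radius_px=4)
        assert h.sum() == pytest.approx(m.sum(), rel=0.05)


class TestPipelineMonotonicity:
    def test_sparser_processes_never_less_vacant(self):
        # lowering fine_process_rate (young→aged-like) must not reduce the
        # vacant-square fraction, replicate by replicate
        for seed in (0, 1, 2):
            vacants = []
            for rate in (0.6, 0.1):
                scene = syn.generate_field(
                    condition="young", n_cells=10, seed=seed,
                    field_size=(170.0, 170.0, 20.0),
                    params_per_condition={"young": {"fine_process_rate": rate}},
                )
                r = syn.render_stack(scene)
                proj = sp.max_projection(r.channels["ch1"])
                mask, _ = sp.threshold_binarize(proj)
                g = sp.grid_analysis(sp.skeletonize_mask(mask, 0.25))
                vacants.append(g.vacant_percent)
            assert vacants[1] >= vacants[0]
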
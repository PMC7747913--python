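"""Fundus-reference registration: pincushion, pyramid, polynomial fit."""

import warnings

import numpy as np
import pytest
import scipy.ndimage as ndi

import octmosaic as om
from octmosaic import registration as reg


@pytest.fixture(scope="module")
def reference(fundus_phantom):
    return reg.prepare_fundus_reference(fundus_phantom.fundus_map, 8.2,
                                        pad_px=32)


def quadratic_map(coef_x, coef_y):
    def q(pts):
        x, y = pts[..., 0], pts[..., 1]
        a = np.stack([x * x, y * y, x * y, x, y, np.ones_like(x)], axis=-1)
        return np.stack([a @ coef_x, a @ coef_y], axis=-1)
    return q


class TestPrepareFundusReference:
    def test_green_channel_selected(self):
        rgb = np.zeros((40, 40, 3))
        rgb[..., 1] = np.arange(1600).reshape(40, 40)
        ref = reg.prepare_fundus_reference(rgb, 8.2, pad_px=0)
        assert np.allclose(ref.pixels, rgb[..., 1])

    def test_native_pitch_only_pads(self):
        img = np.random.default_rng(0).random((30, 30))
        ref = reg.prepare_fundus_reference(img, 8.2, pad_px=5)
        assert ref.shape == (40, 40)
        assert np.allclose(ref.pixels[5:-5, 5:-5], img)
        assert np.all(ref.pixels[:5] == 0.0)

    def test_45_degree_photo_size_arithmetic(self):
        """45 deg at 300 um/deg and 8.2 um/px -> ~1646 px plus padding."""
        n_in = 200
        pitch_in = 45 * 300.0 / n_in       # um per input pixel
        img = np.ones((n_in, n_in))
        ref = reg.prepare_fundus_reference(img, pitch_in, pad_px=10)
        expected = round(n_in * pitch_in / 8.2) + 20
        assert abs(ref.shape[0] - expected) <= 1

    def test_missing_pitch_rejected(self):
        with pytest.raises(ValueError):
            reg.prepare_fundus_reference(np.ones((8, 8)), None)


class TestPincushion:
    def test_zero_k_is_identity(self):
        model = reg.PincushionModel.for_shape((100, 100), 0.0)
        pts = np.array([[10.0, 20.0], [80.0, 5.0]])
        assert np.allclose(model.correct_points(pts), pts)

    def test_centre_is_fixed_point(self):
        model = reg.PincushionModel.for_shape((101, 101), 0.3)
        centre = np.array([[50.0, 50.0]])
        assert np.allclose(model.correct_points(centre), centre)

    def test_direct_radius_arithmetic(self):
        """r_u=0.5, k=0.2 -> r_c = 0.5*(1+0.2*0.25) = 0.525."""
        model = reg.PincushionModel(k=0.2, center=(0.0, 0.0), scale=1.0)
        out = model.correct_points(np.array([[0.5, 0.0]]))
        assert out[0, 0] == pytest.approx(0.525)

    def test_point_round_trip(self):
        model = reg.PincushionModel.for_shape((200, 200), 0.15)
        rng = np.random.default_rng(1)
        pts = rng.uniform(0, 199, (500, 2))
        back = model.uncorrect_points(model.correct_points(pts))
        assert np.abs(back - pts).max() < 1e-8

    def test_image_warp_round_trip(self, fundus_phantom):
        img = fundus_phantom.fundus_map[:256, :256]
        model = reg.PincushionModel.for_shape(img.shape, 0.1)
        back = reg.undistort_image(reg.distort_image(img, model), model)
        # two bilinear resamples soften vessel edges slightly
        inner = (slice(40, -40), slice(40, -40))
        assert np.abs(back[inner] - img[inner]).max() < 0.05
        assert np.abs(back[inner] - img[inner]).mean() < 0.005


class TestMaskedPhaseCorrelate:
    def test_crop_recovered_within_half_pixel(self, fundus_phantom,
                                              reference):
        part = fundus_phantom.fundus_map[150:150 + 256, 200:200 + 256]
        cx, cy, peak = reg.masked_phase_correlate(reference, part)
        assert cx == pytest.approx(200 + 32 + 128, abs=0.5)
        assert cy == pytest.approx(150 + 32 + 128, abs=0.5)

    def test_neutral_mask_identical_to_unmasked(self, fundus_phantom,
                                                reference):
        part = fundus_phantom.fundus_map[100:228, 100:228]
        unmasked = reg.masked_phase_correlate(reference, part)
        neutral = reg.masked_phase_correlate(reference, part,
                                             np.ones(reference.shape))
        assert unmasked == neutral

    def test_mask_suppresses_decoy_peak(self):
        """Two identical motifs: the Gaussian mask selects the true one."""
        rng = np.random.default_rng(5)
        motif = ndi.gaussian_filter(rng.random((64, 64)), 1.0)
        scene = np.zeros((256, 256))
        scene[40:104, 40:104] = motif      # decoy
        scene[150:214, 160:224] = motif    # true location
        ref = reg.FundusReference(pixels=scene)
        mask = reg.gaussian_mask(scene.shape, (192, 182), (20, 20))
        cx, cy, _ = reg.masked_phase_correlate(ref, motif, mask)
        assert cx == pytest.approx(192, abs=1.0)
        assert cy == pytest.approx(182, abs=1.0)

    def test_oversized_part_rejected(self, reference):
        with pytest.raises(ValueError):
            reg.masked_phase_correlate(
                reference, np.zeros((reference.shape[0] + 1, 8)))


class TestPyramidPointset:
    def test_level_zero_single_pair(self, fundus_phantom, reference):
        part = fundus_phantom.fundus_map[150:150 + 256, 200:200 + 256]
        pairs = reg.pyramid_pointset(reference, part, levels_n=0)
        assert len(pairs) == 1

    def test_two_levels_give_21_accurate_pairs(self, fundus_phantom,
                                               reference):
        """1 + 4 + 16 pairs, all reproducing the known placement."""
        top, left = 150, 200
        part = fundus_phantom.fundus_map[top:top + 256, left:left + 256]
        pairs = reg.pyramid_pointset(reference, part, levels_n=2,
                                     min_part_px=16)
        assert len(pairs) == 21
        for p in pairs:
            assert p.target[0] == pytest.approx(p.source[0] + left + 32,
                                                abs=0.5)
            assert p.target[1] == pytest.approx(p.source[1] + top + 32,
                                                abs=0.5)

    def test_small_parts_stop_branch_early(self, fundus_phantom,
                                           reference):
        part = fundus_phantom.fundus_map[150:150 + 128, 200:200 + 128]
        with pytest.warns(UserWarning, match="stopped early"):
            pairs = reg.pyramid_pointset(reference, part, levels_n=3,
                                         min_part_px=64)
        assert len(pairs) == 5     # level 1 parts are 64 px; level 2 not

    def test_warped_projection_pairs_follow_displacement(self,
                                                         reference):
        """Quadrant offsets vary consistently with a known quadratic
        warp's local displacement."""
        coef_x = np.array([4e-5, -2e-5, 1e-5, 1.01, 0.01, 229.0])
        coef_y = np.array([-2e-5, 3e-5, -1e-5, -0.01, 1.0, 184.0])
        q = quadratic_map(coef_x, coef_y)
        yy, xx = np.mgrid[0:256, 0:256].astype(float)
        m = q(np.stack([xx, yy], axis=-1))
        proj = ndi.map_coordinates(reference.pixels, [m[..., 1], m[..., 0]],
                                   order=1)
        pairs = reg.pyramid_pointset(reference, proj, levels_n=2,
                                     min_part_px=16)
        for p in pairs:
            expected = q(np.array(p.source))
            assert p.target[0] == pytest.approx(expected[0], abs=1.0)
            assert p.target[1] == pytest.approx(expected[1], abs=1.0)


class TestPruneAndFit:
    def _pairs_from_map(self, q, n=16, peaks=None, span=250.0):
        rng = np.random.default_rng(7)
        src = rng.uniform(0, span, (n, 2))
        dst = q(src)
        peaks = peaks if peaks is not None else np.ones(n)
        return [reg.PointPair(source=tuple(s), target=tuple(d),
                              peak_height=float(p), level=0)
                for s, d, p in zip(src, dst, peaks)]

    def test_affine_recovered_exactly(self):
        q = quadratic_map(np.array([0, 0, 0, 1.1, -0.05, 12.0]),
                          np.array([0, 0, 0, 0.04, 0.97, -8.0]))
        tf = reg.prune_and_fit(self._pairs_from_map(q))
        assert np.allclose(tf.poly_x[:3], 0.0, atol=1e-9)
        assert np.allclose(tf.poly_y[:3], 0.0, atol=1e-9)
        assert tf.residual_px < 1e-9

    def test_quadratic_recovered_to_1e6(self):
        coef_x = np.array([3e-5, -2e-5, 1e-5, 1.02, 0.01, 229.0])
        coef_y = np.array([-1e-5, 2.5e-5, -1.5e-5, -0.008, 0.99, 152.0])
        q = quadratic_map(coef_x, coef_y)
        tf = reg.prune_and_fit(self._pairs_from_map(q, n=20))
        assert np.allclose(tf.poly_x, coef_x, atol=1e-6)
        assert np.allclose(tf.poly_y, coef_y, atol=1e-6)

    def test_thirty_percent_pruning_keeps_ceil(self):
        """10 pairs: ceil(0.7*10) = 7 survive."""
        q = quadratic_map(np.array([0, 0, 0, 1, 0, 5.0]),
                          np.array([0, 0, 0, 0, 1, -3.0]))
        peaks = np.array([1.0] * 7 + [0.1, 0.05, 0.01])
        pairs = self._pairs_from_map(q, n=10, peaks=peaks)
        tf = reg.prune_and_fit(pairs)
        assert tf.meta["n_kept"] == 7

    def test_few_pairs_fall_back(self):
        q = quadratic_map(np.array([0, 0, 0, 1, 0, 5.0]),
                          np.array([0, 0, 0, 0, 1, -3.0]))
        with pytest.warns(UserWarning, match="affine"):
            tf = reg.prune_and_fit(self._pairs_from_map(q, n=6))
        assert np.allclose(tf.poly_x[:3], 0.0)
        assert tf.residual_px < 1e-6

    def test_single_pair_is_translation(self):
        pair = reg.PointPair(source=(10.0, 20.0), target=(110.0, 15.0),
                             peak_height=1.0, level=0)
        tf = reg.prune_and_fit([pair])
        out = tf.forward_points(np.array([[0.0, 0.0]]))
        assert np.allclose(out, [[100.0, -5.0]])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            reg.prune_and_fit([])


class TestRegionTransform:
    def test_forward_inverse_round_trip(self):
        """10,000 random points through forward then inverse must come
        back within a quarter pixel."""
        coef_x = np.array([3e-5, -2e-5, 1e-5, 1.02, 0.01, 229.0])
        coef_y = np.array([-1e-5, 2.5e-5, -1.5e-5, -0.008, 0.99, 152.0])
        q = quadratic_map(coef_x, coef_y)
        rng = np.random.default_rng(8)
        src = rng.uniform(0, 250, (40, 2))
        pairs = [reg.PointPair(tuple(s), tuple(d), 1.0, 0)
                 for s, d in zip(src, q(src))]
        pin = reg.PincushionModel.for_shape((256, 256), 0.12)
        tf = reg.prune_and_fit(pairs, pincushion=pin)
        pts = rng.uniform(0, 255, (10000, 2))
        back = tf.inverse_points(tf.forward_points(pts))
        assert np.abs(back - pts).max() <= 0.25

    def test_serialization_round_trip(self):
        tf = reg.RegionTransform(
            poly_x=np.array([0, 0, 0, 1.0, 0, 3.0]),
            poly_y=np.array([0, 0, 0, 0, 1.0, -2.0]),
            inv_poly_x=np.array([0, 0, 0, 1.0, 0, -3.0]),
            inv_poly_y=np.array([0, 0, 0, 0, 1.0, 2.0]))
        d = tf.to_dict()
        tf2 = reg.RegionTransform.from_dict(d)
        pts = np.array([[5.0, 6.0]])
        assert np.allclose(tf.forward_points(pts), tf2.forward_points(pts))


class TestEstimateK:
    def test_known_k_recovered_within_grid_step(self, fundus_phantom,
                                                reference):
        """Synthesize a capture with k*=0.15; the grid search must land
        on 0.15 (unimodal score curve, minimum at the truth)."""
        ideal = fundus_phantom.fundus_map[150:150 + 256, 200:200 + 256]
        model = reg.PincushionModel.for_shape(ideal.shape, 0.15)
        captured = reg.distort_image(ideal, model)
        grid = [0.0, 0.05, 0.10, 0.15, 0.20]
        est = reg.estimate_k([captured], reference, grid, levels_n=1,
                             min_part_px=16)
        assert est.k == pytest.approx(0.15, abs=0.05)
        curve = est.score_curve
        assert min(curve, key=curve.get) == est.k

    def test_undistorted_input_prefers_zero(self, fundus_phantom,
                                            reference):
        part = fundus_phantom.fundus_map[150:150 + 256, 200:200 + 256]
        est = reg.estimate_k([part], reference, [-0.05, 0.0, 0.05, 0.1],
                             levels_n=1, min_part_px=16)
        assert est.k == pytest.approx(0.0, abs=0.05)

    def test_empty_grid_rejected(self, reference):
        with pytest.raises(ValueError):
            reg.estimate_k([np.ones((64, 64))], reference, [])


class TestGeometryRoundTrip:
    def test_rendered_region_registers_to_its_centre(self, fundus_phantom,
                                                     reference):
        """Identity-distortion render -> projection -> registration must
        recover the region placement within 1 px."""
        geom = om.AcquisitionGeometry.desk(samples=(192, 96),
                                           depth_samples=128)
        vol = om.render_oct_volume(fundus_phantom, geom, "central",
                                   seed=4, noise_sd=0.02)
        surf = om.segment_volume(vol, smooth_window=13)
        flat, _ = om.flatten_volume(vol, surf)
        proj = om.project_band(flat, band_um=30.0)
        iso = reg.resample_isotropic(proj)
        pairs = reg.pyramid_pointset(reference, iso, levels_n=1,
                                     min_part_px=16)
        tf = reg.prune_and_fit(pairs)
        # centre of the projection must land on the phantom centre
        centre_src = np.array([[(iso.shape[1] - 1) / 2.0,
                                (iso.shape[0] - 1) / 2.0]])
        mapped = tf.forward_points(centre_src)[0]
        n = fundus_phantom.shape[0]
        expected = (n - 1) / 2.0 + 32       # plus reference padding
        assert mapped[0] == pytest.approx(expected, abs=1.0)
        assert mapped[1] == pytest.approx(expected, abs=1.0)
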
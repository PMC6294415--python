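"""HG frame, core/gradient ROI delineation, overlap and ROI statistics."""

import numpy as np
import pytest

from tonocore.gradients import (VectorField, cluster_reversals,
                                detect_reversals, smooth_map_or_field,
                                sobel_field)
from tonocore.roi import (Frame, core_roi, curvature_by_frequency,
                          gradient_rois, hg_frame, overlap_stats,
                          reversal_orientation, roi_stats)
from tonocore.synth import Ellipse


def ridge_map(angle_deg, n=80, width=6.0):
    yy, xx = np.meshgrid(np.arange(float(n)), np.arange(float(n)),
                         indexing="ij")
    th = np.deg2rad(angle_deg)
    d = -np.sin(th) * (xx - n / 2) + np.cos(th) * (yy - n / 2)
    return np.exp(-(d / width) ** 2)


class TestHgFrame:
    @pytest.mark.parametrize("angle", [40.0, 130.0])
    def test_ridge_axis_recovered(self, angle):
        m = ridge_map(angle)
        roi = m > 0.4
        f = hg_frame(m, roi, 0.33)
        d = abs(f.axis_deg - angle) % 180
        assert min(d, 180 - d) < 2.0

    def test_circular_bump_degenerate(self):
        n = 60
        yy, xx = np.meshgrid(np.arange(float(n)), np.arange(float(n)),
                             indexing="ij")
        m = np.exp(-(((xx - n / 2) ** 2 + (yy - n / 2) ** 2) / 100.0))
        with pytest.warns(UserWarning, match="isotropic"):
            f = hg_frame(m, m > 0.3, 0.33)
        assert f.degenerate

    def test_empty_roi(self):
        with pytest.raises(ValueError):
            hg_frame(np.zeros((5, 5)), np.zeros((5, 5), bool))


def ellipse_mask(angle_deg, a=20.0, b=10.0, n=90):
    yy, xx = np.meshgrid(np.arange(float(n)), np.arange(float(n)),
                         indexing="ij")
    th = np.deg2rad(angle_deg)
    u = np.cos(th) * (xx - n / 2) + np.sin(th) * (yy - n / 2)
    v = -np.sin(th) * (xx - n / 2) + np.cos(th) * (yy - n / 2)
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


class TestRoiStats:
    def test_ellipse_long_axis(self):
        frame = Frame(origin_rc=(45, 45), axis_deg=0.0)
        st = roi_stats(ellipse_mask(70.0), frame)
        d = abs(st.long_axis_deg - 70.0) % 180
        assert min(d, 180 - d) < 1.0
        assert st.axis_stable

    def test_disc_unstable(self):
        frame = Frame(origin_rc=(45, 45), axis_deg=0.0)
        with pytest.warns(UserWarning, match="isotropic"):
            st = roi_stats(ellipse_mask(0.0, a=12, b=12), frame)
        assert not st.axis_stable

    def test_uniform_field_mean_direction(self):
        frame = Frame(origin_rc=(45, 45), axis_deg=0.0)
        th = np.deg2rad(70.0)
        fld = VectorField(np.full((90, 90), np.cos(th)),
                          np.full((90, 90), np.sin(th)),
                          np.ones((90, 90), bool))
        st = roi_stats(ellipse_mask(0.0), frame, fld)
        assert st.mean_gradient_deg == pytest.approx(70.0)

    def test_centroid_in_frame_coordinates(self):
        frame = Frame(origin_rc=(10, 10), axis_deg=90.0, pixel_mm=1.0)
        roi = np.zeros((40, 40), bool)
        roi[20, 10] = True   # 10 rows below origin; u = +10 for a 90 deg axis
        with pytest.warns(UserWarning, match="isotropic"):
            st = roi_stats(roi, frame)
        assert st.centroid_u_mm == pytest.approx(10.0)
        assert st.centroid_v_mm == pytest.approx(0.0)
        assert st.area_mm2 == pytest.approx(1.0)

    def test_empty_roi(self):
        with pytest.raises(ValueError):
            roi_stats(np.zeros((5, 5), bool), Frame((2, 2), 0.0))


class TestCoreRoi:
    def _labels(self, truth):
        return truth.labels

    def test_exact_binary_recovery(self, default_truth):
        t = default_truth
        inside = Ellipse(2.0, 0.0, 11.0, 4.0).contains(t.u, t.v)
        m = inside.astype(float)
        roi = core_roi(m, t.labels, "above", t.mask)
        assert np.array_equal(roi, inside & t.mask)

    def test_polarity_complement(self, default_truth):
        t = default_truth
        inside = Ellipse(2.0, 0.0, 11.0, 4.0).contains(t.u, t.v)
        m = inside.astype(float)
        above = core_roi(m, t.labels, "above", t.mask)
        below = core_roi(m, t.labels, "below", t.mask)
        assert not np.any(above & below)
        assert np.array_equal(above | below, t.mask)

    def test_noisy_dice(self, default_truth, rng):
        """Effect 1, noise SD 1/4 of the effect: Dice with truth > 0.8."""
        t = default_truth
        inside = Ellipse(-2.0, 0.0, 10.0, 3.5).contains(t.u, t.v)
        m = inside + 0.25 * rng.standard_normal(t.grid_shape)
        roi = core_roi(m, t.labels, "above", t.mask)
        truth_roi = inside & t.mask
        dice = 2 * (roi & truth_roi).sum() / (roi.sum() + truth_roi.sum())
        assert dice > 0.8

    def test_missing_labels_rejected(self, default_truth):
        with pytest.raises(ValueError, match="te10"):
            core_roi(np.ones((5, 5)), {"anterior": np.ones((5, 5), bool),
                                       "posterior": np.ones((5, 5), bool)},
                     "above", np.ones((5, 5), bool))


class TestGradientRois:
    @pytest.fixture()
    def truth_clusters(self, default_truth):
        t = default_truth
        fld = sobel_field(t.pf_cam, t.mask, t.patch.pixel_mm)
        sm = smooth_map_or_field(fld, 6.0, t.patch.pixel_mm)
        rm = detect_reversals(sm, t.pf_cam)
        return cluster_reversals(rm)

    def test_rois_match_truth_bands(self, default_truth, truth_clusters):
        t = default_truth
        frame = hg_frame(t.curvature, t.labels["hg"], t.patch.pixel_mm)
        ant, post = gradient_rois(truth_clusters, frame, t.mask)
        L, px = t.band_width_mm, t.patch.pixel_mm
        tol = 1.5 * px
        band_ant = (t.v > 0) & (t.v < L) & t.mask
        band_post = (t.v < 0) & (t.v > -L) & t.mask
        # interior pixels (further than tol from any band boundary) agree
        interior_ant = (t.v > tol) & (t.v < L - tol) & t.mask
        interior_post = (t.v < -tol) & (t.v > -L + tol) & t.mask
        assert np.all(ant[interior_ant])
        assert np.all(post[interior_post])
        outside = t.mask & (np.abs(t.v) > L + tol)
        assert not np.any(ant[outside]) and not np.any(post[outside])

    def test_missing_side_raises(self, default_truth, truth_clusters):
        t = default_truth
        frame = hg_frame(t.curvature, t.labels["hg"], t.patch.pixel_mm)
        lows_plus_ant = [c for c in truth_clusters
                         if c.denomination == "low"
                         or np.mean(frame.to_frame(c.pixels[:, 0],
                                                   c.pixels[:, 1])[1]) > 0]
        with pytest.raises(ValueError, match="posterior"):
            gradient_rois(lows_plus_ant, frame, t.mask)

    def test_masked_corridor_clipped(self, default_truth, truth_clusters):
        t = default_truth
        frame = hg_frame(t.curvature, t.labels["hg"], t.patch.pixel_mm)
        mask = t.mask.copy()
        mask[:, 50:55] = False
        ant, _ = gradient_rois(truth_clusters, frame, mask)
        assert not np.any(ant[:, 50:55])


class TestOverlap:
    def test_identities(self):
        a = np.zeros((10, 10), bool)
        a[2:6, 2:6] = True
        b = np.zeros((10, 10), bool)
        b[4:9, 4:9] = True
        ov = overlap_stats(a, a, b)
        assert ov.overlap_anterior == 1.0
        sym1 = overlap_stats(a, b, b).overlap_anterior
        sym2 = overlap_stats(b, a, a).overlap_anterior
        assert sym1 == sym2

    def test_disjoint_and_ratio(self):
        a = np.zeros((10, 10), bool)
        a[:5] = True
        b = ~a
        ov = overlap_stats(a, a, b)
        assert ov.overlap_posterior == 0.0
        assert np.isinf(ov.overlap_ratio)
        assert np.isnan(overlap_stats(a, np.zeros_like(a), b).overlap_anterior)

    def test_symmetric_core_ratio_one(self, default_truth):
        t = default_truth
        core = (np.abs(t.v) < 4) & (np.abs(t.u) < 10) & t.mask
        ant = (t.v > 0) & (t.v < t.band_width_mm) & t.mask
        post = (t.v < 0) & (t.v > -t.band_width_mm) & t.mask
        ov = overlap_stats(core, ant, post)
        assert ov.overlap_ratio == pytest.approx(1.0, abs=0.05)


class TestReversalOrientation:
    def _cluster(self, angle, n_px):
        from tonocore.gradients import ReversalCluster

        t = np.linspace(-10, 10, n_px)
        pix = np.column_stack([50 + t * np.sin(np.deg2rad(angle)),
                               50 + t * np.cos(np.deg2rad(angle))]).round().astype(int)
        return ReversalCluster(pixels=pix, orientation_deg=angle % 180,
                               denomination="low")

    def test_parallel_cluster_zero(self):
        frame = Frame((50, 50), 0.0)
        assert reversal_orientation([self._cluster(0.0, 100)], frame) == \
            pytest.approx(0.0, abs=1e-6)

    def test_symmetric_clusters_average_to_zero(self):
        frame = Frame((50, 50), 0.0)
        cl = [self._cluster(10.0, 100), self._cluster(-10.0, 100)]
        assert reversal_orientation(cl, frame) == pytest.approx(0.0, abs=1e-6)

    def test_no_clusters(self):
        with pytest.raises(ValueError):
            reversal_orientation([], Frame((0, 0), 0.0))


class TestCurvatureByFrequency:
    def test_constant_curvature(self, default_truth, rng):
        t = default_truth
        tab = curvature_by_frequency(t.mask, t.pf_cam,
                                     np.full(t.grid_shape, 0.4), n_bins=5)
        assert np.allclose(tab.mean_curvature, 0.4)

    def test_single_bin_is_roi_mean(self, default_truth):
        t = default_truth
        tab = curvature_by_frequency(t.mask, t.pf_cam, t.curvature, n_bins=1)
        assert tab.mean_curvature[0] == pytest.approx(t.curvature[t.mask].mean())

    def test_anterior_band_trend(self, default_truth):
        """On the anterior gradient, low preferred frequencies sit on the
        gyral crest (positive curvature) and high frequencies on the bank
        (negative): binned curvature decreases with frequency."""
        t = default_truth
        band = (t.v > 0) & (t.v < t.band_width_mm) & t.mask
        tab = curvature_by_frequency(band, t.pf_cam, t.curvature, n_bins=6)
        assert tab.mean_curvature.iloc[0] > tab.mean_curvature.iloc[-1]
        assert tab.mean_curvature.iloc[0] > 0 > tab.mean_curvature.iloc[-1]


class TestFrameCovariance:
    def test_rotation_translation_invariance(self, default_truth):
        """Rotating the whole patch by 90 deg leaves frame-relative ROI
        statistics unchanged within discretisation tolerance."""
        t = default_truth
        frame = hg_frame(t.curvature, t.labels["hg"], t.patch.pixel_mm)
        core = Ellipse(2.0, 1.0, 11.0, 4.0, 20.0).contains(t.u, t.v) & t.mask
        st = roi_stats(core, frame)

        curv_r = np.rot90(t.curvature)
        hg_r = np.rot90(t.labels["hg"])
        core_r = np.rot90(core)
        frame_r = hg_frame(curv_r, hg_r, t.patch.pixel_mm)
        st_r = roi_stats(core_r, frame_r)
        d = abs(st.long_axis_deg - st_r.long_axis_deg) % 180
        assert min(d, 180 - d) < 1.0
        assert st.area_mm2 == st_r.area_mm2
        assert abs(abs(st.centroid_u_mm) - abs(st_r.centroid_u_mm)) < 0.5
        assert abs(abs(st.centroid_v_mm) - abs(st_r.centroid_v_mm)) < 0.5
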
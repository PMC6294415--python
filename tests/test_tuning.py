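"""Tuning curves: centroid/spread, debiasing, width fitting, split-half."""

import numpy as np
import pytest

from tonocore.scale import hz_to_cam
from tonocore.tuning import (STIM_CAM, GaussianBank, centroid, debias,
                             debias_map, spread, split_half, tuning_width)


def brute_centroid(beta, f):
    num = den = 0.0
    for b, x in zip(beta, f):
        w = max(b, 0.0)
        num += w * x
        den += w
    return num / den if den > 0 else float("nan")


def brute_spread(beta, f):
    c = brute_centroid(beta, f)
    num = den = 0.0
    for b, x in zip(beta, f):
        w = max(b, 0.0)
        num += w * (x - c) ** 2
        den += w
    return np.sqrt(num / den) if den > 0 else float("nan")


class TestCentroidSpread:
    def test_single_peak(self):
        beta = np.array([0, 0, 0, 1.0, 0, 0, 0])
        assert centroid(beta) == pytest.approx(STIM_CAM[3])
        assert spread(beta) == 0.0

    def test_two_point(self):
        beta = np.zeros(7)
        beta[0] = beta[6] = 0.8
        assert centroid(beta) == pytest.approx((STIM_CAM[0] + STIM_CAM[6]) / 2)
        assert spread(beta) == pytest.approx((STIM_CAM[6] - STIM_CAM[0]) / 2)

    def test_matches_direct_sum_oracle(self, rng):
        for _ in range(100):
            beta = rng.standard_normal(7)  # negatives exercised (clipped)
            if np.all(beta <= 0):
                continue
            assert centroid(beta) == pytest.approx(
                brute_centroid(beta, STIM_CAM), abs=1e-12)
            assert spread(beta) == pytest.approx(
                brute_spread(beta, STIM_CAM), abs=1e-12)

    def test_all_nonpositive_undefined(self):
        assert np.isnan(centroid(-np.ones(7)))
        assert np.isnan(spread(-np.ones(7)))

    def test_literal_spread_reading(self):
        beta = np.array([0, 0.5, 1.0, 0.5, 0, 0, 0])
        c = centroid(beta)
        expect = np.sum((STIM_CAM - c) ** 2) / np.clip(beta, 0, None).sum()
        assert spread(beta, literal=True) == pytest.approx(expect)


class TestDebias:
    def test_self_match(self, bank):
        idx = [10, 5000, 15000, 23000]
        for i in idx:
            assert debias(bank.curves[i], bank) == bank.modes[i]

    def test_idempotent_on_bank_curves(self, bank, rng):
        for i in rng.integers(0, bank.modes.size, 100):
            m = debias(bank.curves[i], bank)
            j = np.argmin(np.abs(bank.modes - m) + np.abs(bank.widths - bank.widths[i]))
            assert debias(bank.curves[j], bank) == m

    def test_monotone_curve_outside_range(self, bank):
        assert debias(np.linspace(0.1, 1.0, 7), bank) > STIM_CAM[-1]
        assert debias(np.linspace(1.0, 0.1, 7), bank) < STIM_CAM[0]

    def test_centroid_bias_grows_at_edges_debias_corrects(self, bank):
        """The motivating bias: centroids are pulled to mid-range near the
        stimulus edges, and the bank matching removes most of it."""
        sigma = 4.0
        modes = hz_to_cam(np.array([251.0, 900.0, 2400.0, 6009.0]))
        cen_err, deb_err = [], []
        for m in modes:
            beta = np.exp(-((STIM_CAM - m) ** 2) / (2 * sigma ** 2))
            cen_err.append(abs(centroid(beta) - m))
            deb_err.append(abs(debias(beta, bank) - m))
        # bias grows towards the edges ...
        assert cen_err[0] > 2.0 and cen_err[-1] > 2.0
        assert cen_err[1] < cen_err[0] and cen_err[2] < cen_err[-1]
        # ... and the debiased estimates stay far more accurate
        assert max(deb_err) < 0.5
        assert max(deb_err) < 0.1 * max(cen_err)

    def test_empty_bank_rejected(self):
        with pytest.raises(ValueError):
            debias(np.ones(7), None)

    def test_debias_map_masks(self, bank):
        betas = np.ones((2, 7, 4, 4))
        mask = np.zeros((4, 4), bool)
        mask[1:3, 1:3] = True
        out = debias_map(betas, bank, mask)
        assert np.isnan(out[:, 0, 0]).all()
        assert np.isfinite(out[:, 1, 1]).all()


def curves_to_stack(curves):
    """(n, 7) -> (1 depth, 7, n, 1) pixel stack."""
    return np.moveaxis(np.asarray(curves), 1, 0)[None, :, :, None]


class TestTuningWidth:
    def test_noiseless_width_recovery(self):
        """Widths of noiseless Gaussian curves recovered within 2 percent
        for sigma in [2, 10] ERB_N (no smoothing)."""
        sigmas = np.linspace(2, 10, 9)
        modes = np.linspace(STIM_CAM[1], STIM_CAM[5], 9)
        curves = [1.3 * np.exp(-((STIM_CAM - m) ** 2) / (2 * s * s))
                  for m, s in zip(modes, sigmas)]
        stack = curves_to_stack(curves)
        mask = np.ones((len(curves), 1), bool)
        w = tuning_width(stack, mask, smoothing_fwhm_mm=0.0)
        assert np.allclose(w[:, 0], sigmas, rtol=0.02)

    def test_flat_curve_invalid(self):
        stack = curves_to_stack([np.full(7, 0.7)])
        w = tuning_width(stack, np.ones((1, 1), bool), smoothing_fwhm_mm=0.0)
        assert np.isnan(w[0, 0])

    def test_fit_beats_grid_search_oracle(self, rng):
        """The polished fit attains at least the SSE of an independent
        4-parameter grid search, with widths within one oracle grid cell."""
        grid_m = np.arange(STIM_CAM[0] - 4, STIM_CAM[-1] + 4.01, 0.5)
        grid_s = np.geomspace(0.4, 20.0, 30)
        curves, true_w = [], []
        for _ in range(100):
            m = rng.uniform(STIM_CAM[0], STIM_CAM[-1])
            s = rng.uniform(1.5, 12.0)
            h = rng.uniform(0.5, 2.0)
            b = -rng.uniform(0.0, 0.3)
            y = h * np.exp(-((STIM_CAM - m) ** 2) / (2 * s * s)) + b
            y += 0.05 * rng.standard_normal(7)
            curves.append(y)
            true_w.append(s)
        stack = curves_to_stack(curves)
        mask = np.ones((len(curves), 1), bool)
        w, fit = tuning_width(stack, mask, smoothing_fwhm_mm=0.0,
                              return_fit=True)
        grid_h = np.linspace(0, 2.5, 11)
        grid_b = np.linspace(-0.5, 0, 6)
        # oracle: exhaustive search over the full 4-parameter grid
        g_all = np.exp(-((STIM_CAM - grid_m[:, None, None]) ** 2)
                       / (2 * grid_s[None, :, None] ** 2))      # (m, s, 7)
        models = (grid_h[:, None, None, None, None] * g_all
                  + grid_b[None, :, None, None, None])          # (h, b, m, s, 7)
        for i, y in enumerate(curves):
            sse_all = ((y - models) ** 2).sum(axis=-1)
            flat = np.argmin(sse_all)
            _, _, _, k = np.unravel_index(flat, sse_all.shape)
            best_sse = sse_all.ravel()[flat]
            best_s = grid_s[k]
            assert fit["sse"][i, 0] <= best_sse + 1e-9
            if np.isfinite(w[i, 0]):
                # agree with the oracle cell, unless the continuous fit
                # found a strictly better optimum the coarse grid missed
                cell = best_s * (grid_s[1] / grid_s[0] - 1)
                assert (abs(w[i, 0] - best_s) <= 1.5 * cell
                        or fit["sse"][i, 0] < best_sse - 1e-8)

    def test_selectivity_ellipse_detected_under_noise(self, rng):
        """Narrow-tuning region (4 vs 9 ERB_N) at SNR 2: interior mean
        width below exterior mean width (one-sided test p < 0.01)."""
        from scipy import stats

        from tonocore.synth import (CoreTruth, Ellipse, NoiseModel,
                                    PatchConfig, generate_truth,
                                    simulate_betas)

        patch = PatchConfig(grid_shape=(40, 40), mask_semi_u_mm=5.5,
                            mask_semi_v_mm=5.5)
        core = CoreTruth(myelin_ellipse=Ellipse(-0.5, 0, 3, 1.5),
                         selectivity_ellipse=Ellipse(0, 0, 3.5, 2.0),
                         te10=Ellipse(0, 0, 1.5, 1.0),
                         te11=Ellipse(-3, 0, 1.0, 0.8),
                         te12=Ellipse(3, 0, 1.0, 0.8))
        t = generate_truth(patch, core=core)
        betas, _ = simulate_betas(t, noise=NoiseModel(beta_noise_sd=0.5),
                                  rng=rng)
        w = tuning_width(betas, t.mask, pixel_mm=patch.pixel_mm)
        inside = core.selectivity_ellipse.contains(t.u, t.v) & np.isfinite(w)
        outside = t.mask & ~core.selectivity_ellipse.contains(t.u, t.v) & np.isfinite(w)
        res = stats.ttest_ind(w[inside], w[outside], alternative="less")
        assert res.pvalue < 0.01


class TestSplitHalf:
    def test_identical_halves(self, bank, default_truth, rng):
        from tonocore.synth import NoiseModel, simulate_betas

        betas, _ = simulate_betas(default_truth, rng=rng,
                                  noise=NoiseModel(beta_noise_sd=0.3),
                                  n_depths=4)
        r = split_half(betas, betas, bank, default_truth.mask,
                       depth_range=(0, 4))
        assert r == pytest.approx(1.0)

    def test_pure_noise_uncorrelated(self, bank, rng):
        mask = np.ones((30, 30), bool)
        a = rng.standard_normal((2, 7, 30, 30))
        b = rng.standard_normal((2, 7, 30, 30))
        r = split_half(a, b, bank, mask, depth_range=(0, 2))
        assert abs(r) < 3.0 / np.sqrt(mask.sum())

    def test_reliability_increases_as_noise_decreases(self, bank, rng):
        from tonocore.synth import (CoreTruth, Ellipse, NoiseModel,
                                    PatchConfig, generate_truth,
                                    simulate_betas)

        patch = PatchConfig(grid_shape=(40, 40), mask_semi_u_mm=5.5,
                            mask_semi_v_mm=5.5)
        core = CoreTruth(myelin_ellipse=Ellipse(-0.5, 0, 3, 1.5),
                         selectivity_ellipse=Ellipse(0.5, 0, 3, 1.5),
                         te10=Ellipse(0, 0, 1.5, 1.0),
                         te11=Ellipse(-3, 0, 1.0, 0.8),
                         te12=Ellipse(3, 0, 1.0, 0.8))
        t = generate_truth(patch, core=core)
        rs = []
        for sd in (1.5, 0.5):
            a, _ = simulate_betas(t, noise=NoiseModel(beta_noise_sd=sd),
                                  n_depths=2, rng=rng)
            b, _ = simulate_betas(t, noise=NoiseModel(beta_noise_sd=sd),
                                  n_depths=2, rng=rng)
            rs.append(split_half(a, b, bank, t.mask, depth_range=(0, 2)))
        assert 0 < rs[0] < rs[1] < 1

    def test_too_few_common_pixels(self, bank):
        a = np.ones((1, 7, 2, 1))
        mask = np.zeros((2, 1), bool)
        with pytest.raises(ValueError):
            split_half(a, a, bank, mask, depth_range=(0, 1))
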
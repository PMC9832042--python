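"""Surface-roughness tests: contour extraction, quartic-fit equivalence
with a brute-force normal-equations oracle, index invariances, and
recovery of the generator's programmed amplitudes."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from cartimorph.roughness import (
    SurfaceContour,
    compute_roughness,
    extract_surface_contour,
    fit_quartic,
    roughness_by_group,
    roughness_from_mask,
)
from cartimorph.simulate import generate_surface_mask

from conftest import quartic_fit_oracle


class TestContourExtraction:
    def test_full_rectangle_gives_top_row(self):
        mask = np.ones((40, 100), dtype=np.uint8)
        contour = extract_surface_contour(mask)
        assert len(contour.x) == 100
        assert np.all(contour.y == 0)
        assert np.array_equal(contour.x, np.arange(100.0))

    def test_zero_amplitude_mask_recovers_baseline(self):
        baseline = np.array([30.0, 0.05, 1e-4, 0.0, 0.0])
        mask, _ = generate_surface_mask(150, 128, baseline, 0.0, seed=0)
        contour = extract_surface_contour(mask)
        x = contour.x
        expected = np.rint(
            baseline[0] + baseline[1] * x + baseline[2] * x**2
        )
        assert np.array_equal(contour.y, expected)

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError, match="no tissue"):
            extract_surface_contour(np.zeros((20, 20), dtype=np.uint8))

    def test_too_few_columns_raises(self):
        mask = np.zeros((20, 20), dtype=np.uint8)
        mask[5:, 3:7] = 1  # only 4 columns wide
        with pytest.raises(ValueError, match="contour too short"):
            extract_surface_contour(mask)

    def test_largest_component_wins_and_gaps_excluded(self):
        mask = np.zeros((30, 40), dtype=np.uint8)
        mask[10:, 0:30] = 1  # large slab
        mask[2:4, 35:39] = 1  # small distractor
        contour = extract_surface_contour(mask)
        assert contour.x.max() == 29
        assert np.all(contour.y == 10)

    def test_contour_validation(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            SurfaceContour(np.array([0, 1, 1, 2, 3, 4]), np.zeros(6))
        with pytest.raises(ValueError, match="too short"):
            SurfaceContour(np.arange(5), np.zeros(5))


class TestQuarticFit:
    def test_exact_quartic_has_zero_residuals(self):
        x = np.arange(0, 101, dtype=float)
        y = 2.0 + 1e-3 * x**4
        coeffs, resid = fit_quartic(SurfaceContour(x, y))
        assert np.max(np.abs(resid)) < 1e-6
        assert coeffs[4] == pytest.approx(1e-3, rel=1e-8)

    def test_constant_contour(self):
        x = np.arange(10, dtype=float)
        coeffs, resid = fit_quartic(SurfaceContour(x, np.full(10, 7.0)))
        assert coeffs[0] == pytest.approx(7.0, abs=1e-9)
        assert np.allclose(coeffs[1:], 0.0, atol=1e-9)
        assert np.allclose(resid, 0.0, atol=1e-9)

    def test_residuals_match_normal_equations_oracle(self, rng):
        """50 random small contours: residuals and MAD error agree with
        the brute-force least-squares oracle to 1e-8 relative."""
        for _ in range(50):
            n = rng.integers(8, 31)
            x = np.sort(rng.choice(np.arange(200), size=n, replace=False)).astype(float)
            y = rng.normal(50, 5, n) + 0.01 * (x - x.mean()) ** 2
            contour = SurfaceContour(x, y)
            _, resid = fit_quartic(contour)
            _, resid_oracle = quartic_fit_oracle(x, y)
            assert np.allclose(resid, resid_oracle, rtol=1e-8, atol=1e-8)
            res = compute_roughness(contour)
            assert res.error == pytest.approx(
                np.mean(np.abs(resid_oracle)), rel=1e-8
            )


class TestRoughnessIndex:
    def test_perfect_quartic_gives_zero_roughness(self):
        x = np.arange(0, 100, dtype=float)
        y = 10 + 0.5 * x - 1e-3 * x**2 + 1e-6 * x**4
        res = compute_roughness(SurfaceContour(x, y))
        assert res.error == pytest.approx(0.0, abs=1e-8)
        assert res.roughness == pytest.approx(0.0, abs=1e-10)

    def test_error_is_mean_absolute_residual_of_fit(self, rng):
        x = np.arange(0, 100, dtype=float)
        y = 50 + rng.normal(0, 2, 100)
        contour = SurfaceContour(x, y)
        _, resid = fit_quartic(contour)
        res = compute_roughness(contour)
        assert res.error == pytest.approx(np.mean(np.abs(resid)), rel=1e-12)
        assert res.roughness == pytest.approx(res.error / res.length, rel=1e-12)

    def test_length_is_endpoint_distance(self):
        x = np.arange(0, 100, dtype=float)
        y = np.linspace(0, 30, 100)
        res = compute_roughness(SurfaceContour(x, y))
        assert res.length == pytest.approx(np.hypot(99, 30), rel=1e-12)

    def test_scale_invariance(self, rng):
        x = np.arange(0, 100, dtype=float)
        y = 50 + rng.normal(0, 3, 100)
        r1 = compute_roughness(SurfaceContour(x, y)).roughness
        for s in (2.0, 7.5):
            r2 = compute_roughness(SurfaceContour(s * x, s * y)).roughness
            assert r2 == pytest.approx(r1, rel=1e-9)

    def test_vertical_translation_invariance(self, rng):
        x = np.arange(0, 80, dtype=float)
        y = 40 + rng.normal(0, 2, 80)
        r1 = compute_roughness(SurfaceContour(x, y)).roughness
        r2 = compute_roughness(SurfaceContour(x, y + 100)).roughness
        # L changes only through endpoints; y-shift leaves both E and
        # endpoint geometry unchanged
        assert r2 == pytest.approx(r1, rel=1e-12)

    def test_rms_metric_option(self, rng):
        x = np.arange(0, 60, dtype=float)
        y = 30 + rng.normal(0, 2, 60)
        contour = SurfaceContour(x, y)
        _, resid = fit_quartic(contour)
        res = compute_roughness(contour, metric="rms")
        assert res.error == pytest.approx(np.sqrt(np.mean(resid**2)), rel=1e-12)
        with pytest.raises(ValueError):
            compute_roughness(contour, metric="median")


class TestAmplitudeRecovery:
    def test_estimated_error_monotone_in_amplitude(self):
        """Estimated E tracks the generator's programmed roughness
        amplitude (smaller sweep than the acceptance run)."""
        amplitudes = [0.5, 2.0, 8.0]
        baseline = np.array([60.0, 0.0, 0.0, 0.0, 0.0])
        est, true = [], []
        for i, amp in enumerate(amplitudes):
            for seed in range(5):
                mask, truth = generate_surface_mask(
                    300, 128, baseline, amp, seed=100 * i + seed, smooth_window=5
                )
                est.append(roughness_from_mask(mask).error)
                true.append(amp)
        rho = spearmanr(true, est).statistic
        assert rho > 0.9

    def test_group_trend_positive_under_programmed_effect(self):
        baseline = np.array([60.0, 0.0, 0.0, 0.0, 0.0])
        masks, meta = {}, []
        for code, (group, amp) in enumerate(
            [("young", 1.0), ("middle", 2.5), ("aged", 4.0)]
        ):
            for s in range(4):
                img_id = f"{group}_{s}"
                masks[img_id], _ = generate_surface_mask(
                    300, 128, baseline, amp, seed=17 + 10 * code + s, smooth_window=5
                )
                meta.append(
                    {"image_id": img_id, "sample_id": img_id,
                     "group": group, "group_code": code}
                )
        table, trend = roughness_by_group(masks, pd.DataFrame(meta))
        assert trend.params["group_code"] > 0
        assert trend.pvalues["group_code"] < 0.05

    def test_single_sample_per_group_rejected(self):
        baseline = np.array([60.0, 0.0, 0.0, 0.0, 0.0])
        masks, meta = {}, []
        for code, group in enumerate(["young", "aged"]):
            img_id = f"{group}_0"
            masks[img_id], _ = generate_surface_mask(200, 128, baseline, 1.0, seed=code)
            meta.append({"image_id": img_id, "sample_id": img_id,
                         "group": group, "group_code": code})
        with pytest.raises(ValueError, match=">= 2"):
            roughness_by_group(masks, pd.DataFrame(meta))

    def test_failed_masks_warn_and_are_excluded(self):
        baseline = np.array([60.0, 0.0, 0.0, 0.0, 0.0])
        masks, meta = {}, []
        for code, group in enumerate(["young", "aged"]):
            for s in range(2):
                img_id = f"{group}_{s}"
                masks[img_id], _ = generate_surface_mask(
                    200, 128, baseline, 1.0, seed=5 * code + s
                )
                meta.append({"image_id": img_id, "sample_id": img_id,
                             "group": group, "group_code": code})
        masks["young_0"] = np.zeros((128, 200), dtype=np.uint8)  # empty mask
        meta.append({"image_id": "young_2", "sample_id": "young_2",
                     "group": "young", "group_code": 0})
        masks["young_2"], _ = generate_surface_mask(200, 128, baseline, 1.0, seed=77)
        with pytest.warns(UserWarning, match="failed"):
            table, _ = roughness_by_group(masks, pd.DataFrame(meta))
        assert "young_0" not in set(table["sample_id"])
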
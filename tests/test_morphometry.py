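"""Nuclear morphometry tests: the 53-descriptor roster, analytic shape
limits on rasterized disks and ellipses, brute-force moment-oracle
equivalence, invariances, and segmentation against generator truth."""

import warnings

import numpy as np
import pandas as pd
import pytest

from cartimorph.morphometry import (
    FEATURE_NAMES,
    GEOMETRY_FEATURE_NAMES,
    ZERNIKE_FEATURE_NAMES,
    LabeledNuclei,
    aggregate_nuclei_by_sample,
    eccentricity_from_moments,
    ellipse_from_coords,
    measure_features,
    segment_nuclei,
)
from cartimorph.simulate import generate_nuclei_image

from conftest import moments_oracle, raster_ellipse


class TestRoster:
    def test_roster_is_exactly_53_descriptors(self):
        assert len(FEATURE_NAMES) == 53
        assert len(set(FEATURE_NAMES)) == 53
        assert len(GEOMETRY_FEATURE_NAMES) == 23
        assert len(ZERNIKE_FEATURE_NAMES) == 30

    def test_measured_table_has_53_feature_columns(self):
        mask = raster_ellipse(12, 8).astype(np.uint8)
        df = measure_features(LabeledNuclei(mask.astype(np.int32), 1))
        feat_cols = [c for c in df.columns if c not in ("image_id", "nucleus_id")]
        assert feat_cols == list(FEATURE_NAMES)
        assert np.isfinite(df[feat_cols].to_numpy(dtype=float)).all()


class TestShapeLimits:
    def test_large_disk_limits(self):
        mask = raster_ellipse(40, 40)
        df = measure_features(LabeledNuclei(mask.astype(np.int32), 1))
        row = df.iloc[0]
        assert row["eccentricity"] <= 0.08
        assert row["solidity"] >= 0.98
        assert row["form_factor"] >= 0.92
        assert row["area"] == pytest.approx(np.pi * 40**2, rel=0.02)
        assert row["max_feret_diameter"] == pytest.approx(81, rel=0.03)
        assert row["min_feret_diameter"] == pytest.approx(81, rel=0.03)
        assert row["max_radius"] == pytest.approx(41, rel=0.05)

    def test_ellipse_eccentricity_analytic(self):
        mask = raster_ellipse(40, 20)
        e = eccentricity_from_moments(mask)
        assert e == pytest.approx(np.sqrt(3) / 2, abs=0.02)

    def test_rotated_ellipse_orientation_and_eccentricity(self):
        mask = raster_ellipse(40, 20, phi_deg=37.0)
        res = ellipse_from_coords(np.argwhere(mask))
        assert res["eccentricity"] == pytest.approx(np.sqrt(3) / 2, abs=0.02)
        assert res["orientation"] == pytest.approx(37.0, abs=2.0)

    def test_square_block_is_round(self):
        mask = np.zeros((30, 30), dtype=bool)
        mask[5:25, 5:25] = True
        assert eccentricity_from_moments(mask) <= 0.02

    def test_eccentricity_monotone_in_axis_ratio(self):
        ratios = [1.0, 0.8, 0.6, 0.4, 0.2]
        eccs = [
            eccentricity_from_moments(raster_ellipse(40, 40 * r)) for r in ratios
        ]
        assert all(e2 > e1 for e1, e2 in zip(eccs, eccs[1:]))

    def test_collinear_object_convention(self):
        coords = np.stack([np.full(10, 5), np.arange(10)], axis=1)
        e = eccentricity_from_moments(coords)
        assert e == pytest.approx(1.0, abs=1e-6)

    def test_minimum_area(self):
        with pytest.raises(ValueError, match=">= 2"):
            eccentricity_from_moments(np.array([[3, 3]]))


class TestMomentOracle:
    def test_moment_features_match_bruteforce_oracle(self, rng):
        """Moments-ellipse features agree with the double-loop pixel
        oracle to 1e-10 on small random objects."""
        for _ in range(10):
            a = rng.uniform(4, 10)
            b = rng.uniform(2, a)
            phi = rng.uniform(-90, 90)
            mask = raster_ellipse(a, b, phi_deg=phi)
            if mask.sum() > 500 or mask.sum() < 5:
                continue
            res = ellipse_from_coords(np.argwhere(mask))
            oracle = moments_oracle(mask)
            assert res["eccentricity"] == pytest.approx(
                oracle["eccentricity"], abs=1e-10
            )
            assert res["major_axis_length"] == pytest.approx(
                oracle["major_axis_length"], abs=1e-10
            )
            assert res["centroid_x"] == pytest.approx(oracle["centroid"][0], abs=1e-10)
            assert res["centroid_y"] == pytest.approx(oracle["centroid"][1], abs=1e-10)


class TestInvariances:
    @pytest.fixture
    def wobbly_object(self):
        img, _ = generate_nuclei_image(
            1, 0.7, 0.0, seed=21, shape=(96, 96)
        )
        return img

    def test_rotation_90_near_invariance(self, wobbly_object):
        inv_features = [
            "area", "eccentricity", "solidity", "form_factor",
            *ZERNIKE_FEATURE_NAMES,
        ]
        lab1 = segment_nuclei(wobbly_object, 20, 5000)
        lab2 = segment_nuclei(np.rot90(wobbly_object), 20, 5000)
        f1 = measure_features(lab1).iloc[0]
        f2 = measure_features(lab2).iloc[0]
        for name in inv_features:
            ref = max(abs(f1[name]), 1e-3)
            assert abs(f1[name] - f2[name]) / ref < 0.02, name

    def test_translation_invariance_exact(self):
        mask = raster_ellipse(10, 6, phi_deg=20)
        coords = np.argwhere(mask)
        f1 = measure_features(
            LabeledNuclei(mask.astype(np.int32), 1)
        ).iloc[0]
        big = np.zeros((80, 80), dtype=np.int32)
        big[coords[:, 0] + 31, coords[:, 1] + 17] = 1
        f2 = measure_features(LabeledNuclei(big, 1)).iloc[0]
        for name in FEATURE_NAMES:
            if name in ("centroid_x", "centroid_y"):
                continue
            assert f1[name] == pytest.approx(f2[name], abs=1e-10), name

    def test_single_pixel_object_has_conventions_not_nans(self):
        lab = np.zeros((9, 9), dtype=np.int32)
        lab[4, 4] = 1
        df = measure_features(LabeledNuclei(lab, 1))
        row = df.iloc[0]
        assert row["area"] == 1.0
        assert row["perimeter"] == 1.0
        assert row["eccentricity"] == 0.0
        assert np.isfinite(row[list(FEATURE_NAMES)].to_numpy(dtype=float)).all()


class TestSegmentation:
    def test_three_disks_three_objects(self):
        img = np.full((100, 100), 50, dtype=np.uint16)
        for cy, cx in ((20, 20), (50, 70), (80, 30)):
            rr, cc = np.mgrid[0:100, 0:100]
            img[(rr - cy) ** 2 + (cc - cx) ** 2 <= 64] = 4000
        lab = segment_nuclei(img, 20, 1000)
        assert lab.count == 3

    def test_generator_nuclei_recovered_with_matching_centroids(self):
        img, truth = generate_nuclei_image(25, 0.7, 0.05, seed=3, shape=(512, 512))
        lab = segment_nuclei(img, 50, 5000)
        assert lab.count == 25
        feats = measure_features(lab)
        measured = feats.sort_values(["centroid_y", "centroid_x"])[
            ["centroid_y", "centroid_x"]
        ].to_numpy()
        true = truth.sort_values(["center_y", "center_x"])[
            ["center_y", "center_x"]
        ].to_numpy()
        # nearest-neighbour match per truth nucleus
        for ty, tx in true:
            d = np.hypot(measured[:, 0] - ty, measured[:, 1] - tx).min()
            assert d < 2.0

    def test_uniform_image_warns_and_yields_zero_objects(self):
        with pytest.warns(UserWarning, match="uniform"):
            lab = segment_nuclei(np.full((50, 50), 7, dtype=np.uint16), 10, 100)
        assert lab.count == 0

    def test_size_filter_excludes_out_of_range_objects(self):
        img = np.full((80, 80), 50, dtype=np.uint16)
        img[10:12, 10:12] = 4000       # 4 px, below min_area
        img[30:50, 30:50] = 4000       # 400 px, in range
        lab = segment_nuclei(img, 20, 1000)
        assert lab.count == 1

    def test_border_objects_flagged(self):
        img = np.full((60, 60), 50, dtype=np.uint16)
        img[0:10, 20:32] = 4000
        lab = segment_nuclei(img, 20, 1000)
        assert lab.count == 1
        assert lab.border_labels == (1,)

    def test_label_consecutiveness_enforced(self):
        bad = np.zeros((10, 10), dtype=np.int32)
        bad[2, 2] = 3
        with pytest.raises(ValueError, match="consecutive"):
            LabeledNuclei(bad, 1)


class TestAggregation:
    def test_equal_count_images_average(self):
        feats = pd.DataFrame(
            {
                "image_id": ["i1", "i1", "i2", "i2"],
                "nucleus_id": [1, 2, 1, 2],
                "eccentricity": [0.55, 0.65, 0.75, 0.85],
            }
        )
        meta = pd.DataFrame(
            {"image_id": ["i1", "i2"], "sample_id": ["s1", "s1"]}
        )
        out = aggregate_nuclei_by_sample(feats, meta)
        assert len(out) == 1
        assert out["eccentricity"].iloc[0] == pytest.approx(0.7)
        assert out["n_nuclei"].iloc[0] == 4

    def test_per_image_then_per_sample_averaging(self):
        # unequal nuclei counts: image means first, then their mean
        feats = pd.DataFrame(
            {
                "image_id": ["i1", "i1", "i1", "i2"],
                "nucleus_id": [1, 2, 3, 1],
                "eccentricity": [0.6, 0.6, 0.6, 0.8],
            }
        )
        meta = pd.DataFrame({"image_id": ["i1", "i2"], "sample_id": ["s1", "s1"]})
        out = aggregate_nuclei_by_sample(feats, meta)
        assert out["eccentricity"].iloc[0] == pytest.approx(0.7)

    def test_sample_without_nuclei_dropped_with_warning(self):
        feats = pd.DataFrame(
            {"image_id": ["i1"], "nucleus_id": [1], "eccentricity": [0.5]}
        )
        meta = pd.DataFrame(
            {"image_id": ["i1", "i2"], "sample_id": ["s1", "s2"]}
        )
        with pytest.warns(UserWarning, match="zero nuclei"):
            out = aggregate_nuclei_by_sample(feats, meta)
        assert list(out["sample_id"]) == ["s1"]

    def test_cohort_sample_means_near_truth(self, tiny_cohort):
        import pandas as pd
        from pathlib import Path
        from cartimorph.io import read_image

        meta = pd.read_csv(tiny_cohort["metadata"])
        truth = pd.read_csv(tiny_cohort["truth_nuclei"])
        root = Path(tiny_cohort["out_dir"])
        frames = []
        for rec in meta.to_dict("records"):
            img = read_image(root / rec["dapi_path"])
            lab = segment_nuclei(img, 50, 5000, rec["image_id"])
            frames.append(measure_features(lab))
        feats = pd.concat(frames, ignore_index=True)
        per_sample = aggregate_nuclei_by_sample(feats, meta)
        truth_means = truth.groupby("sample_id")["eccentricity"].agg(["mean", "std", "size"])
        merged = per_sample.merge(truth_means, on="sample_id")
        se = merged["std"] / np.sqrt(merged["size"])
        # rasterization adds ~0.01 absolute; stay within 2 SE + that
        assert (np.abs(merged["eccentricity"] - merged["mean"]) <= 2 * se + 0.015).all()
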
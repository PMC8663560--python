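"""Shape/voxel normalization, outlier removal, label scaling, splitting."""

import numpy as np
import pandas as pd
import pytest

from adiposcan.config import LabelModelConfig
from adiposcan.preprocess import (
    DegenerateVolumeError,
    NormalizedVolume,
    body_voxel_stats,
    denormalize_mae,
    normalize_labels,
    normalize_shape,
    normalize_voxels,
    remove_outliers,
    stratified_split,
)
from adiposcan.synthgen import BodyVolume, generate_labels


def _full_body_volume(shape, value=2.0):
    vox = np.full(shape, value, dtype=np.float32)
    mask = np.ones(shape, dtype=bool)
    return BodyVolume(voxels=vox, body_mask=mask, region_masks={})


class TestNormalizeShape:
    @pytest.mark.parametrize("slices", [90, 104, 120])
    def test_vertical_interpolation_to_target(self, slices, tiny_profile):
        vol = _full_body_volume((slices, *tiny_profile.raw_inplane))
        out = normalize_shape(vol, tiny_profile.target_dims, final_dims=None)
        assert out.voxels.shape == tiny_profile.target_dims

    def test_final_downsampling(self, base_phantom, tiny_profile):
        out = normalize_shape(base_phantom, tiny_profile.target_dims, tiny_profile.final_dims)
        assert out.voxels.shape == tiny_profile.final_dims
        assert np.all(out.voxels[~out.body_mask] == 0)

    def test_identity_at_target_dims(self):
        vol = _full_body_volume((24, 22, 37))
        out = normalize_shape(vol, (24, 22, 37), final_dims=(24, 22, 37))
        assert np.allclose(out.voxels, vol.voxels, atol=1e-5)

    def test_constant_body_stays_constant(self):
        vol = _full_body_volume((101, 22, 37), value=3.5)
        out = normalize_shape(vol, (24, 22, 37), final_dims=None)
        assert np.allclose(out.voxels[out.body_mask], 3.5, atol=1e-5)

    def test_idempotent_fixed_point(self, base_phantom, tiny_profile):
        once = normalize_shape(base_phantom, tiny_profile.target_dims, tiny_profile.final_dims)
        twice = normalize_shape(
            BodyVolume(once.voxels, once.body_mask, once.region_masks),
            tiny_profile.final_dims,
            tiny_profile.final_dims,
        )
        assert np.allclose(once.voxels, twice.voxels, atol=1e-5)

    def test_region_masks_stay_disjoint(self, base_phantom, tiny_profile):
        out = normalize_shape(base_phantom, tiny_profile.target_dims, tiny_profile.final_dims)
        union = np.zeros(out.voxels.shape, dtype=int)
        for m in out.region_masks.values():
            union += m.astype(int)
            assert np.all(out.body_mask[m])
        assert union.max() <= 1

    def test_rejects_bad_dims(self, base_phantom):
        with pytest.raises(ValueError):
            normalize_shape(base_phantom, (0, 10, 10))

    def test_rejects_single_slice(self):
        vol = _full_body_volume((1, 8, 8))
        with pytest.raises(ValueError):
            normalize_shape(vol, (10, 8, 8))


class TestNormalizeVoxels:
    def test_standardization_and_positivity(self, base_phantom, tiny_profile):
        nv = normalize_shape(base_phantom, tiny_profile.target_dims, tiny_profile.final_dims)
        out = normalize_voxels(nv)
        body = out.body_mask
        # SD of the standardization step (before truncation/shift) is exactly 1
        pre = (nv.voxels[body] - out.params["mean"]) / out.params["sd"]
        assert abs(pre.std() - 1.0) < 1e-6
        assert abs(pre.mean()) < 1e-6
        assert out.voxels[body].min() > 0
        assert np.all(out.voxels[~body] == 0)

    def test_shared_transform_is_deterministic(self, base_phantom, tiny_profile):
        nv = normalize_shape(base_phantom, tiny_profile.target_dims, tiny_profile.final_dims)
        stats = body_voxel_stats([nv])
        a = normalize_voxels(nv, stats_source=stats)
        b = normalize_voxels(nv, stats_source=stats)
        assert np.array_equal(a.voxels, b.voxels)

    def test_zero_variance_rejected(self):
        nv = NormalizedVolume(np.full((4, 4, 4), 2.0, dtype=np.float32), np.ones((4, 4, 4), bool))
        with pytest.raises(DegenerateVolumeError):
            normalize_voxels(nv)

    def test_histogram_background_identification(self, rng):
        vox = np.zeros((10, 10, 10), dtype=np.float32)
        vox[2:8, 2:8, 2:8] = rng.normal(1.0, 0.1, (6, 6, 6)).astype(np.float32)
        nv = NormalizedVolume(vox, None)
        out = normalize_voxels(nv, use_provided_mask=False)
        assert out.body_mask.sum() == 6 * 6 * 6


class TestLabels:
    def test_minmax_definition(self):
        tab = pd.DataFrame({"age": [20.0, 40.0, 60.0]})
        out, tf, obs = normalize_labels(tab, continuous=("age",))
        assert np.allclose(out["age"], [0.0, 0.5, 1.0])
        assert tf["age"] == (20.0, 60.0)

    def test_denormalized_mae_roundtrip(self):
        assert denormalize_mae(0.07, (18.0, 48.0)) == pytest.approx(2.1)
        assert denormalize_mae(0.0, (0.0, 100.0)) == 0.0

    def test_missing_value_masked_not_dropped(self):
        tab = pd.DataFrame({"age": [20.0, np.nan, 60.0], "bmi": [20.0, 25.0, 30.0]})
        out, tf, obs = normalize_labels(tab, continuous=("age", "bmi"))
        assert not obs.loc[1, "age"]
        assert obs.loc[1, "bmi"]
        assert np.isnan(out.loc[1, "age"])
        assert out.loc[1, "bmi"] == pytest.approx(0.5)

    def test_train_fold_extrema_used(self):
        tab = pd.DataFrame({"age": [20.0, 40.0, 60.0, 80.0]})
        train = np.array([True, True, True, False])
        out, tf, _ = normalize_labels(tab, continuous=("age",), train_mask=train)
        assert tf["age"] == (20.0, 60.0)
        assert out["age"].iloc[3] == pytest.approx(1.5)  # outside the train range

    def test_constant_column_rejected(self):
        tab = pd.DataFrame({"age": [30.0, 30.0, 30.0]})
        with pytest.raises(ValueError):
            normalize_labels(tab, continuous=("age",))


def _mc_isolation_depths(X, n_trees=400, seed=0):
    """Monte-Carlo expected isolation depth: an independent reference for
    anomaly ranking on tiny tables (shorter depth = more anomalous)."""
    rng = np.random.default_rng(seed)
    n, p = X.shape
    depths = np.zeros(n)

    def grow(idx, depth):
        if len(idx) <= 1:
            for i in idx:
                depths[i] += depth
            return
        f = rng.integers(p)
        vals = X[idx, f]
        lo, hi = vals.min(), vals.max()
        if lo == hi:
            for i in idx:
                depths[i] += depth
            return
        cut = rng.uniform(lo, hi)
        grow(idx[vals < cut], depth + 1)
        grow(idx[vals >= cut], depth + 1)

    for _ in range(n_trees):
        grow(np.arange(n), 0)
    return depths / n_trees


class TestOutliers:
    def test_extreme_row_flagged(self, rng):
        n = 40
        tab = pd.DataFrame(
            {
                "insulin_sensitivity": np.r_[rng.normal(12, 1.5, n), 900.0],
                "bmi": np.r_[rng.normal(27, 2, n), 27.0],
                "hba1c": np.r_[rng.normal(5.5, 0.2, n), 5.5],
                "total_adipose_volume": np.r_[rng.normal(30, 3, n), 30.0],
            }
        )
        keep = remove_outliers(tab, contamination=0.03, seed=1)
        assert not keep[n]
        assert keep[:n].sum() >= n - 2

    def test_ranking_matches_isolation_depth_reference(self, rng):
        X = np.c_[rng.normal(0, 1, 7), rng.normal(0, 1, 7)]
        X = np.vstack([X, [40.0, -35.0]])  # far outlier among 8 points
        depths = _mc_isolation_depths(X, seed=3)
        assert np.argmin(depths) == 7  # reference isolates the planted point fastest
        tab = pd.DataFrame(
            {
                "insulin_sensitivity": X[:, 0],
                "bmi": X[:, 1],
                "hba1c": np.full(8, 5.5),
                "total_adipose_volume": np.full(8, 30.0),
            }
        )
        keep = remove_outliers(tab, contamination=0.13, seed=0)
        assert not keep[7]

    def test_contamination_zero_keeps_all(self):
        tab = pd.DataFrame(
            {c: np.arange(5.0) for c in ("insulin_sensitivity", "bmi", "hba1c", "total_adipose_volume")}
        )
        assert remove_outliers(tab, contamination=0.0).all()

    def test_missing_column_rejected(self):
        with pytest.raises(ValueError):
            remove_outliers(pd.DataFrame({"bmi": [1.0, 2.0]}))


class TestSplit:
    @pytest.fixture(scope="class")
    def labels(self):
        return generate_labels(1000, LabelModelConfig(), seed=0)

    def test_fold_sizes_exact(self, labels):
        sp = stratified_split(labels, seed=1)
        counts = sp["fold"].value_counts()
        assert counts["train"] == 700 and counts["validation"] == 150 and counts["test"] == 150

    def test_per_stratum_within_one_sample(self, labels):
        sp = stratified_split(labels, seed=1)
        for _, grp in sp.groupby("stratum"):
            ns = len(grp)
            assert ns >= 2  # every multivariate stratum has more than one sample
            for fold, frac in zip(("train", "validation", "test"), (0.70, 0.15, 0.15)):
                assert abs((grp["fold"] == fold).sum() - ns * frac) <= 1 + 1e-9

    def test_deterministic_and_size_invariant_across_seeds(self, labels):
        a = stratified_split(labels, seed=5)
        b = stratified_split(labels, seed=5)
        c = stratified_split(labels, seed=6)
        assert a["fold"].equals(b["fold"])
        assert not a["fold"].equals(c["fold"])
        assert a["fold"].value_counts().to_dict() == c["fold"].value_counts().to_dict()

    def test_single_stratum_still_honors_fractions(self):
        tab = pd.DataFrame(
            {"bmi": np.full(100, 25.0), "insulin_sensitivity": np.full(100, 10.0), "diabetes": np.zeros(100, int)}
        )
        sp = stratified_split(tab, seed=2)
        counts = sp["fold"].value_counts()
        assert counts["train"] == 70 and counts["validation"] == 15 and counts["test"] == 15

    def test_bad_fractions_rejected(self, labels):
        with pytest.raises(ValueError):
            stratified_split(labels, fractions=(0.8, 0.15, 0.15))
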
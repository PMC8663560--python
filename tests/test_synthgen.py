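"""Phantom generator and label model: determinism, monotone couplings,
diagnosis thresholds."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from adiposcan.config import DiagnosisThresholds, LabelModelConfig
from adiposcan.synthgen import (
    assign_diagnosis,
    assign_microalbuminuria,
    generate_embedding_mixture,
    generate_labels,
    generate_phantom,
    spec_from_row,
)


class TestDiagnosis:
    @pytest.mark.parametrize(
        "fasting,g2h,hba1c,expected",
        [
            (7.2, 8.0, 40, (1, 0, 1)),   # fasting criterion, strict >
            (7.0, 8.0, 40, (0, 1, 0)),   # exactly 7.0 is not diabetic; 8.0 at 2h is IGT
            (5.0, 12.0, 40, (1, 0, 1)),  # 2h criterion, inclusive >=
            (5.0, 8.0, 48, (1, 0, 1)),   # HbA1c criterion, inclusive >=
            (4.8, 6.5, 30, (0, 0, 0)),   # below every threshold
            (6.0, 6.5, 30, (0, 1, 0)),   # isolated IFG -> prediabetes
            (5.0, 8.5, 30, (0, 1, 0)),   # isolated IGT -> prediabetes
            (6.0, 8.5, 30, (0, 1, 1)),   # IFG + IGT extends the third label
        ],
    )
    def test_threshold_logic(self, fasting, g2h, hba1c, expected):
        assert assign_diagnosis(fasting, g2h, hba1c) == expected

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            assign_diagnosis(-1.0, 8.0, 40)

    def test_closure_against_brute_force(self):
        """Exhaustive grid check against an independent threshold re-implementation."""
        t = DiagnosisThresholds()
        fasting = np.arange(3.0, 9.0, 0.1)
        g2h = np.arange(3.0, 13.0, 0.25)
        hba1c = np.array([30.0, 47.9, 48.0, 55.0])
        for f in fasting:
            for g in g2h:
                for h in hba1c:
                    da, db, dg = assign_diagnosis(f, g, h)
                    # brute-force reference, written straight from the rules
                    ref_da = int(f > 7.0 or g >= 11.1 or h >= 48.0)
                    ref_ifg = int(5.6 <= f <= 6.9)
                    ref_igt = int(7.8 <= g <= 11.0)
                    ref_db = int(not ref_da and (ref_ifg or ref_igt))
                    ref_dg = int(ref_da or (ref_ifg and ref_igt))
                    assert (da, db, dg) == (ref_da, ref_db, ref_dg)
                    assert not (da and db)  # diabetes excludes prediabetes
                    assert dg >= da  # extended label contains diabetes
        assert t.fasting_diabetes == 7.0

    @pytest.mark.parametrize("uacr,expected", [(30.0, 1), (29.9, 0), (0.0, 0), (250.0, 1)])
    def test_microalbuminuria(self, uacr, expected):
        assert assign_microalbuminuria(uacr) == expected

    def test_microalbuminuria_negative_rejected(self):
        with pytest.raises(ValueError):
            assign_microalbuminuria(-0.1)


class TestPhantom:
    def test_seeded_determinism(self, base_spec, tiny_profile):
        a = generate_phantom(base_spec, tiny_profile)
        b = generate_phantom(base_spec, tiny_profile)
        assert np.array_equal(a.voxels, b.voxels)
        assert np.array_equal(a.body_mask, b.body_mask)

    def test_invariants(self, base_phantom):
        base_phantom.check_invariants()
        total = sum(int(m.sum()) for m in base_phantom.region_masks.values())
        assert total <= int(base_phantom.body_mask.sum())

    def test_bmi_scales_girth(self, base_spec, tiny_profile):
        lo = dataclasses.replace(base_spec, bmi=25.0)
        hi = dataclasses.replace(base_spec, bmi=35.0)
        assert generate_phantom(hi, tiny_profile).body_mask.sum() > generate_phantom(lo, tiny_profile).body_mask.sum()

    def test_depot_fraction_monotone_intensity(self, base_spec, tiny_profile):
        means = []
        for frac in (0.2, 0.5, 0.8):
            spec = dataclasses.replace(
                base_spec, depot_fractions={**base_spec.depot_fractions, "visceral_lower": frac}
            )
            vol = generate_phantom(spec, tiny_profile)
            means.append(vol.voxels[vol.region_masks["visceral_lower"]].mean())
        assert means[0] < means[1] < means[2]

    def test_sex_morphology(self, base_spec, tiny_profile):
        female = generate_phantom(dataclasses.replace(base_spec, sex=1, seed=3), tiny_profile)
        male = generate_phantom(dataclasses.replace(base_spec, sex=0, seed=3), tiny_profile)
        assert not np.array_equal(female.body_mask, male.body_mask)

    def test_slice_count_rejected(self, base_spec, tiny_profile):
        with pytest.raises(ValueError):
            generate_phantom(dataclasses.replace(base_spec, slice_count=130), tiny_profile)
        with pytest.raises(ValueError):
            generate_phantom(dataclasses.replace(base_spec, slice_count=89), tiny_profile)

    def test_bad_fraction_rejected(self, base_spec, tiny_profile):
        spec = dataclasses.replace(
            base_spec, depot_fractions={**base_spec.depot_fractions, "thigh": 1.2}
        )
        with pytest.raises(ValueError):
            generate_phantom(spec, tiny_profile)


class TestCohortLabels:
    def test_determinism(self):
        a = generate_labels(50, LabelModelConfig(), seed=5)
        b = generate_labels(50, LabelModelConfig(), seed=5)
        assert a.equals(b)

    def test_n_below_one_rejected(self):
        with pytest.raises(ValueError):
            generate_labels(0, LabelModelConfig(), seed=0)

    def test_prevalence_within_binomial_interval(self):
        cfg = LabelModelConfig()
        labels = generate_labels(200, cfg, seed=123)
        k = int(labels["diabetes"].sum())
        lo, hi = stats.binom.interval(0.999, 200, cfg.prevalence_diabetes)
        assert lo <= k <= hi

    def test_diagnosis_labels_consistent_with_glycemia(self):
        labels = generate_labels(300, LabelModelConfig(), seed=9)
        da, db, dg = assign_diagnosis(
            labels["fasting_glucose"], labels["glucose_2h"], labels["hba1c_mmolmol"]
        )
        assert np.array_equal(da, labels["diabetes"].to_numpy())
        assert np.array_equal(db, labels["prediabetes"].to_numpy())
        assert np.array_equal(dg, labels["diabetes_ext"].to_numpy())

    def test_noiseless_glycemia_is_deterministic_in_depots(self):
        cfg = LabelModelConfig(
            is_noise_sd=0.0, fasting_noise_sd=0.0, g2h_noise_sd=0.0, hba1c_noise_sd=0.0,
            fasting_dm_spread=0.0, g2h_dm_spread=0.0, hba1c_dm_spread_pct=0.0,
        )
        lab = generate_labels(150, cfg, seed=2)
        neg = lab[lab["diabetes"] == 0]
        ins = np.clip(
            cfg.is_base
            - cfg.is_visc_slope * neg["frac_visceral_lower"]
            - cfg.is_thigh_slope * neg["frac_thigh"],
            cfg.is_floor,
            None,
        )
        deficit = np.clip(cfg.is_base - ins, 0, None)
        fasting = np.clip(cfg.fasting_base + cfg.fasting_is_slope * deficit, 3.8, 6.9)
        assert np.allclose(neg["fasting_glucose"], fasting)

    def test_visceral_insulin_coupling_negative(self):
        labels = generate_labels(250, LabelModelConfig(), seed=21)
        rho = stats.spearmanr(labels["frac_visceral_lower"], labels["insulin_sensitivity"]).statistic
        assert rho < -0.3

    def test_pattern_mode_matches_visceral_totals(self):
        lab = generate_labels(400, LabelModelConfig(signal="pattern"), seed=4)
        both = lab["frac_visceral_lower"] + lab["frac_visceral_upper"]
        dm, nd = both[lab.diabetes == 1], both[lab.diabetes == 0]
        # combined visceral load indistinguishable between groups
        assert abs(dm.mean() - nd.mean()) < 0.04

    def test_followup_invariants(self, small_cohort):
        _, labels, fu = small_cohort
        assert (fu["time_to_diabetes"] >= 0).all()
        assert set(fu["diabetes_event"].unique()) <= {0, 1}
        assert (fu["time_to_diabetes"] <= 10.0 + 1e-9).all()
        assert (fu["baseline_uacr"] > 0).all()

    def test_spec_from_row_roundtrip(self, small_cohort, tiny_profile):
        _, labels, _ = small_cohort
        spec = spec_from_row(labels.iloc[0])
        vol = generate_phantom(spec, tiny_profile)
        vol.check_invariants()


class TestEmbeddingMixture:
    def test_shape_and_determinism(self):
        X1, z1 = generate_embedding_mixture(100, seed=8)
        X2, z2 = generate_embedding_mixture(100, seed=8)
        assert X1.shape == (100, 128)
        assert np.array_equal(X1, X2) and np.array_equal(z1, z2)

    def test_components_well_separated(self):
        X, z = generate_embedding_mixture(200, seed=8)
        centroids = np.stack([X[z == c].mean(axis=0) for c in range(4)])
        between = min(
            np.linalg.norm(centroids[i] - centroids[j])
            for i in range(4)
            for j in range(i + 1, 4)
        )
        within = np.mean([np.linalg.norm(X[z == c] - centroids[c], axis=1).mean() for c in range(4)])
        assert between > 2 * within

    @given(st.integers(min_value=4, max_value=64))
    @settings(max_examples=10, deadline=None, derandomize=True)
    def test_any_size_draws(self, n):
        X, z = generate_embedding_mixture(n, seed=1)
        assert X.shape[0] == n and z.shape[0] == n
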
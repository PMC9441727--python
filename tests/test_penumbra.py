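"""Contrast coding, mixed models, penumbra rule, and risk regressions."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from fwpenumbra.penumbra import (
    detect_penumbra,
    fit_risk_models,
    fit_roi_lmm,
    forward_difference_matrix,
    penumbra_mean,
    quartile_comparison,
)
from fwpenumbra.regions import REGION_NAMES, contrast_names
from fwpenumbra.synthcohort import CohortSpec, simulate_cohort_rois

NULL_EFFECTS = dict.fromkeys(
    ["age", "female", "log_wmh_load", "smoking", "diabetes", "hypertension"], 0.0
)


def _contrast_table(pvals):
    names = contrast_names(REGION_NAMES)[: len(pvals)]
    return pd.DataFrame(
        {"name": names, "estimate": 0.1, "se": 0.01, "pvalue": list(pvals)}
    )


class TestForwardDifferenceMatrix:
    def test_three_levels_balanced_means(self):
        """Cell means (5, 3, 3) in a balanced design give contrasts (2, 0)."""
        x = forward_difference_matrix(3)
        means = np.array([5.0, 3.0, 3.0])
        reps = 4
        design = np.column_stack([np.ones(3 * reps), np.repeat(x, reps, axis=0)])
        y = np.repeat(means, reps)
        beta, *_ = np.linalg.lstsq(design, y, rcond=None)
        assert np.allclose(beta[1:], [2.0, 0.0], atol=1e-12)

    def test_two_levels_is_difference_of_means(self):
        x = forward_difference_matrix(2)
        design = np.column_stack([np.ones(2), x])
        beta = np.linalg.solve(design, np.array([7.0, 3.0]))
        assert beta[1] == pytest.approx(4.0)

    def test_nine_levels_gives_eight_contrasts(self):
        assert forward_difference_matrix(9).shape == (9, 8)

    @pytest.mark.parametrize("k", range(2, 10))
    def test_matches_bruteforce_cell_mean_differences(self, k):
        """Least squares on a balanced design must reproduce adjacent
        cell-mean differences to 1e-10 for every k up to 9."""
        rng = np.random.default_rng(40 + k)
        means = rng.normal(0.0, 1.0, k)
        x = forward_difference_matrix(k)
        reps = 3
        design = np.column_stack([np.ones(k * reps), np.repeat(x, reps, axis=0)])
        y = np.repeat(means, reps)
        beta, *_ = np.linalg.lstsq(design, y, rcond=None)
        assert np.allclose(beta[1:], -np.diff(means), atol=1e-10)
        assert beta[0] == pytest.approx(means.mean(), abs=1e-10)

    def test_single_level_rejected(self):
        with pytest.raises(ValueError):
            forward_difference_matrix(1)


class TestFitRoiLmm:
    def test_near_zero_noise_recovers_constructed_differences(self):
        offsets = (0.37, 0.20, 0.13, 0.11, 0.10, 0.10, 0.10, 0.10, 0.10)
        spec = CohortSpec(
            n_subjects=40,
            fw_profile=offsets,
            fw_effects=NULL_EFFECTS,
            fat_effects=NULL_EFFECTS,
            between_sd=1e-9,
            residual_sd=1e-9,
            seed=5,
        )
        t = simulate_cohort_rois(spec)
        res = fit_roi_lmm(t, "fw")
        assert np.allclose(
            res.contrasts["estimate"].to_numpy(), -np.diff(np.asarray(offsets)), atol=1e-6
        )

    def test_zero_between_subject_sd_matches_ols(self):
        spec = CohortSpec(n_subjects=60, between_sd=0.0, residual_sd=0.02, seed=8)
        t = simulate_cohort_rois(spec)
        res = fit_roi_lmm(t, "fw")
        # independent OLS on the identical design
        from fwpenumbra.penumbra import _roi_design

        exog, names, _ = _roi_design(t, ("age", "female", "log_wmh_load"))
        ols = sm.OLS(t["fw"].to_numpy(), exog).fit()
        assert np.allclose(
            res.contrasts["estimate"].to_numpy(), ols.params[1:9], atol=1e-6
        )

    def test_age_effect_recovered_within_two_se(self):
        effects = dict(NULL_EFFECTS, age=0.008)
        profile = tuple(v + 0.25 for v in (0.37, 0.20, 0.13, 0.11, 0.10, 0.10, 0.10, 0.10, 0.10))
        spec = CohortSpec(
            n_subjects=200, fw_profile=profile, fw_effects=effects, seed=14
        )
        t = simulate_cohort_rois(spec)
        res = fit_roi_lmm(t, "fw")
        age = res.covariates.set_index("name").loc["age"]
        assert abs(age["estimate"] - 0.008) < 2 * age["se"]

    def test_too_few_subjects_rejected(self):
        t = simulate_cohort_rois(CohortSpec(n_subjects=1, seed=0))
        with pytest.raises(ValueError):
            fit_roi_lmm(t, "fw")


class TestDetectPenumbra:
    def test_published_fw_pattern_gives_8mm(self):
        """The FW p column (8-10 mm significant at .017, 10-12 mm not)
        delimits a 4-rim / 8 mm penumbra."""
        res = detect_penumbra(
            _contrast_table([1e-4, 1e-4, 1e-4, 1e-4, 0.017, 0.932, 0.154, 0.180])
        )
        assert res.extent_mm == 8
        assert res.member_rims == ["2mm", "4mm", "6mm", "8mm"]

    def test_published_fat_pattern_gives_12mm(self):
        """FA-t significant through 12-14 mm but not 14-16 mm: 12 mm extent."""
        res = detect_penumbra(
            _contrast_table([1e-4, 1e-4, 1e-4, 1e-4, 1e-4, 1e-4, 0.003, 0.141]),
            outcome="fa_t",
        )
        assert res.extent_mm == 12

    def test_nothing_significant_gives_zero(self):
        assert detect_penumbra(_contrast_table([0.5] * 8)).extent_mm == 0

    def test_everything_significant_gives_full_band(self):
        assert detect_penumbra(_contrast_table([1e-4] * 8)).extent_mm == 16

    def test_monotone_in_alpha(self):
        rng = np.random.default_rng(33)
        for _ in range(50):
            tab = _contrast_table(rng.random(8))
            extents = [
                detect_penumbra(tab, alpha=a).extent_mm for a in (0.2, 0.1, 0.05, 0.01)
            ]
            assert all(a >= b for a, b in zip(extents, extents[1:]))

    def test_unordered_contrasts_rejected(self):
        tab = _contrast_table([0.01] * 8).iloc[::-1].reset_index(drop=True)
        with pytest.raises(ValueError):
            detect_penumbra(tab)

    def test_inner_rule_counts_plain_prefix(self):
        tab = _contrast_table([1e-4, 1e-4, 1e-4, 1e-4, 0.017, 0.932, 0.154, 0.180])
        assert detect_penumbra(tab, rule="inner").extent_mm == 10


class TestRiskModels:
    @staticmethod
    def _subject_table(spec):
        t = simulate_cohort_rois(spec)
        subj = t[t["roi"] == "WMH"].copy()
        pen = penumbra_mean(t, ["2mm", "4mm", "6mm", "8mm"], outcome="fw")
        subj = subj.set_index("subject")
        subj["fw_penumbra"] = pen
        return subj.reset_index()

    def test_zero_noise_coefficients_exact(self):
        effects = dict(NULL_EFFECTS, smoking=0.006, age=0.001)
        spec = CohortSpec(
            n_subjects=120,
            fw_effects=effects,
            between_sd=0.0,
            residual_sd=0.0,
            seed=6,
        )
        tab = self._subject_table(spec)
        res = fit_risk_models(tab, "fw_penumbra").set_index("name")
        assert res.loc["smoking", "estimate"] == pytest.approx(0.006, abs=1e-10)
        assert res.loc["age", "estimate"] == pytest.approx(0.001, abs=1e-10)
        assert res.loc["diabetes", "estimate"] == pytest.approx(0.0, abs=1e-10)

    def test_smoking_effect_recovered_within_two_se(self):
        effects = dict(NULL_EFFECTS, smoking=0.006)
        spec = CohortSpec(n_subjects=300, fw_effects=effects, seed=7)
        tab = self._subject_table(spec)
        res = fit_risk_models(tab, "fw_penumbra").set_index("name")
        assert abs(res.loc["smoking", "estimate"] - 0.006) < 2 * res.loc["smoking", "se"]

    def test_null_smoking_coefficient_near_zero(self):
        spec = CohortSpec(n_subjects=400, fw_effects=NULL_EFFECTS, seed=9)
        tab = self._subject_table(spec)
        res = fit_risk_models(tab, "fw_penumbra").set_index("name")
        assert abs(res.loc["smoking", "estimate"]) < 3 * res.loc["smoking", "se"]

    def test_permuted_smoking_ci_covers_zero(self):
        """With smoking labels permuted, the 95% CI covers zero in at least
        94 of 100 seeded permutations."""
        effects = dict(NULL_EFFECTS, smoking=0.006)
        spec = CohortSpec(n_subjects=200, fw_effects=effects, seed=11)
        tab = self._subject_table(spec)
        rng = np.random.default_rng(55)
        covered = 0
        for _ in range(100):
            perm = tab.copy()
            perm["smoking"] = rng.permutation(perm["smoking"].to_numpy())
            res = fit_risk_models(perm, "fw_penumbra").set_index("name")
            est, se = res.loc["smoking", "estimate"], res.loc["smoking", "se"]
            if abs(est) <= 1.96 * se:
                covered += 1
        assert covered >= 94

    def test_collinear_covariates_rejected(self):
        spec = CohortSpec(n_subjects=50, seed=3)
        tab = self._subject_table(spec)
        tab["diabetes"] = tab["smoking"]
        with pytest.raises(ValueError, match="condition"):
            fit_risk_models(tab, "fw_penumbra")


class TestQuartileComparison:
    def test_equal_extent_groups_detect_same_extent(self):
        spec = CohortSpec(n_subjects=240, seed=19)
        t = simulate_cohort_rois(spec)
        out = quartile_comparison(t)
        assert out["q1"]["extent_mm"] == out["q4"]["extent_mm"]
        assert out["same_extent"]

    def test_identical_groups_identical_profiles(self):
        t = simulate_cohort_rois(CohortSpec(n_subjects=40, seed=21))
        t = t.copy()
        t["wmh_volume_ml"] = 1.0  # all tied: split by stable subject order
        out = quartile_comparison(t)
        q = 10
        lo = set(range(q))
        hi = set(range(30, 40))
        prof_lo = t[t["subject"].isin(lo)].groupby("roi", observed=True)["fw"].mean()
        assert np.allclose(out["q1"]["profile"].to_numpy(), prof_lo.to_numpy())

    def test_too_few_subjects_rejected(self):
        t = simulate_cohort_rois(CohortSpec(n_subjects=7, seed=1))
        with pytest.raises(ValueError):
            quartile_comparison(t)
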
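import numpy as np
import pytest

from cbfcovnet import (
    GenerativeModel,
    GroupEffectSpec,
    apply_group_effect,
    modular_model,
    sample_cohort,
    sample_null_pair,
)
from cbfcovnet.synthetic import ModelValidationError


def offdiag(mat):
    return mat[~np.eye(mat.shape[0], dtype=bool)]


def within_between_masks(assignment):
    same = assignment[:, None] == assignment[None, :]
    eye = np.eye(len(assignment), dtype=bool)
    return same & ~eye, ~same


class TestSampling:
    def test_same_seed_bit_identical(self, default_model):
        a = sample_cohort(default_model, 20, seed=42)
        b = sample_cohort(default_model, 20, seed=42)
        assert np.array_equal(a.values, b.values)
        assert np.array_equal(a.age, b.age)
        assert np.array_equal(a.gender, b.gender)

    def test_different_seeds_differ(self, default_model):
        a = sample_cohort(default_model, 20, seed=42)
        b = sample_cohort(default_model, 20, seed=43)
        assert not np.array_equal(a.values, b.values)

    def test_independence_case_near_zero_correlations(self):
        model = modular_model(n_regions=20, n_modules=2, within_module_r=0.0,
                              between_module_r=0.0, hubs_per_module=0,
                              age_slope=0.0, gender_effect=0.0)
        cohort = sample_cohort(model, 500, seed=1)
        r = np.corrcoef(cohort.values, rowvar=False)
        assert np.max(np.abs(offdiag(r))) < 0.15

    def test_single_module_target_correlation(self):
        model = modular_model(n_regions=12, n_modules=1, within_module_r=0.6,
                              between_module_r=0.0, age_slope=0.0,
                              gender_effect=0.0)
        cohort = sample_cohort(model, 2000, seed=2)
        r = np.corrcoef(cohort.values, rowvar=False)
        assert abs(offdiag(r).mean() - 0.6) < 0.05

    def test_ages_and_gender_within_configured_ranges(self, default_model):
        cohort = sample_cohort(default_model, 300, seed=3)
        assert cohort.age.min() >= 18 and cohort.age.max() <= 55
        assert set(np.unique(cohort.gender)) <= {0.0, 1.0}

    def test_too_few_subjects_rejected(self, default_model):
        with pytest.raises(ValueError):
            sample_cohort(default_model, 2, seed=0)


class TestImpliedCorrelation:
    def test_block_structure_values_without_hubs(self):
        model = modular_model(within_module_r=0.5, hubs_per_module=0)
        r = model.implied_correlation()
        within, between = within_between_masks(model.module_assignment)
        assert r[within] == pytest.approx(0.5)
        assert r[between] == pytest.approx(0.1)
        r3 = modular_model().implied_correlation()  # default contrast 0.3/0.1
        assert r3[within] == pytest.approx(0.3)
        assert r3[between] == pytest.approx(0.1)
        assert np.diag(r) == pytest.approx(np.ones(90))

    def test_hub_regions_carry_stronger_long_range_coupling(self):
        model = modular_model(within_module_r=0.5, hubs_per_module=1,
                              hub_between_r=0.3)
        r = model.implied_correlation()
        assignment = model.module_assignment
        hubs = np.nonzero(model.global_loading ** 2 > 0.15)[0]
        assert len(hubs) == 6  # one per module by default
        h0, h1 = hubs[0], hubs[1]
        assert assignment[h0] != assignment[h1]
        assert r[h0, h1] == pytest.approx(0.3)
        non_hub = [i for i in range(90)
                   if assignment[i] == assignment[h1] and i not in hubs][0]
        assert r[h0, non_hub] > 0.1  # hub-to-regular exceeds the background
        regular = [i for i in range(90)
                   if assignment[i] != assignment[non_hub] and i not in hubs][0]
        assert r[non_hub, regular] == pytest.approx(0.1)

    def test_implied_matrix_is_psd(self, default_model):
        ev = np.linalg.eigvalsh(default_model.implied_correlation())
        assert ev.min() >= -1e-10

    def test_sample_correlation_converges_with_n(self, default_model):
        implied = default_model.implied_correlation()
        errs = []
        for n in (100, 1000, 5000):
            cohort = sample_cohort(default_model, n, seed=4)
            from cbfcovnet import residualize_covariates
            r = np.corrcoef(residualize_covariates(cohort), rowvar=False)
            errs.append(np.median(np.abs(offdiag(r) - offdiag(implied))))
        assert errs[0] > errs[1] > errs[2]

    def test_overlarge_between_target_rejected_with_block_named(self):
        with pytest.raises(ModelValidationError, match="module 0"):
            modular_model(n_modules=6, within_module_r=0.1, between_module_r=0.5,
                          hubs_per_module=0)

    def test_out_of_range_within_rejected(self):
        with pytest.raises(ModelValidationError):
            modular_model(within_module_r=1.2).implied_correlation()


class TestCovariateEffects:
    def test_planted_slopes_recovered_by_regression(self):
        # independent regions so the per-region OLS standard error applies;
        # 3 SE keeps the joint check over 20 estimates stable
        model = modular_model(n_regions=10, n_modules=2, within_module_r=0.0,
                              between_module_r=0.0, hubs_per_module=0,
                              age_slope=-0.3, gender_effect=4.0)
        cohort = sample_cohort(model, 500, seed=5)
        x = np.column_stack([np.ones(500), cohort.age, cohort.gender])
        beta, res_ss, *_ = np.linalg.lstsq(x, cohort.values, rcond=None)
        xtx_inv = np.linalg.inv(x.T @ x)
        dof = 500 - 3
        for j in range(10):
            sigma2 = res_ss[j] / dof
            se_age = np.sqrt(sigma2 * xtx_inv[1, 1])
            se_gen = np.sqrt(sigma2 * xtx_inv[2, 2])
            assert abs(beta[1, j] - (-0.3)) < 3 * se_age
            assert abs(beta[2, j] - 4.0) < 3 * se_gen


class TestGroupEffect:
    def test_identity_effect_returns_equal_model(self, default_model):
        out = apply_group_effect(default_model, GroupEffectSpec())
        assert out.equals(default_model)

    def test_delta_arithmetic_on_targets(self):
        model = modular_model(within_module_r=0.6)
        eff = GroupEffectSpec(affected_modules=tuple(range(6)),
                              within_module_r_delta=-0.3)
        out = apply_group_effect(model, eff)
        assert out.within_module_r == pytest.approx(np.full(6, 0.3))

    def test_unaffected_blocks_identical(self):
        model = modular_model()
        eff = GroupEffectSpec(affected_modules=(0,), within_module_r_delta=-0.2)
        out = apply_group_effect(model, eff)
        r0, r1 = model.implied_correlation(), out.implied_correlation()
        untouched = ~np.isin(model.module_assignment, [0])
        sub = np.ix_(untouched, untouched)
        assert r1[sub] == pytest.approx(r0[sub], abs=1e-12)

    @pytest.mark.parametrize("mode", ["attenuate", "redistribute"])
    def test_sampled_within_module_reduction_matches_delta(self, mode):
        model = modular_model(age_slope=0.0, gender_effect=0.0)
        eff = GroupEffectSpec(affected_modules=tuple(range(6)),
                              within_module_r_delta=-0.2, mode=mode)
        out = apply_group_effect(model, eff)
        base = sample_cohort(model, 2000, seed=6)
        shifted = sample_cohort(out, 2000, seed=7)
        within, _ = within_between_masks(model.module_assignment)
        r0 = np.corrcoef(base.values, rowvar=False)[within].mean()
        r1 = np.corrcoef(shifted.values, rowvar=False)[within].mean()
        # redistribute keeps ~1/n_extra of pairs at the original level, so
        # the mean drop is slightly below |delta| for that mode
        assert abs((r0 - r1) - 0.2) < 0.05

    def test_redistribution_conserves_common_variance(self):
        model = modular_model()
        eff = GroupEffectSpec(affected_modules=tuple(range(6)),
                              within_module_r_delta=-0.2, mode="redistribute")
        out = apply_group_effect(model, eff)
        assert out.unique_variances() == pytest.approx(
            model.unique_variances(), abs=1e-12
        )

    def test_out_of_range_delta_rejected(self):
        model = modular_model(within_module_r=0.5)
        with pytest.raises(ModelValidationError):
            apply_group_effect(model, GroupEffectSpec(
                affected_modules=(0,), within_module_r_delta=-0.7))

    def test_nodal_delta_shifts_one_region(self):
        model = modular_model(age_slope=0.0, gender_effect=0.0,
                              within_module_r=0.5, hubs_per_module=0)
        eff = GroupEffectSpec(affected_regions=(0,), nodal_r_delta=-0.2)
        out = apply_group_effect(model, eff)
        r = out.implied_correlation()
        same_module = np.nonzero(model.module_assignment == 0)[0][1:]
        assert r[0, same_module] == pytest.approx(0.3)
        other = np.nonzero(model.module_assignment != 0)[0]
        assert r[0, other] == pytest.approx(0.1 * 0.3 / 0.5)  # proportional
        r_base = model.implied_correlation()
        assert r[1:, 1:][np.triu_indices(89, 1)] == pytest.approx(
            r_base[1:, 1:][np.triu_indices(89, 1)]
        )


class TestNullPair:
    def test_same_seed_same_pair(self, small_model):
        a1, b1 = sample_null_pair(small_model, 12, 10, seed=8)
        a2, b2 = sample_null_pair(small_model, 12, 10, seed=8)
        assert np.array_equal(a1.values, a2.values)
        assert np.array_equal(b1.values, b2.values)

    def test_cohort_sizes_and_labels(self, small_model):
        a, b = sample_null_pair(small_model, 96, 91, seed=9)
        assert (a.n_subjects, b.n_subjects) == (96, 91)
        assert set(a.group) == {"a"} and set(b.group) == {"b"}
        assert not np.array_equal(a.values[:91], b.values)


class TestSerialization:
    def test_json_round_trip(self, default_model):
        text = default_model.to_json()
        back = GenerativeModel.from_json(text)
        assert back.equals(default_model)

    def test_json_round_trip_with_effect(self, default_model, tmp_path):
        eff = GroupEffectSpec(affected_modules=(0, 1),
                              within_module_r_delta=-0.2, mode="redistribute")
        model = apply_group_effect(default_model, eff)
        path = tmp_path / "model.json"
        model.to_json(path)
        assert GenerativeModel.from_json(path).equals(model)
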
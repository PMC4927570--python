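import logging

import numpy as np
import pytest

from cbfcovnet import (
    CohortTable,
    admissible_sparsity_grid,
    build_covariance_matrix,
    default_sparsity_grid,
    edge_count_at_sparsity,
    modular_model,
    residualize_covariates,
    sample_cohort,
    threshold_at_sparsity,
)
from cbfcovnet.network import round_half_away


def _cohort(values, age=None, gender=None):
    n = values.shape[0]
    rng = np.random.default_rng(0)
    return CohortTable(
        values=values,
        age=rng.uniform(20, 50, n) if age is None else age,
        gender=rng.integers(0, 2, n).astype(float) if gender is None else gender,
        group=np.full(n, "g"),
    )


class TestResidualize:
    def test_values_linear_in_age_leave_zero_residuals(self):
        rng = np.random.default_rng(1)
        age = rng.uniform(20, 50, 30)
        values = np.outer(age, np.array([2.0, -1.0, 0.5])) + 7.0
        res = residualize_covariates(_cohort(values, age=age))
        assert np.max(np.abs(res)) < 1e-9

    def test_residuals_orthogonal_to_covariates(self, small_cohort):
        res = residualize_covariates(small_cohort)
        age_c = small_cohort.age - small_cohort.age.mean()
        gen_c = small_cohort.gender - small_cohort.gender.mean()
        assert np.max(np.abs(res.mean(axis=0))) < 1e-10
        assert np.max(np.abs(age_c @ res)) / len(age_c) < 1e-8
        assert np.max(np.abs(gen_c @ res)) / len(gen_c) < 1e-10

    def test_gender_coding_is_irrelevant(self, small_cohort):
        flipped = CohortTable(
            values=small_cohort.values,
            age=small_cohort.age,
            gender=1.0 - small_cohort.gender,
            group=small_cohort.group,
        )
        res_a = residualize_covariates(small_cohort)
        res_b = residualize_covariates(flipped)
        assert res_a == pytest.approx(res_b, abs=1e-9)

    def test_constant_covariate_dropped_with_warning(self, caplog):
        rng = np.random.default_rng(2)
        values = rng.normal(size=(20, 4))
        cohort = _cohort(values, gender=np.zeros(20))
        with caplog.at_level(logging.WARNING):
            res = residualize_covariates(cohort)
        assert "gender" in caplog.text
        assert res.shape == values.shape

    def test_zero_slope_model_keeps_raw_correlations(self):
        model = modular_model(n_regions=20, n_modules=2, age_slope=0.0,
                              gender_effect=0.0)
        cohort = sample_cohort(model, 500, seed=3)
        raw = np.corrcoef(cohort.values, rowvar=False)
        adj = np.corrcoef(residualize_covariates(cohort), rowvar=False)
        assert np.max(np.abs(raw - adj)) < 0.02

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError):
            residualize_covariates(_cohort(np.zeros((3, 4))))


class TestCovarianceMatrix:
    def test_duplicated_and_negated_columns(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=20)
        res = np.column_stack([x, x, -x, rng.normal(size=20)])
        cov = build_covariance_matrix(res)
        assert cov.r[0, 1] == pytest.approx(1.0)
        assert cov.r[0, 2] == pytest.approx(-1.0)
        assert cov.r == pytest.approx(cov.r.T)

    def test_ninety_region_cohort_gives_90x90(self, default_model):
        cohort = sample_cohort(default_model, 30, seed=5)
        cov = build_covariance_matrix(residualize_covariates(cohort))
        assert cov.r.shape == (90, 90)

    def test_zero_variance_region_named(self):
        res = np.column_stack([np.ones(10), np.random.default_rng(0).normal(size=10)])
        with pytest.raises(ValueError, match="region_001"):
            build_covariance_matrix(res)

    def test_affine_rescaling_invariance(self, small_cohort):
        res = residualize_covariates(small_cohort)
        cov = build_covariance_matrix(res)
        scaled = res.copy()
        scaled[:, 3] = 7.5 * scaled[:, 3]
        cov2 = build_covariance_matrix(scaled)
        assert cov2.r == pytest.approx(cov.r, abs=1e-12)


class TestThresholding:
    def test_exact_edge_count_formula(self):
        assert edge_count_at_sparsity(0.05, 90) == 200  # round(0.05 * 4005)
        rng = np.random.default_rng(6)
        r = rng.uniform(0.01, 1.0, (40, 40))
        r = np.triu(r, 1) + np.triu(r, 1).T
        for s in (0.05, 0.13, 0.27, 0.5, 1.0):
            net = threshold_at_sparsity(r, s)
            assert net.n_edges == edge_count_at_sparsity(s, 40)

    def test_round_half_away_convention(self):
        assert round_half_away(2.5) == 3
        assert round_half_away(3.5) == 4
        assert round_half_away(-2.5) == -3
        assert round_half_away(2.49) == 2

    def test_full_sparsity_on_positive_matrix_is_complete(self):
        r = np.full((8, 8), 0.3)
        np.fill_diagonal(r, 1.0)
        net = threshold_at_sparsity(r, 1.0)
        assert net.n_edges == 28

    def test_binary_and_weighted_share_edge_set(self, small_cohort):
        cov = build_covariance_matrix(residualize_covariates(small_cohort))
        w = threshold_at_sparsity(cov, 0.2, kind="weighted")
        b = threshold_at_sparsity(cov, 0.2, kind="binary")
        assert np.array_equal(w.adjacency > 0, b.adjacency > 0)
        assert set(np.unique(b.adjacency)) <= {0.0, 1.0}

    def test_edge_sets_nest_across_sparsity(self, small_cohort):
        cov = build_covariance_matrix(residualize_covariates(small_cohort))
        prev = None
        for s in (0.05, 0.1, 0.2, 0.35, 0.5):
            edges = set(zip(*np.nonzero(np.triu(
                threshold_at_sparsity(cov, s).adjacency, 1))))
            if prev is not None:
                assert prev <= edges
            prev = edges

    def test_kept_weights_are_positive_correlations(self, small_cohort):
        cov = build_covariance_matrix(residualize_covariates(small_cohort))
        net = threshold_at_sparsity(cov, 0.1)
        iu, ju = np.nonzero(np.triu(net.adjacency, 1))
        assert np.all(net.adjacency[iu, ju] > 0)
        assert net.adjacency[iu, ju] == pytest.approx(cov.r[iu, ju])

    def test_absolute_policy_ranks_by_magnitude(self):
        r = np.array([
            [1.0, -0.9, 0.2, 0.1],
            [-0.9, 1.0, 0.05, 0.0],
            [0.2, 0.05, 1.0, 0.3],
            [0.1, 0.0, 0.3, 1.0],
        ])
        net = threshold_at_sparsity(r, 1 / 6, edge_policy="absolute")
        assert net.adjacency[0, 1] == pytest.approx(0.9)  # |−0.9| wins

    def test_insufficient_positive_edges_rejected(self):
        r = -0.5 * np.ones((6, 6))
        np.fill_diagonal(r, 1.0)
        r[0, 1] = r[1, 0] = 0.4
        with pytest.raises(ValueError, match="positive"):
            threshold_at_sparsity(r, 0.5)

    def test_no_edges_rejected(self):
        r = np.eye(30)
        with pytest.raises(ValueError, match="no edges"):
            threshold_at_sparsity(r, 1e-4)


class TestSparsityGrid:
    def test_default_grid_span_and_count(self):
        grid = default_sparsity_grid()
        assert len(grid) == 46
        assert grid[0] == pytest.approx(0.05)
        assert grid[-1] == pytest.approx(0.50)
        assert np.diff(grid) == pytest.approx(np.full(45, 0.01))

    def test_average_degree_identity(self, small_cohort):
        cov = build_covariance_matrix(residualize_covariates(small_cohort))
        _, flags = admissible_sparsity_grid(cov, cov, np.array([0.1, 0.3]))
        for _, row in flags.iterrows():
            net = threshold_at_sparsity(cov, row["sparsity"])
            degrees = (net.adjacency > 0).sum(axis=1)
            assert row["avg_degree"] == pytest.approx(degrees.mean())

    def test_degree_criterion_marginal_at_low_sparsity(self, default_model):
        # at s=0.05, N=90: average degree 2*200/90 = 4.44 < ln(90) = 4.4998,
        # so the advisory flag is False yet the grid still includes 0.05
        cohort = sample_cohort(default_model, 40, seed=8)
        cov = build_covariance_matrix(residualize_covariates(cohort))
        grid, flags = admissible_sparsity_grid(cov, cov)
        assert grid[0] == pytest.approx(0.05)
        assert not flags.iloc[0]["degree_above_log_n"]
        assert flags.iloc[-1]["degree_above_log_n"]

    def test_non_increasing_grid_rejected(self, small_cohort):
        cov = build_covariance_matrix(residualize_covariates(small_cohort))
        with pytest.raises(ValueError):
            admissible_sparsity_grid(cov, cov, np.array([0.2, 0.1]))


class TestCohortTableIO:
    def test_tsv_round_trip(self, small_cohort, tmp_path):
        path = tmp_path / "cohort.tsv"
        small_cohort.to_tsv(path)
        back = CohortTable.from_tsv(path)
        assert back.values == pytest.approx(small_cohort.values, rel=1e-9)
        assert back.age == pytest.approx(small_cohort.age, rel=1e-9)
        assert np.array_equal(back.gender, small_cohort.gender)
        assert back.region_names == small_cohort.region_names

    def test_missing_values_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            CohortTable(values=np.array([[1.0, np.nan]] * 3),
                        age=np.zeros(3), gender=np.zeros(3),
                        group=np.array(["g"] * 3))
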
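"""AUC summarization over the sparsity grid and permutation-based group tests.

Each topological measure evaluated over the sparsity grid yields a curve;
the area under that curve (trapezoidal by default) is the scalar actually
compared between groups. Group differences are assessed by permutation:
subjects are pooled, randomly reassigned to two pseudo-groups of the
original sizes, and the *entire* pipeline (covariate residualization,
correlation, thresholding, metrics, null-model normalization) is recomputed
under each relabeling — exactly the procedure applied to the real labels.

The p-value is the add-one estimator p = (1 + #{|null| >= |observed|}) /
(1 + n_perm), two-tailed by default (``tail="one"`` counts signed
exceedances). Nodal tests share one relabeling stream across regions, so
the cross-region dependence of the null is preserved and one permutation
prices all 90 (or N) regional comparisons; the multiple-comparison rule for
nodal results is the false-positive correction p < 1/N.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .metrics import (
    clustering_coefficient,
    distance_matrix,
    global_efficiency,
    local_efficiency,
    nodal_metrics,
    path_length_harmonic,
)
from .network import (
    CohortTable,
    build_covariance_matrix,
    default_sparsity_grid,
    residualize_covariates,
    threshold_at_sparsity,
)
from .nulls import null_metric_distribution, small_world_params
from .metrics import GlobalMetrics

__all__ = [
    "AnalysisConfig",
    "MetricCurve",
    "PermutationResult",
    "NodalResult",
    "GLOBAL_MEASURES",
    "NODAL_MEASURES",
    "auc",
    "metric_curves",
    "group_global_curves",
    "group_nodal_curves",
    "permutation_test_global",
    "permutation_test_nodal",
]

GLOBAL_MEASURES = ("gamma", "lambda", "sigma", "E_glob", "E_loc", "C", "L",
                   "C_null", "L_null")
NODAL_MEASURES = ("degree", "efficiency", "betweenness")

_MAX_SEED = 2**31 - 1


@dataclass
class AnalysisConfig:
    """Settings shared by every stage of the covariance-network analysis.

    Defaults reproduce the reference analysis: weighted networks, signed
    edge selection, sparsity grid 0.05-0.50 step 0.01, 100 rewired nulls
    per threshold, 1000 permutations, trapezoidal AUC, two-tailed p.
    """

    kind: str = "weighted"
    edge_policy: str = "signed"
    clustering_variant: str = "onnela"
    n_null: int = 100
    swaps_per_edge: int = 10
    n_perm: int = 1000
    auc_rule: str = "trapezoid"
    tail: str = "two"

    def __post_init__(self) -> None:
        if self.kind not in ("weighted", "binary"):
            raise ValueError(f"unknown network kind {self.kind!r}")
        if self.auc_rule not in ("trapezoid", "rectangle"):
            raise ValueError(f"unknown AUC rule {self.auc_rule!r}")
        if self.tail not in ("two", "one"):
            raise ValueError(f"tail must be 'two' or 'one'")
        if self.n_null < 1 or self.n_perm < 1 or self.swaps_per_edge < 1:
            raise ValueError("counts must be positive")


@dataclass
class MetricCurve:
    """One measure evaluated over the sparsity grid for one group."""

    sparsity_values: np.ndarray
    values: np.ndarray
    measure: str
    group: str = ""

    def __post_init__(self) -> None:
        self.sparsity_values = np.asarray(self.sparsity_values, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.sparsity_values.shape != self.values.shape:
            raise ValueError("grid and values must have matching lengths")
        if self.sparsity_values.size >= 2 and np.any(np.diff(self.sparsity_values) <= 0):
            raise ValueError("sparsity grid must be strictly increasing")


@dataclass
class PermutationResult:
    """AUC group difference, its permutation null, and the p-value."""

    measure: str
    auc_a: float
    auc_b: float
    observed_diff: float
    null_diffs: np.ndarray
    p_value: float
    n_perm: int


@dataclass
class NodalResult:
    """Per-region permutation results for the nodal centrality measures.

    ``p_values`` and ``observed_diff`` are DataFrames (regions x measures);
    ``significant`` flags p < 1/N, the expected-below-one-false-positive
    correction.
    """

    p_values: pd.DataFrame
    observed_diff: pd.DataFrame
    significant: pd.DataFrame
    n_perm: int
    threshold: float


def auc(curve: MetricCurve | np.ndarray, grid: np.ndarray | None = None,
        rule: str = "trapezoid") -> float:
    """Area under a metric-versus-sparsity curve.

    Trapezoidal by default; ``rule="rectangle"`` uses left-endpoint
    rectangles (excluding the final grid point) for sensitivity checks.
    """
    if isinstance(curve, MetricCurve):
        y, x = curve.values, curve.sparsity_values
    else:
        y = np.asarray(curve, dtype=float)
        if grid is None:
            raise ValueError("grid required when passing a bare value array")
        x = np.asarray(grid, dtype=float)
    if y.shape != x.shape:
        raise ValueError("curve and grid lengths differ")
    if y.size < 2:
        raise ValueError("AUC needs at least 2 grid points")
    if rule == "trapezoid":
        return float(np.trapezoid(y, x))
    if rule == "rectangle":
        return float(np.sum(y[:-1] * np.diff(x)))
    raise ValueError(f"unknown AUC rule {rule!r}")


def _spawn_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.SeedSequence(seed).generate_state(n, dtype=np.uint32) % _MAX_SEED


def group_global_curves(
    values: np.ndarray,
    age: np.ndarray,
    gender: np.ndarray,
    grid: np.ndarray,
    config: AnalysisConfig,
    seed: int = 0,
) -> dict[str, np.ndarray]:
    """Global measures over the grid for one group of subjects.

    Runs residualization -> correlation -> thresholding -> metrics, with
    gamma/lambda/sigma normalized against ``config.n_null`` degree-matched
    rewired surrogates per threshold. ``seed`` controls only the null
    ensembles (the rest of the computation is deterministic).
    """
    cohort = CohortTable(values=values, age=age, gender=gender,
                         group=np.full(len(age), "g"))
    res = residualize_covariates(cohort)
    cov = build_covariance_matrix(res)
    out = {m: np.empty(len(grid)) for m in GLOBAL_MEASURES}
    null_seeds = _spawn_seeds(seed, len(grid))
    for t, s in enumerate(grid):
        try:
            net = threshold_at_sparsity(cov, s, kind=config.kind,
                                        edge_policy=config.edge_policy)
            dist = distance_matrix(net)
            e_glob = global_efficiency(dist)
            length = path_length_harmonic(dist)
            _, c_mean = clustering_coefficient(net, variant=config.clustering_variant)
            _, e_loc = local_efficiency(net)
            real = GlobalMetrics(clustering_mean=c_mean, path_length=length,
                                 e_glob=e_glob, e_loc=e_loc)
            ensemble = null_metric_distribution(
                net, m=config.n_null, seed=int(null_seeds[t]),
                swaps_per_edge=config.swaps_per_edge,
                clustering_variant=config.clustering_variant,
            )
            sw = small_world_params(real, ensemble)
        except Exception as err:
            raise RuntimeError(f"metric computation failed at sparsity {s}: {err}") from err
        out["gamma"][t] = sw.gamma
        out["lambda"][t] = sw.lam
        out["sigma"][t] = sw.sigma
        out["E_glob"][t] = e_glob
        out["E_loc"][t] = e_loc
        out["C"][t] = c_mean
        out["L"][t] = length
        out["C_null"][t] = float(np.mean(ensemble.clustering_means))
        out["L_null"][t] = float(np.mean(ensemble.path_lengths))
    return out


def group_nodal_curves(
    values: np.ndarray,
    age: np.ndarray,
    gender: np.ndarray,
    grid: np.ndarray,
    config: AnalysisConfig,
) -> dict[str, np.ndarray]:
    """Nodal centrality curves (measures x regions x grid) for one group."""
    cohort = CohortTable(values=values, age=age, gender=gender,
                         group=np.full(len(age), "g"))
    res = residualize_covariates(cohort)
    cov = build_covariance_matrix(res)
    n = cov.n_regions
    out = {m: np.empty((n, len(grid))) for m in NODAL_MEASURES}
    for t, s in enumerate(grid):
        net = threshold_at_sparsity(cov, s, kind=config.kind,
                                    edge_policy=config.edge_policy)
        nm = nodal_metrics(net)
        out["degree"][:, t] = nm.degree
        out["efficiency"][:, t] = nm.efficiency
        out["betweenness"][:, t] = nm.betweenness
    return out


def metric_curves(
    cohort: CohortTable,
    grid: np.ndarray | None = None,
    config: AnalysisConfig | None = None,
    seed: int = 0,
    include_nodal: bool = False,
) -> list[MetricCurve]:
    """All metric curves of one cohort as tidy `MetricCurve` objects."""
    grid = default_sparsity_grid() if grid is None else np.asarray(grid, float)
    config = config or AnalysisConfig()
    label = str(cohort.group[0]) if len(cohort.group) else ""
    curves = []
    glob = group_global_curves(cohort.values, cohort.age, cohort.gender,
                               grid, config, seed=seed)
    for measure, vals in glob.items():
        curves.append(MetricCurve(grid, vals, measure, group=label))
    if include_nodal:
        nod = group_nodal_curves(cohort.values, cohort.age, cohort.gender, grid, config)
        for measure, mat in nod.items():
            for i, name in enumerate(cohort.region_names):
                curves.append(
                    MetricCurve(grid, mat[i], f"{measure}[{name}]", group=label)
                )
    return curves


def _pool(cohort_a: CohortTable, cohort_b: CohortTable):
    if cohort_a.n_regions != cohort_b.n_regions:
        raise ValueError("cohorts must share the region set")
    if cohort_a.n_subjects < 3 or cohort_b.n_subjects < 3:
        raise ValueError("each group needs at least 3 subjects")
    values = np.vstack([cohort_a.values, cohort_b.values])
    age = np.concatenate([cohort_a.age, cohort_b.age])
    gender = np.concatenate([cohort_a.gender, cohort_b.gender])
    return values, age, gender, cohort_a.n_subjects


def _p_value(observed: float, nulls: np.ndarray, tail: str) -> float:
    if tail == "two":
        exceed = np.sum(np.abs(nulls) >= abs(observed))
    else:
        exceed = np.sum(nulls >= observed)
    return float((1 + exceed) / (1 + len(nulls)))


def permutation_test_global(
    cohort_a: CohortTable,
    cohort_b: CohortTable,
    measures: tuple[str, ...] = ("gamma", "lambda", "sigma", "E_glob", "E_loc"),
    n_perm: int | None = None,
    seed: int = 0,
    grid: np.ndarray | None = None,
    config: AnalysisConfig | None = None,
) -> dict[str, PermutationResult]:
    """Permutation test of AUC group differences for global measures.

    The observed difference is AUC(group A) - AUC(group B); each of the
    ``n_perm`` relabelings reassigns subjects to pseudo-groups of the
    original sizes and reruns residualization through AUC. One relabeling
    stream prices all requested measures simultaneously.
    """
    config = config or AnalysisConfig()
    n_perm = config.n_perm if n_perm is None else int(n_perm)
    if n_perm < 1:
        raise ValueError("n_perm must be at least 1")
    grid = default_sparsity_grid() if grid is None else np.asarray(grid, float)
    values, age, gender, n_a = _pool(cohort_a, cohort_b)
    n_tot = values.shape[0]
    eval_seeds = _spawn_seeds(seed, n_perm + 1)
    rng = np.random.default_rng(_spawn_seeds(seed ^ 0x5EED, 1)[0])

    def eval_split(idx_a, idx_b, s):
        ca = group_global_curves(values[idx_a], age[idx_a], gender[idx_a],
                                 grid, config, seed=int(s))
        cb = group_global_curves(values[idx_b], age[idx_b], gender[idx_b],
                                 grid, config, seed=int(s) + 1)
        return {m: (auc(ca[m], grid, config.auc_rule),
                    auc(cb[m], grid, config.auc_rule)) for m in measures}

    idx = np.arange(n_tot)
    observed = eval_split(idx[:n_a], idx[n_a:], eval_seeds[0])
    nulls = {m: np.empty(n_perm) for m in measures}
    for p in range(n_perm):
        perm = rng.permutation(n_tot)
        got = eval_split(perm[:n_a], perm[n_a:], eval_seeds[p + 1])
        for m in measures:
            nulls[m][p] = got[m][0] - got[m][1]
    out = {}
    for m in measures:
        a_auc, b_auc = observed[m]
        diff = a_auc - b_auc
        out[m] = PermutationResult(
            measure=m, auc_a=a_auc, auc_b=b_auc, observed_diff=diff,
            null_diffs=nulls[m], p_value=_p_value(diff, nulls[m], config.tail),
            n_perm=n_perm,
        )
    return out


def permutation_test_nodal(
    cohort_a: CohortTable,
    cohort_b: CohortTable,
    n_perm: int | None = None,
    seed: int = 0,
    grid: np.ndarray | None = None,
    config: AnalysisConfig | None = None,
) -> NodalResult:
    """Permutation test of nodal degree/efficiency/betweenness AUC differences.

    One relabeling evaluates every region, so all regional p-values share
    the same permutation stream. Regions are flagged significant at the
    corrected threshold p < 1/N.
    """
    config = config or AnalysisConfig()
    n_perm = config.n_perm if n_perm is None else int(n_perm)
    if n_perm < 1:
        raise ValueError("n_perm must be at least 1")
    grid = default_sparsity_grid() if grid is None else np.asarray(grid, float)
    values, age, gender, n_a = _pool(cohort_a, cohort_b)
    n_tot = values.shape[0]
    n_regions = cohort_a.n_regions
    rng = np.random.default_rng(_spawn_seeds(seed ^ 0x5EED, 1)[0])

    def eval_split(idx_a, idx_b):
        ca = group_nodal_curves(values[idx_a], age[idx_a], gender[idx_a], grid, config)
        cb = group_nodal_curves(values[idx_b], age[idx_b], gender[idx_b], grid, config)
        return {
            m: np.array([
                auc(ca[m][i], grid, config.auc_rule) - auc(cb[m][i], grid, config.auc_rule)
                for i in range(n_regions)
            ])
            for m in NODAL_MEASURES
        }

    idx = np.arange(n_tot)
    observed = eval_split(idx[:n_a], idx[n_a:])
    exceed = {m: np.zeros(n_regions) for m in NODAL_MEASURES}
    for _ in range(n_perm):
        perm = rng.permutation(n_tot)
        got = eval_split(perm[:n_a], perm[n_a:])
        for m in NODAL_MEASURES:
            if config.tail == "two":
                exceed[m] += np.abs(got[m]) >= np.abs(observed[m])
            else:
                exceed[m] += got[m] >= observed[m]
    names = cohort_a.region_names
    p = pd.DataFrame(
        {m: (1 + exceed[m]) / (1 + n_perm) for m in NODAL_MEASURES}, index=names
    )
    obs = pd.DataFrame({m: observed[m] for m in NODAL_MEASURES}, index=names)
    thresh = 1.0 / n_regions
    return NodalResult(
        p_values=p, observed_diff=obs, significant=p < thresh,
        n_perm=n_perm, threshold=thresh,
    )
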
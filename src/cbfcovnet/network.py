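"""Group-level CBF covariance network construction.

Nodes are brain regions; edges are across-subject Pearson correlations of
regional cerebral blood flow, computed after removing age and gender effects
by per-region linear regression. The correlation matrix is thresholded at a
target *sparsity* (fraction of possible edges retained) so that networks
compared across groups have exactly the same number of edges.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "CohortTable",
    "CovarianceMatrix",
    "ThresholdedNetwork",
    "residualize_covariates",
    "build_covariance_matrix",
    "threshold_at_sparsity",
    "admissible_sparsity_grid",
    "default_sparsity_grid",
    "edge_count_at_sparsity",
    "round_half_away",
]


@dataclass
class CohortTable:
    """Subjects x regions table of mean regional CBF plus covariates.

    Attributes
    ----------
    values : ndarray, shape (n_subjects, n_regions)
        Mean regional CBF per subject (any consistent units; typically
        normalized to the whole-brain mean).
    age : ndarray, shape (n_subjects,)
        Age in years.
    gender : ndarray, shape (n_subjects,)
        Binary gender code (0/1). The coding direction is irrelevant for
        network construction because residualization is affine-invariant.
    group : ndarray of str, shape (n_subjects,)
        Group label per subject.
    region_names : list of str
        Ordered region identifiers (the network's node labels).
    """

    values: np.ndarray
    age: np.ndarray
    gender: np.ndarray
    group: np.ndarray
    region_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.age = np.asarray(self.age, dtype=float)
        self.gender = np.asarray(self.gender, dtype=float)
        self.group = np.asarray(self.group)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D subjects x regions array")
        n = self.values.shape[0]
        if not (self.age.shape == self.gender.shape == self.group.shape == (n,)):
            raise ValueError("covariate lengths must match the number of subjects")
        if not self.region_names:
            self.region_names = [f"region_{i + 1:03d}" for i in range(self.values.shape[1])]
        if len(self.region_names) != self.values.shape[1]:
            raise ValueError("region_names length must match the number of regions")
        if np.isnan(self.values).any():
            raise ValueError("cohort values contain missing entries")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_regions(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.region_names)
        df.insert(0, "gender", self.gender.astype(int))
        df.insert(0, "age", self.age)
        df.insert(0, "group", self.group)
        df.insert(0, "subject_id", [f"sub-{i + 1:04d}" for i in range(self.n_subjects)])
        return df

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CohortTable":
        meta = ["subject_id", "group", "age", "gender"]
        regions = [c for c in df.columns if c not in meta]
        return cls(
            values=df[regions].to_numpy(float),
            age=df["age"].to_numpy(float),
            gender=df["gender"].to_numpy(float),
            group=df["group"].to_numpy(str),
            region_names=list(regions),
        )

    @classmethod
    def from_tsv(cls, path) -> "CohortTable":
        return cls.from_frame(pd.read_csv(path, sep="\t"))


@dataclass
class CovarianceMatrix:
    """Region x region Pearson correlation matrix for one group."""

    r: np.ndarray
    n_subjects: int
    region_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        if self.r.ndim != 2 or self.r.shape[0] != self.r.shape[1]:
            raise ValueError("correlation matrix must be square")
        if not np.allclose(self.r, self.r.T, atol=1e-12):
            raise ValueError("correlation matrix must be symmetric")
        if np.nanmax(np.abs(self.r)) > 1 + 1e-10:
            raise ValueError("correlation values must lie in [-1, 1]")
        if not self.region_names:
            self.region_names = [f"region_{i + 1:03d}" for i in range(self.r.shape[0])]

    @property
    def n_regions(self) -> int:
        return self.r.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.r, index=self.region_names, columns=self.region_names)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", float_format="%.10g")

    @classmethod
    def from_tsv(cls, path, n_subjects: int = 0) -> "CovarianceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(r=df.to_numpy(float), n_subjects=n_subjects,
                   region_names=[str(c) for c in df.columns])


@dataclass
class ThresholdedNetwork:
    """Undirected network at a fixed sparsity.

    ``adjacency`` is dense, symmetric, zero-diagonal and nonnegative; for
    ``kind="binary"`` entries are 0/1. The number of edges is exactly
    ``round(s * N * (N - 1) / 2)`` with half-away-from-zero rounding.
    """

    adjacency: np.ndarray
    sparsity: float
    kind: str = "weighted"
    region_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.adjacency = np.asarray(self.adjacency, dtype=float)
        a = self.adjacency
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(a) != 0):
            raise ValueError("self-loops are not allowed")
        if np.any(a < 0):
            raise ValueError("edge weights must be nonnegative")
        if not self.region_names:
            self.region_names = [f"region_{i + 1:03d}" for i in range(a.shape[0])]

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(np.triu(self.adjacency, 1)))

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            self.adjacency, index=self.region_names, columns=self.region_names
        ).to_csv(path, sep="\t", float_format="%.10g")


def round_half_away(x: float) -> int:
    """Round to the nearest integer, halves away from zero."""
    return int(math.floor(abs(x) + 0.5) * (1 if x >= 0 else -1))


def edge_count_at_sparsity(s: float, n_regions: int) -> int:
    """Target edge count K = round(s * N(N-1)/2)."""
    return round_half_away(s * n_regions * (n_regions - 1) / 2.0)


def residualize_covariates(cohort: CohortTable) -> np.ndarray:
    """Remove age and gender effects from every region by OLS.

    Fits ``cbf ~ 1 + age + gender`` independently per region and returns the
    residual matrix (subjects x regions). A covariate that is constant across
    the cohort (e.g. a single-gender sample) is dropped with a warning rather
    than producing a singular design.
    """
    n = cohort.n_subjects
    if n < 4:
        raise ValueError("residualization needs at least 4 subjects")
    cols = [np.ones(n)]
    for name, v in (("age", cohort.age), ("gender", cohort.gender)):
        if np.ptp(v) == 0:
            logger.warning("covariate %r is constant; dropped from residualization", name)
            continue
        cols.append(v)
    x = np.column_stack(cols)
    beta, *_ = np.linalg.lstsq(x, cohort.values, rcond=None)
    return cohort.values - x @ beta


def build_covariance_matrix(
    residuals: np.ndarray, region_names: Sequence[str] | None = None
) -> CovarianceMatrix:
    """Pearson correlations between region pairs across subjects."""
    residuals = np.asarray(residuals, dtype=float)
    if residuals.ndim != 2 or residuals.shape[0] < 3:
        raise ValueError("need a 2-D matrix with at least 3 subjects")
    names = list(region_names) if region_names is not None else [
        f"region_{i + 1:03d}" for i in range(residuals.shape[1])
    ]
    sd = residuals.std(axis=0)
    dead = np.nonzero(sd == 0)[0]
    if dead.size:
        raise ValueError(
            "zero-variance region(s): " + ", ".join(names[i] for i in dead[:5])
        )
    r = np.corrcoef(residuals, rowvar=False)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    return CovarianceMatrix(r=r, n_subjects=residuals.shape[0], region_names=names)


def _ranked_edges(r: np.ndarray, edge_policy: str):
    """Upper-triangle edges sorted by descending selection key.

    Ties broken lexicographically on (i, j) so that thresholding is
    deterministic and edge sets nest across increasing sparsity.
    """
    n = r.shape[0]
    iu, ju = np.triu_indices(n, 1)
    vals = r[iu, ju]
    if edge_policy == "signed":
        key = vals
    elif edge_policy == "absolute":
        key = np.abs(vals)
    else:
        raise ValueError(f"unknown edge policy {edge_policy!r}")
    order = np.lexsort((ju, iu, -key))
    return iu[order], ju[order], vals[order], key[order]


def threshold_at_sparsity(
    cov: CovarianceMatrix | np.ndarray,
    s: float,
    kind: str = "weighted",
    edge_policy: str = "signed",
) -> ThresholdedNetwork:
    """Keep the K = round(s * N(N-1)/2) strongest edges of the matrix.

    With the default ``edge_policy="signed"`` edges are ranked by signed
    correlation and only positive correlations are eligible as edges: a
    negative value reached before K edges are placed simply cedes its slot
    to the next positive value, and the call fails if fewer than K positive
    correlations exist. ``edge_policy="absolute"`` ranks by magnitude and
    uses |r| as the weight. Weighted networks keep the correlation as the
    edge weight; binary networks set kept edges to 1 (same edge set).
    """
    if isinstance(cov, CovarianceMatrix):
        r, names = cov.r, cov.region_names
    else:
        r = np.asarray(cov, dtype=float)
        names = None
    if not 0 < s <= 1:
        raise ValueError("sparsity must lie in (0, 1]")
    if kind not in ("weighted", "binary"):
        raise ValueError(f"unknown network kind {kind!r}")
    n = r.shape[0]
    k = edge_count_at_sparsity(s, n)
    if k < 1:
        raise ValueError(f"sparsity {s} yields no edges for N={n}")
    iu, ju, vals, key = _ranked_edges(r, edge_policy)
    if edge_policy == "signed":
        pos = vals > 0
        iu, ju, vals = iu[pos], ju[pos], vals[pos]
    else:
        vals = np.abs(vals)
    if vals.size < k:
        raise ValueError(
            f"only {vals.size} admissible (positive) correlations but "
            f"{k} edges requested at sparsity {s}"
        )
    adj = np.zeros((n, n))
    sel = slice(0, k)
    w = vals[sel] if kind == "weighted" else np.ones(k)
    adj[iu[sel], ju[sel]] = w
    adj[ju[sel], iu[sel]] = w
    return ThresholdedNetwork(
        adjacency=adj, sparsity=float(s), kind=kind,
        region_names=list(names) if names else [],
    )


def default_sparsity_grid(
    s_min: float = 0.05, s_max: float = 0.50, step: float = 0.01
) -> np.ndarray:
    """Sparsity grid, default 0.05..0.50 in steps of 0.01 (46 values)."""
    n = int(round((s_max - s_min) / step)) + 1
    grid = s_min + step * np.arange(n)
    return np.round(grid, 10)


def admissible_sparsity_grid(
    cov_a: CovarianceMatrix,
    cov_b: CovarianceMatrix,
    grid: np.ndarray | None = None,
    log_base: str = "natural",
) -> tuple[np.ndarray, pd.DataFrame]:
    """The configured sparsity grid plus advisory per-threshold diagnostics.

    For each threshold the average degree 2K/N is compared against log(N)
    (natural log by default, the usual small-world criterion). The check is
    advisory: the returned grid is fixed by configuration, and the flags let
    callers inspect marginal thresholds instead of silently pruning them.
    """
    if grid is None:
        grid = default_sparsity_grid()
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("sparsity grid is empty")
    if np.any(np.diff(grid) <= 0):
        raise ValueError("sparsity grid must be strictly increasing")
    if cov_a.n_regions != cov_b.n_regions:
        raise ValueError("groups must share the same node set")
    n = cov_a.n_regions
    log_n = math.log(n) if log_base == "natural" else math.log10(n)
    rows = []
    for s in grid:
        k = edge_count_at_sparsity(s, n)
        avg_deg = 2.0 * k / n
        rows.append(
            {"sparsity": s, "n_edges": k, "avg_degree": avg_deg,
             "degree_above_log_n": avg_deg > log_n}
        )
    return grid, pd.DataFrame(rows)
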
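# Methods

## The model

A CBF covariance network is a group-level construct: for a cohort of
subjects, each brain region contributes one mean CBF value per subject,
and the edge between two regions is the Pearson correlation of those
values across subjects, after removing age and gender by per-region
ordinary least squares (`cbf ~ 1 + age + gender`). Residualization is
affine-invariant, so the gender coding (0/1 vs 1/0) and any linear
rescaling of a region's values do not change the network.

Correlation matrices are compared across groups at matched connection
density: at sparsity *s* the `K = round(s·N(N−1)/2)` strongest positive
correlations become edges (half-away-from-zero rounding; deterministic
lexicographic tie-break, which also makes edge sets nest across
increasing *s*). Negative correlations are never used as edges under the
default `signed` policy — weighted clustering and path measures require
nonnegative weights and covariance-network practice is to discard them; a
magnitude-ranking `absolute` policy is available. If fewer than K positive
correlations exist the run fails loudly rather than padding.

### Topological measures

Weighted edge length is 1/weight. Characteristic path length is the
harmonic mean `L = N(N−1) / Σ_{i≠j} 1/d_ij`, which is finite on
disconnected networks and satisfies `L·E_glob = 1` exactly; this identity
is asserted in tests. Weighted clustering uses the Onnela
geometric-mean-of-triangle-weights form with weights rescaled by the
network maximum (the dominant convention in weighted small-world brain
studies; the Barrat form is available via configuration). Local efficiency
of node *i* is the global efficiency of the subgraph induced on *i*'s
neighbors; nodes with fewer than two neighbors score 0 and degree-0 nodes
stay in network means so N is constant across thresholds. Betweenness is
raw Brandes counting on the same 1/weight lengths with fractional credit
for equal-length paths. All kernels are O(N³) dense implementations
(numba-compiled) and are verified against exhaustive brute-force oracles
and networkx on small graphs to 1e−10.

### Null models and normalization

γ and λ normalize clustering and path length by the means of a
degree-matched ensemble: Maslov–Sneppen double-edge swaps (10·|E|
attempted swaps, proposals creating self-loops or multi-edges rejected)
preserve the binary degree sequence exactly; for weighted networks the
original weight multiset is reassigned to the rewired edges in random
order. Ensemble size defaults to 100. σ = γ/λ exactly. MCMC mixing
adequacy, rather than exact uniform sampling of the degree class, is
accepted as in common practice; the swap-success rate is logged when a
graph is too rigid to rewire.

### AUC and permutation testing

Each measure's curve over the sparsity grid (default 0.05–0.50, step
0.01) is summarized by its trapezoidal AUC (a rectangle rule is available
for sensitivity checks). Group comparison is by permutation: subjects are
pooled, reassigned to pseudo-groups of the original sizes, and the whole
pipeline is rerun per relabeling — including re-residualization within
each pseudo-group, mirroring the real-label procedure exactly. The
p-value is add-one, two-tailed on |AUC difference| by default:
`p = (1 + #{|null| ≥ |obs|}) / (1 + n_perm)`. A one-tailed mode exists
because the verbal description of such procedures is often directional;
two-tailed is the conservative default given that differences in both
directions are reported. Nodal tests (degree/strength, nodal efficiency,
betweenness per region) share a single relabeling stream across regions,
preserving the cross-region dependence of the null, and are corrected
with the false-positive rule p < 1/N — with the add-one estimator and
n_perm = 100 the expected number of flagged regions under the null is
90/101 ≈ 0.89, i.e. below one false positive per analysis.

### Threshold-selection diagnostics

The average-degree criterion (2K/N > ln N) and connectivity are reported
per threshold as advisory flags, not enforced: at s = 0.05 and N = 90 the
average degree 4.44 sits marginally below ln 90 ≈ 4.50, yet 0.05 is the
standard grid start, so silently pruning thresholds would be surprising.

## The synthetic cohort generator

The generator exists because covariance networks are group-level objects:
no per-subject dataset can be distributed that reproduces a published
group result, so validation must rest on cohorts with *known* covariance
structure. Regions are partitioned into modules; the standardized
residual of region *i* is built from independent latent factors — its
module factor (loading √within-share), a global factor carrying the
between-module background (regions can be designated hubs with larger
global loadings), optional auxiliary factors, and unique noise. The
implied correlation matrix is positive semi-definite by construction, and
validation errors name the offending region/module. Covariates enter
additively (age slope in CBF/year, gender offset in CBF units), ages are
uniform on [18, 55], gender is Bernoulli(0.5); all configurable, every
sampling operation takes an explicit seed.

Default conditions: 90 regions, 6 equal modules, within-module r = 0.3
over a between-module background of r = 0.1, residual SD 5 on a baseline
of 50 (a standardized mL/100g/min scale), age slope −0.15 CBF/year,
gender offset +3. The moderate 0.3/0.1 contrast was chosen so that the
thresholded networks sit in the small-world regime across the *entire*
0.05–0.50 density range — γ > 1 and σ > 1 everywhere with λ near 1 —
matching the regime real CBF covariance networks occupy. Sharper
contrasts (e.g. within r = 0.5) fragment the sparsest networks into
module cliques: harmonic λ then rises far above 1 at low density and σ
dips marginally below 1 at density 0.5, which is a property of the
idealized block structure, not of the pipeline. (The reproduction script
deliberately uses the sharper 0.5/0.1 contrast for its headline minima,
where the γ floor is higher.)

### The planted group effect

`apply_group_effect` edits loadings, never sampled data, so both groups
share one generative mechanism except the planted change. The default
effect reduces the within-module correlation target by 0.2 in three of
the six modules and splits the removed common variance equally between
region-unique noise (`attenuate` component) and diffuse auxiliary
cross-module factors (`redistribute` component, one of six auxiliary
factors per region chosen by a fixed assignment seed). This mixture was
calibrated against the dissociation it must emulate — decreased γ, σ and
E_loc with preserved λ and E_glob:

* pure attenuation lowers all kept edge weights, dragging weighted
  E_glob into group significance;
* pure redistribution conserves the coupling budget so well that the
  local-efficiency deficit becomes undetectable;
* the equal split reduces local structure (γ, E_loc down) while leaving
  the global weight budget and long-range path structure close to intact
  (E_glob, λ differences within permutation noise in most runs).

The weighted λ deserves a caveat: under the weight-permuting
degree-matched null, λ responds to the *dispersion and placement* of the
weight distribution, so any effect that de-modularizes the covariance
also nudges λ downward. With the default effect this residual λ shift is
small (≈−0.005 AUC over the test grid) but occasionally crosses the 0.05
significance line; the dissociation pattern is therefore reproduced in
most, not all, seeds.

A nodal variant rescales selected regions' loading vectors so their
within-module correlations shift by an exact delta (cross-module
correlations scale proportionally), for testing nodal-centrality
detection.

### What the generator does not emulate

Voxelwise images, ASL noise physics, hemodynamics, site/scanner effects,
non-Gaussian CBF distributions, and realistic anatomical covariance
spectra. Passing tests demonstrate that the pipeline's statistics behave
correctly (calibrated type I error, exact invariants, detection of known
effects) — not that any particular clinical finding would replicate.

## Problem sizes used in the test suite

The statistical acceptance checks run the full pipeline at reduced sizes
chosen to keep the whole suite in the tens of minutes on one CPU while
preserving the procedure exactly: the small-world reproduction uses the
full 46-point grid with 20 nulls per threshold; type-I calibration uses
36 regions × 36 subjects/group, 5 thresholds, 4 nulls, 49 permutations
and 200 replicate datasets (the binomial acceptance interval is computed
for the exact null rejection rate of the add-one estimator at that
n_perm, 2/50); the power check uses the full 90-region cohorts (96/91),
5 thresholds, 6 nulls, 99 permutations and 20 seeds; nodal
false-positive control uses 90 regions, 45 subjects/group, 100
permutations and 50 seeds. The `run_pipeline` defaults remain the
reference settings (0.05–0.50/0.01 grid, 100 nulls, 1000 permutations).

## Known limitations

* Weighted λ and E_glob inherit the conventions chosen here (1/weight
  lengths, weight-permuting nulls); other conventions shift absolute
  values, though group contrasts are more stable.
* The permutation test assumes exchangeability of subjects across groups
  after covariate residualization; strong covariate imbalance between
  groups would violate it.
* Degree-matched rewiring is MCMC-based, not exact-uniform over the
  degree class.
* CBF quantification parameter defaults (α = 0.8, T1a = 1.65 s,
  w = 2.025 s, tl = 1.5 s, ρb = C = ωa = 1) are documented assumptions;
  absolute CBF scale cancels from correlation networks after whole-brain
  normalization, but the values must be set per acquisition when absolute
  units matter.
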
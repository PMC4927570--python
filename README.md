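# cbfcovnet

Group-level **cerebral blood flow (CBF) covariance network** analysis:
from cohort tables of regional CBF values (e.g. arterial-spin-labeling MRI
averaged over an anatomical parcellation) to small-world graph statistics,
degree-matched null models, AUC summaries over a sparsity grid, and
permutation-based group comparison.

## The analysis

Nodes are brain regions (e.g. the 90 cerebral regions of the AAL atlas);
the edge between regions *i* and *j* is the Pearson correlation of their
mean CBF **across subjects**, computed after removing age and gender
effects by per-region linear regression. This yields one N×N correlation
matrix per group — a *covariance network*, a group-level construct in the
same family as structural covariance networks based on cortical thickness.

Each matrix is thresholded at a sparsity *s* (fraction of retained edges,
default grid 0.05–0.50 in steps of 0.01) so that both groups' networks
have exactly `round(s·N(N−1)/2)` edges. At every threshold the pipeline
computes:

- **γ** = C / ⟨C_null⟩ — clustering coefficient normalized against
  degree-matched Maslov–Sneppen rewired surrogates (default 100),
- **λ** = L / ⟨L_null⟩ — harmonic-mean characteristic path length
  (`L = N(N−1)/Σ_{i≠j} 1/d_ij`, finite under disconnection), normalized
  the same way,
- **σ** = γ/λ — small-worldness (σ > 1: clustered yet short-pathed),
- global efficiency **E_glob** and local efficiency **E_loc**,
- nodal degree/strength, nodal efficiency and betweenness centrality.

Curves over the grid are summarized by the trapezoidal **AUC**, and group
differences in AUC are tested by permutation: subjects are pooled and
randomly reassigned to pseudo-groups of the original sizes, and the whole
pipeline — residualization, correlation, thresholding, metrics, null
normalization — is recomputed under each relabeling (default 1000).
Nodal p-values share one relabeling stream and are corrected with the
false-positive rule p < 1/N (less than one expected false positive per
analysis).

Because covariance networks exist only at the group level, no public
per-subject dataset accompanies this design; the package therefore ships a
**synthetic cohort generator** (latent module factors, covariate trends,
PSD-by-construction) with plantable group effects, so every stage is
testable end-to-end.

## Worked example

```python
import json
from cbfcovnet import make_demo, run_pipeline

config = make_demo(seed=7, out_dir="demo")   # two synthetic cohorts, 90 regions
summary = run_pipeline(config)               # ~15 min on one CPU
print(json.dumps(summary["p_values"], indent=2))
```

prints (seed 7; 100 permutations, 20 nulls per threshold):

```
{
  "gamma": 0.009900990099009901,
  "lambda": 0.009900990099009901,
  "sigma": 0.009900990099009901,
  "E_glob": 0.10891089108910891,
  "E_loc": 0.019801980198019802
}
```

The demo plants the default group effect (within-module correlation
reduced by 0.2 in half of the modules, with part of the removed coupling
redistributed to diffuse cross-module factors). The patient-like group
shows clearly decreased normalized clustering γ (AUC 0.57 vs 0.93),
small-worldness σ (0.55 vs 0.85) and local efficiency E_loc (0.082 vs
0.106), while global efficiency E_glob is preserved (p = 0.11) — the
dissociation expected when a covariance network shifts toward random
topology without losing overall coupling strength. The normalized path
length λ sits near 1 for both groups (mean 1.03 vs 1.07) but its small
shift also reaches significance over the full grid in this run, because
the sparsest thresholds amplify path-length differences; see
`docs/methods.md` for why λ is the most delicate of the five measures.
`demo/results/` contains the covariance matrices, per-threshold metric
curves, AUC tables, permutation null distributions and nodal results as
TSV/CSV/JSON.

The same analysis runs from the command line:

```bash
cbfcovnet demo --seed 7 --out demo --run
cbfcovnet run --config demo/run_config.json
cbfcovnet extract --cbf-map sub01=cbf.nii --labels aal.nii \
    --parcellation aal.json --out cohort.tsv
```

`extract` turns voxelwise CBF maps plus an integer atlas volume into the
regional table (values divided by each subject's whole-brain mean CBF);
`quantify_cbf` implements the single-compartment pCASL quantification
from control/label signal pairs.

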
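# fconn

Weighted functional-connectome analysis for two-group resting-state fMRI
studies: build sparse positive correlation networks from ROI time series,
characterize them with efficiency-based small-world metrics and spectral
modularity, and infer group differences with permutation statistics.

The package targets the common clinical-neuroimaging design in which a
patient cohort and matched controls are compared at three levels of
network organization — whole-brain (global/local efficiency and their
null-normalized versions), modular (intra- and inter-module connectivity,
per-module topology) and nodal (per-region efficiency, hub-bin profiles,
module enrichment of affected regions) — with clinical covariates tied in
through partial correlations. A synthetic-cohort generator with planted
modular structure, a group effect and a covariate coupling makes the
entire pipeline testable end to end without any imaging data.

## Model

Networks are weighted graphs *G(N, K)* whose edge weights are Pearson
correlations surviving a Bonferroni threshold (α/M over the M = N(N−1)/2
pairs) with negative correlations removed. Edge length is 1/weight, and
with d_ij the resulting shortest path lengths:

```
E_glob(G)   = 1/(N(N−1)) · Σ_{i≠j} 1/d_ij
E_loc(G)    = 1/N · Σ_i E_glob(G_i)          (G_i = neighbor subgraph of i)
E_nodal(i)  = 1/(N−1) · Σ_{j≠i} 1/d_ij
Q(p)        = Σ_s [ w_s/W − (W_s/2W)² ]       (modularity of partition p)
```

Ẽ_glob and Ẽ_loc divide the observed efficiencies by the mean over 100
degree-preserving random networks. Group contrasts use 10,000-permutation
tests with one-tailed critical values at the 95th percentile of the
empirical null; node-wise and module-wise families are FDR-controlled by
Benjamini–Hochberg. See `docs/methods.md` for the full account.

## Worked example

Run the full pipeline on the built-in synthetic cohort (22 patients vs 29
controls, 128 ROIs in four modules, 160 volumes at TR 3 s; the patient
group has the within-module coherence of the largest module reduced, and
hemoglobin is coupled to every subject's coherence):

```sh
fconn run-all --synthetic --seed 1
```

which prints (a few minutes on one CPU):

```
partition: Q=0.707 modules=4 sizes=[40, 31, 36, 21]
e_glob: diff=-0.0377 p=9.999e-05 (less)
e_loc: diff=-0.1089 p=9.999e-05 (less)
e_glob_norm: diff=-0.0020 p=0.439 (less)
e_loc_norm: diff=-0.0649 p=0.9647 (greater)
flagged nodes: 40
enrichment p per module: [0.0001, 1.0, 1.0, 1.0]
partial r(e_glob, hemoglobin) = 0.839 (p=2.589e-05)
```

Reading this output: the control-group backbone decomposes into exactly
the four planted modules (Q = 0.707). Patients show significantly lower
global and local efficiency (one-tailed permutation p ≈ 1e-4, the
resolution floor at 10,000 permutations). Node-wise comparison flags 40
regions with decreased nodal efficiency after FDR correction — precisely
the 40 nodes of the affected module, and the enrichment test localizes
them there (p = 1e-4 in module 0, p = 1 elsewhere). Within patients,
global efficiency correlates positively with hemoglobin (partial r =
0.84 controlling age, sex and head motion), recovering the planted
anemia effect. The normalized efficiencies show no significant group
difference in this synthetic regime.

The same analysis is available as a library call:

```python
from fconn import RunConfig, run_group_pipeline
bundle = run_group_pipeline(RunConfig(seed=1))
bundle.results["global_tests"]["e_glob"]   # {'observed_diff': -0.0377, ...}
```

Other CLI stages (`simulate`, `preprocess`, `network`, `metrics`,
`modules`, `stats`) operate on TSV artifacts for piecemeal or
cross-language use; `--out` directories receive TSV/JSON tables plus
BrainNet-viewer `.node`/`.edge` files for surface rendering.

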
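# Methods

`fconn` implements a complete weighted functional-connectome group
analysis: ROI time-series conditioning, Pearson-correlation network
construction with significance thresholding, efficiency-based small-world
metrics normalized against degree-preserving null models, spectral
modularity detection, and nonparametric group inference. Because no public
imaging data accompany the analysis design it emulates, a first-class
synthetic-cohort generator supplies the inputs; every downstream stage is
specified, tested and benchmarked against that generator's known ground
truth.

## Network model and metrics

Each subject yields an undirected graph *G* with *N* nodes (ROIs) and *K*
edges. Edge weights are the Pearson correlations that survive a two-sided
significance threshold of α/M (Bonferroni over the M = N(N−1)/2 unique
pairs, α = 0.05, p from the t transform of r with df = retained volumes −
2) and are strictly positive; negative correlations are discarded. Edge
*length* is the reciprocal of weight, so strong coupling is a short
functional distance.

With d_ij the shortest path length over these lengths:

- **Global efficiency**  E_glob(G) = (1/(N(N−1))) Σ_{i≠j} 1/d_ij
- **Nodal efficiency**   E_nodal(i) = (1/(N−1)) Σ_{j≠i} 1/d_ij
- **Local efficiency**   E_loc(G) = (1/N) Σ_i E_glob(G_i), where G_i is
  the subgraph induced by i's neighbors (original inter-neighbor weights;
  nodes with fewer than 2 neighbors contribute 0)

Unreachable pairs contribute 1/∞ = 0, the standard convention that keeps
all metrics finite on disconnected graphs; isolated nodes are counted in
N. The node-average of E_nodal equals E_glob exactly, which the report
bundle asserts as an internal-consistency check.

Normalized efficiencies Ẽ = E(real) / mean(E(null)) use an ensemble of
100 random networks per subject that preserve N, K and the full degree
sequence via Maslov–Sneppen double-edge swaps (~10·K attempted swaps per
null; attempts creating self-loops or multi-edges are rejected). The
original weight multiset is randomly permuted onto the rewired topology —
the strength-preserving alternative is a recognized variant but the plain
multiset permutation is the default here. A network is called small-world
when Ẽ_loc > 1 and |Ẽ_glob − 1| ≤ 0.25 (tolerance configurable).

## Modularity

For a partition p, Q(p) = Σ_s [ w_s/W − (W_s/(2W))² ] with W the total
edge weight counted once per edge, w_s the intra-module weight and W_s
the summed nodal strength of module s. This normalization is internally
consistent exactly when W counts each edge once while strengths count
both endpoints; the two-disconnected-cliques oracle (Q = 0.5, the
canonical value) pins that reading down.

Modules are found by recursive leading-eigenvector bisection of the
(generalized) modularity matrix, with greedy single-node sign flips after
each bisection until no flip raises Q, stopping when no split yields a
positive ΔQ. Connected components are partitioned independently.
Eigenvector sign ambiguity is resolved by forcing the first nonzero
component positive, making the algorithm deterministic.

The group-level reference network averages the control subjects' raw
correlation matrices through Fisher's r-to-z, then sparsifies with a
locally adaptive filter: edge (i, j) is kept when it ranks in the top
`local_alpha` fraction (default 0.05) of the incident positive weights of
node i *or* node j, with strict-rank ties so every node keeps its
top-ranked edge(s). The published analysis this emulates cites a
nonparametric sparsification method whose algorithm is not specified in
the text; this filter is a reconstruction with the same intent
(multiscale backbone retention), not a reimplementation of that exact
method. If the backbone connects fewer than 95% of nodes, `local_alpha`
doubles with a logged warning until connectivity or saturation.

## Inference

Group contrasts use label permutation (default 10,000 draws) on the
difference of group means, preserving group sizes; p-values use the
add-one convention (#{null ≥ obs}+1)/(n_perm+1) and the 95th percentile
of the null is reported as the one-tailed critical value. Directions are
pre-specified: patients < controls for raw efficiencies and connectivity,
patients > controls for Ẽ_loc. Head-motion summaries (max/RMS/mean
framewise displacement, Power-style with 50 mm head radius) are
residualized out of the pooled values before permuting.

Node-wise comparisons produce per-node one-tailed permutation p-values
corrected by Benjamini–Hochberg over all nodes (one family); module
connectivity tests form a single BH family over all intra- and
inter-module pairs (the alternative family of intra terms only is
narrower; the full family is the conservative default). Flagged-node
concentration in modules is tested by drawing |flagged| nodes without
replacement (multivariate hypergeometric sampling, 10,000 draws) and
comparing per-module counts; this estimator agrees with the exact
hypergeometric tail within Monte-Carlo error, which the tests verify.

Hub analysis bins each subject's nodal values into 8 equal-width bins
between that subject's min and max and compares per-bin percentages
across groups. Binning defaults to nodal efficiency; a switch selects
nodal strength (the emulated analysis describes both in different
places — a genuine ambiguity surfaced as an option rather than resolved
silently).

Clinical statistics: partial correlations are Pearson correlations of OLS
residuals (complete cases; p from t with df = n − k − 2); demographic
tables use Pearson chi-square without continuity correction for
categorical variables and pooled-variance two-sided t tests for
continuous ones; serum calcium is albumin-corrected by Payne's formula
(Ca + 0.02·(40 − albumin), mmol/L with albumin in g/L).

## Synthetic cohort

The generator emulates a 22-patient vs 29-control resting-state study:
160 volumes at TR = 3 s, with the scaled-down default of 128 ROIs in four
modules of 40/31/36/21 nodes (proportional to a 1,024-parcel atlas split
317/250/289/168; the full scale is available via `full_scale_spec`).

Each ROI's signal is a band-limited factor mixture

    y = a·(√q·f_m + √(1−q)·h_roi) + b·g + σ·ε

with module factor f_m, ROI-private factor h_roi, global factor g (all
unit-variance, spectrally confined to 0.01–0.1 Hz by frequency-domain
masking of white noise — exact band control, no filter transients), and
white noise ε. The shared factors are QR-orthogonalized per subject so
their sample correlations are exactly zero; without this, chance factor
covariances at 155 retained volumes generate heavy-tailed bursts of
spurious cross-module edges that dominate the efficiency metrics at this
network size.

The coherence fraction q ∈ (0, 1] is the carrier of all planted effects.
Because the split √q·f_m + √(1−q)·h keeps every ROI's variance at
a² + b² + σ², population correlations are closed-form —

    within module:   (q·a² + b²) / (a² + b² + σ²)
    between modules: b² / (a² + b² + σ²)

— and, critically, between-module correlations do not depend on q. An
earlier design that scaled the factor *loading* instead was abandoned:
shrinking a module's loading shrinks those ROIs' variance, which inflates
their Pearson correlations with everything else (the shared factor gains
relative weight), so the "weakened" module paradoxically raised
whole-network efficiency. Acting on coherence plants a clean effect:
patients have q multiplied by `patient_effect²` (default 0.6², i.e. the
module-shared loading scaled by 0.6) in the largest module, lowering
intra-module connectivity and nodal efficiency there while leaving
inter-module connectivity exactly unchanged — the pattern the emulated
study reports.

Hemoglobin couples to q through q = 1 + c·(z − 1) clipped to [0.05, 1],
where z standardizes hemoglobin within group and c = 0.15. Full coherence
is reached one SD above the group mean so the modulation is effective
over most of the range; with the knee at the mean itself, half of each
cohort saturates and the planted efficiency–hemoglobin partial
correlation halves (≈0.4 instead of the ≈0.8 the emulated study
reports). Patient hemoglobin is drawn from N(95.4, 22.6) g/L; controls
from N(135, 10) g/L (population-normal; the study publishes only patient
values). Other covariates (age, sex, calcium in mmol/L, albumin,
dialysis duration) follow the published group summaries.

Default loadings a = 0.6, b = 0.25, σ = 0.7 give post-band-pass
within-module correlations ≈ 0.6 and between-module ≈ 0.09 — realistic
magnitudes for within- vs between-network BOLD coupling. At the
scaled-down Bonferroni threshold (r ≈ 0.35 at 128 ROIs) between-module
edges are largely sub-threshold, so individual networks are
module-dominated with sparse bridges, and normalized global efficiency
sits near 0.7 rather than the ≈0.8–1 of real cortical networks: the
strict small-world check fails for most synthetic subjects even though
the planted group effects are fully recoverable. Motion is a small
random walk (0.05 mm / 0.02° steps); WM/CSF confounds are independent
band-limited series carried alongside each subject.

What the generator does not emulate: hemodynamic response shape, spatial
autocorrelation between neighboring parcels, physiological noise
structure, distance-dependent motion artifacts, or any image-space
effect. Passing tests therefore demonstrate correctness of the analysis
machinery and recoverability of factor-model effects, not performance on
real fMRI.

## Numerical choices

- Shortest paths: Dijkstra (scipy.sparse.csgraph) on the full network;
  Floyd–Warshall (numba-compiled) on the small neighbor subgraphs of the
  local-efficiency sum. Both verified against a brute-force oracle to
  1e-9.
- The Maslov–Sneppen attempt loop is numba-compiled; with ~2,000-edge
  networks and 100 nulls per subject the pure-Python loop was the
  pipeline bottleneck.
- Correlations at |r| = 1 off-diagonal are clipped to ±0.999999 before
  Fisher averaging; constant ROI columns correlate as 0 with a warning.
- Detrending is ordinary least squares (intercept + slope); the band-pass
  is a zero-phase rFFT mask with a 2-bin raised-cosine roll-off at each
  band edge, DC always removed.
- Nuisance regression uses the pseudoinverse, so rank-deficient designs
  degrade gracefully (equivalent to dropping collinear columns) and the
  operation is idempotent.
- Permutation tests vectorize label permutations via argsort of uniform
  draws; enrichment draws use `Generator.multivariate_hypergeometric`.
- All randomness flows through numpy Generators seeded from named
  SeedSequences derived from the single run seed; reruns are bit-identical.

## Problem sizes

The default configuration (51 subjects, 128 ROIs, 100 nulls per subject
and per module, 10,000 permutations/draws) was chosen so a complete run —
generation through statistics — finishes in a few minutes on one CPU
core, while preserving the emulated study's sample sizes, volume count,
TR, permutation count and null-ensemble size. The 1,024-ROI full-scale
spec is provided for users who want the original network size.

## Known limitations

- The backbone filter is a reconstruction (see above), and backbone
  density depends on the relaxation loop when the group network is
  module-dominated.
- One-tailed directions must be pre-specified; the package does not
  choose directions from the data.
- The permutation and enrichment p-values are Monte-Carlo estimates with
  resolution 1/(n_perm+1).
- Efficiency normalization uses topology-preserving nulls only; no
  lattice reference, so no small-world σ-style index is computed.
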
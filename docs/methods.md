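# Methods notes

This note records the modelling conventions, numerical choices and known
limitations behind `forestnets`, in the order of the analysis pipeline.

## Competition networks

Trees are points P_i in a planar window with crown radii R_i (metres).
Three graphs are defined on them:

- **CS** — undirected edge iff 0 ≤ ‖P_i − P_j‖ < d_max, default
  d_max = 10 m, a commonly used extent of tree–tree interaction. Crown
  data are not needed, so CS keeps every tree.
- **CL** — undirected edge iff ‖P_i − P_j‖ < R_i + R_j (crown discs
  overlap). Trees with a missing or non-positive crown radius are dropped
  from CL/WCL (the count is logged); this is why a crown network can have
  fewer nodes than the CS network on the same plot.
- **WCL** — each CL overlap contributes two directed edges weighted by the
  competition index CI_ij = R_ij · R_i/R_j, R_ij = (R_i + R_j) − ‖P_i − P_j‖.
  The index is asymmetric (the larger crown competes harder) and satisfies
  CI_ij · CI_ji = R_ij², which the test suite checks on every edge.

Tie-breaking: all comparisons are strict, so a pair at exactly d_max or
with tangent crowns is *not* connected. Coincident treetops are permitted
and maximally overlapped rather than rejected. Distances are Euclidean; no
toroidal wrap-around.

## Network metrics

Density D = 2E/(N(N−1)), average degree k = 2E/N, clustering coefficient
C = (1/N) Σ_i 2e_i/(k_i(k_i−1)) with nodes of degree < 2 contributing 0
(avoids 0/0), and average path length L = the mean shortest-path hop count.
All four are computed on the undirected, unweighted skeleton; for WCL they
therefore equal the CL values, and only the weighted average degree
k_w = 2·ΣCI/N uses the weights. Two conventions for k_w exist because
"replace E by the sum of edge weights" is ambiguous on a directed graph;
the factor-2 literal substitution is the default and `factor=1` is exposed.
Similarly L on the directed WCL graph (ordered pairs) is available via
`average_path_length(net, directed=True)`; with mutual edges it coincides
with the skeleton value, but neither convention is declared canonical.

L is undefined on an edgeless graph (error) and averages over *connected*
pairs only on disconnected graphs, with the connected-pair count reported —
sparse null realizations are routinely disconnected and would otherwise
have infinite L. Betweenness is unnormalized shortest-path betweenness with
endpoints excluded (networkx), reported per node id.

Spatial fields of node metrics use a thin-plate-spline RBF on the node
locations, evaluated on a regular grid (default spacing 2 m). The smoothing
parameter is 0 for exact interpolation or chosen by 5-fold cross-validation
over a log grid (default); at least four non-collinear nodes are required.

## Spatial null models

All five simulators share a rectangular window (default 200 m × 200 m) and
a target tree intensity κ = 0.015 m⁻² (≈ 600 trees), and attach crown radii
by random labelling — i.i.d. marks independent of locations — either
U(2, 5) m (default) or a gamma distribution fitted to data.

- **CSR**: N ~ Poisson(κ|W|), locations i.i.d. uniform.
- **Matérn cluster**: parents are Poisson with intensity κ/μ in the window
  dilated by r_d; each parent emits Poisson(μ) offspring uniform in the
  disc of radius r_d and then dies; offspring outside the window are
  clipped. Defaults μ = 3, r_d = 5 m. Simulating parents in the dilated
  window avoids border thinning. κ counts *trees*, so every model has the
  same expected intensity; the alternative reading (κ counts parents,
  trees at κμ) is available as `kappa_is_parent=True`.
- **Thomas cluster**: as Matérn with an isotropic Gaussian displacement.
  The dispersal radius is mapped to the Gaussian scale as the 95% dispersal
  radius: σ = r_d/√(2 ln 20) ≈ r_d/2.448. This keeps the Thomas clusters
  tighter than the Matérn disc of the same r_d, which is what makes the
  Thomas process the most aggregated of the five models (highest
  crown-overlap edge counts, highest small-scale L(r) envelope). σ can be
  set explicitly.
- **Hard-core (HC)** and **Strauss**: Gibbs inhibition models with the
  density β^n γ^{s(x)}, where s(x) counts pairs closer than r_g (default
  4 m), γ = 0 for HC and γ = p (default 0.5) for Strauss. They are
  simulated by a birth–death Metropolis–Hastings chain with activity
  β = κ: births at uniform locations accepted with probability
  min(1, β|W|/(n+1) · γ^m), deaths with min(1, n/(β|W|) / γ^m), for
  max(30000, 50·β|W|) proposals from an empty start. Realized intensity is
  *below* κ because of the inhibition (≈ 0.009 for HC at defaults) — the
  standard behaviour of these processes when κ is the activity. A
  conditional variant with exactly round(κ|W|) points (`fixed_n=True`) uses
  a remove-and-replace chain (uniform victim, uniform proposal, accepted
  with probability γ^m of the proposal, hard core requires m = 0) with
  10·N minimum sweeps, a 10⁶-proposal cap, and a convergence error naming
  the proposal count if violations remain; note that fixing N forces the
  displaced pairs just outside r_g and pushes the degree metrics back
  toward CSR, so the activity variant is the default for validation work.
  Infeasible packings (> 0.9 disc coverage) are rejected up front.

Reproducibility: every simulator is deterministic given (config, seed).
Batteries give replicate i of *every* model the simulation stream keyed by
`(seed, i)` (crown marks use a separate stream), so runs are reproducible
end-to-end, distinct master seeds give unrelated batteries, and model
comparisons are partially paired — Matérn and Thomas replicates share
parent randomness, which sharpens their mean-edge-count comparison at no
cost.

### What the generator does and does not emulate

The simulators reproduce the first- and second-order spatial structure the
validation needs (intensity, clustering, inhibition) and random crown
labelling. They do not emulate size–location correlations (large trees in
gaps), species structure, habitat heterogeneity (all processes are
homogeneous), or measurement error in crown delineation. Passing the
validation battery therefore shows a metric separates *these* idealized
processes; on real data, inhomogeneity can mimic clustering and correlated
marks can shift the crown-network metrics, which is exactly why the
empirical comparison re-estimates κ and the crown distribution from the
data being analysed.

## Second-order statistics

K̂(r) = |W|/(N(N−1)) · Σ_{i≠j} e_ij 1[d_ij ≤ r], with Ripley's isotropic
edge correction by default: e_ij is the reciprocal of the fraction of the
circle centred at P_i with radius d_ij that lies inside W, in closed form
for a rectangle via the two nearest borders and their shared corner (valid
while r < half the shorter side; the default grid — 513 points from 0 to a
quarter of the shorter side — stays well inside, and a warning fires past
the quarter-side guideline). The translation correction
|W|/((W−|dx|)(H−|dy|)) and no correction are available by flag. The tests
pin both corrections to naive double-loop implementations, with the
isotropic circle fraction checked against an independent arc-decomposition
oracle to 1e-9.

L(r) = √(K(r)/π), optionally centered (L − r). The pair correlation
function uses the same corrections with an Epanechnikov kernel of bandwidth
h = 0.15/√λ̂ (Stoyan's rule) and requires a strictly positive r grid (g
diverges at 0).

Envelopes are pointwise min–max bands over n_sim simulations (classical
rank-1 Monte-Carlo acceptance bands, 199 simulations by default, replicate
streams keyed by `(seed, i)`); no global correction is applied, matching
the usual pointwise reading of such envelopes.

## Validation workflow

A battery runs n_sim replicates per model (default 199), builds the
requested networks per replicate and collects metric bundles; a failed
replicate is retried once with a shifted stream and otherwise dropped with
a log entry, never silently resampled. Metrics are compared across models
by classical one-way ANOVA plus Tukey HSD at α = 0.05 (statsmodels) and a
range-overlap matrix. The *distinguishing* verdict is a deliberately strict
codification: every cross-group pair (cluster vs CSR vs Gibbs) must be both
Tukey-significant and range-disjoint; within-group pairs (Matérn vs
Thomas, HC vs Strauss) are not required to separate. Groups with zero
variance are handled explicitly (identical constant groups ⇒ F = 0,
p = 1). ANOVA is used on possibly non-normal metric distributions by
design — it is the conventional choice for this workflow — and the
comparison report keeps the Tukey table and the range matrix separate so a
rank-based re-analysis can be layered on.

The empirical comparison estimates κ̂ = N/|W| from the observed stem map
(tree density, hence the total-intensity convention for cluster models),
fits the crown-radius gamma distribution by maximum likelihood (origin
fixed at 0; constant radii are a documented error), simulates all five
batteries on the observed window, and reports each observed metric's
percentile (mean-rank convention) and an in-range flag per model.

Sensitivity sweeps are one-at-a-time: each value of each swept parameter
(κ, μ, r_d, r_g, p) overrides every model it applies to and runs a full
battery, stacked with parameter annotations.

## Problem sizes used in tests and the acceptance script

The test suite validates estimators on small instances where exhaustive
oracles are exact (graphs ≤ 12 nodes, patterns ≤ ~110 points, 500-tree
brute-force network checks) and runs the distributional checks at the
default study conditions: the full 5 × 199 battery for cardinality, a
50-replicate battery for the ordering/separation properties, 99 replicates
for estimator calibration and envelope checks (39 inside the test suite for
the envelope, 99 in the acceptance script). These sizes are the package's
own choice of where Monte-Carlo error is comfortably below the effects
being asserted.

## Known limitations

- Homogeneous processes only; no inhomogeneous or covariate-driven nulls.
- Univariate statistics only; no cross-type/bivariate K, mark-correlation
  functions, or global envelope tests.
- The competition index is the crown-overlap kernel above; other
  size–distance kernels are out of scope.
- The isotropic correction's closed form assumes a rectangular window.
- Gibbs chains are finite-length MCMC: extreme parameter combinations
  (near-jamming packings with `fixed_n`) can fail to converge, which is
  reported as an error rather than a biased sample.
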
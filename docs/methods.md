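# Methods

This note describes the models implemented in `sctransport`, the numerical
choices behind them, and what the synthetic fixtures do and do not
demonstrate.

## The transport model

All problem classes produce a **coupling** `P`: a non-negative matrix whose
entry `P_ij` is the probability mass moved from source observation `i`
(a cell, nucleus, spot or spatial bin) to target observation `j`. The row
and column sums of `P` are constrained to prescribed marginal vectors
`a` and `b` — the prior weight each observation carries.

### Entropic W-type problems

The balanced problem minimises `<C, P> - eps * H(P)` over couplings with
exact marginals, where `C` is a pairwise cost between source and target in
a shared representation and `H(P) = -sum P (log P - 1)` is the entropy
regulariser. Entropic smoothing makes the problem strongly convex and
solvable by Sinkhorn scaling iterations; larger `eps` gives a blurrier
plan, and as `eps -> infinity` the plan converges to the independence
coupling `a b^T`. All iterations run in the log domain: the scaled-variable
form of the iteration overflows once `eps` is small relative to the costs,
while the log-domain form is algebraically identical and stable.
Convergence is declared when the L1 deviation of the realised marginals
drops below a tolerance (default `1e-6` in the solver core); the deviation
is always reported on the returned coupling, never silently discarded.

### Unbalanced marginals

Sampling biases and noisy growth priors argue against enforcing marginals
exactly. The unbalanced variant replaces each hard constraint with a
KL-divergence penalty of weight `rho = eps * tau / (1 - tau)`,
`tau in (0, 1]`; the generalised Sinkhorn iteration raises the scaling
updates to the power `tau`. `tau = 1` is implemented as the exact balanced
constraint rather than a large finite weight. Because the marginals are
intentionally allowed to drift, convergence is declared on the fixed point
of the dual potentials, and the realised marginal deviation is reported.

### Low-rank couplings

For large populations the plan is constrained to
`P = Q diag(1/g) R^T` with `Q in U(a, g)` and `R in U(b, g)`, where `g` is
a positive inner weight vector of length `rank`. Optimisation is mirror
descent on the factors: the gradients of the transport cost are
exponentiated into KL kernels with an adaptive step `lr_gamma / ||grad||_inf`
and the triple is re-projected onto its coupling constraints by an
alternating-Sinkhorn inner loop. The shared inner weight satisfies
`g^3 = K3 (K1^T u1)(K2^T u2)` elementwise at the projection fixed point,
giving a cube-root update; `g` is floored at `1e-10` to prevent component
collapse. The objective is non-convex, so the solver runs one deterministic
initialisation (equivalent to the independence plan, which guarantees the
result never does worse than the rank-1 solution) plus Dirichlet random
restarts controlled by `seed`, and returns the best iterate. The default
step size `lr_gamma = 100` works across the fixture sizes used here and is
configurable.

### Gromov-Wasserstein and fused problems

When source and target live in different spaces (expression vs physical
coordinates, or two slides' coordinate frames), couplings are scored by
structural correspondence: the GW objective
`sum_ijkl (Cx_ij - Cy_kl)^2 P_ik P_jl` compares within-space distance
matrices. The solver is mirror descent: the squared-loss decomposition
turns the gradient into two matrix products; each outer step solves an
entropic W problem on the linearised cost, warm-started from the previous
potentials, until the plan stops changing. The fused (FGW) problem blends
a feature term and a structural term with weight `alpha`:
`alpha = 0` reduces exactly to the W problem and `alpha = 1` to GW, and
these reductions are tested to solver tolerance. Unbalanced marginals,
when requested, apply inside the inner W solves.

The GW objective is non-convex and plain mirror descent at small `eps`
stalls in shallow local optima (observed directly on 5-point instances).
The solvers therefore anneal the regularisation: it starts at 5% of the
mean absolute linearised cost and halves per outer iteration down to the
requested `eps`; convergence is only declared at the target value.
Annealing is on by default and can be disabled.

### Sinkhorn divergence

Coupling stability is compared with the debiased divergence
`S_eps(mu, nu) = OT_eps(mu, nu) - (OT_eps(mu, mu) + OT_eps(nu, nu)) / 2`,
where each `OT_eps` is the transport cost plus `eps` times the KL
divergence of the plan from the product measure. Histograms are lifted off
zero by `1e-12` so the solver's strict-positivity requirement holds on a
shared support; the inner solves run at tolerance `1e-12` so symmetry and
non-negativity hold to `1e-9`.

## Problem classes

**Temporal.** Consecutive time points are coupled on a phenotypic cost
(squared Euclidean, cosine, or graph-geodesic distance on a chosen
representation; costs are mean-scaled by default so `eps` is comparable
across problems). The left marginal encodes growth: either the birth–death
form `a_i ∝ g(x_i)^dt` with `g = exp(beta - delta)` (which normalises to a
probability vector by construction), or the score-difference form
`a_i ∝ exp((p_i - q_i) / c)`. The latter is not normalised as written;
since a marginal must carry fixed total mass, it is renormalised before
use — a deliberate, documented choice. The scale `c` has no natural
default and is a required parameter. The right marginal is uniform by
default. Multi-time-point chains compose by matrix multiplication under
the Markov assumption. Push (`P^T p`) and pull (`P q`) operations yield
descendant and ancestor distributions; aggregating the plan over
annotations gives transition tables (zero-mass rows are kept as zero rows,
not NaN); correlating pull/push densities with expression ranks putative
driver and target genes (Spearman ties by average ranks; zero-variance
features are NaN and excluded from ranking).

Realised marginals convert to biological growth rates as
`g_i = N a_i s`, with `s` the population-size ratio between the time
points; the apoptosis rate is `sum_(g_i < 1) (1 - g_i) / N`.

**Fate probabilities.** A block Markov chain is assembled over all time
points: row-normalised couplings on the superdiagonal (weight 0.9 by
default) and within-time similarity on the diagonal (weight 0.1); the last
time point keeps its within-time block at full weight. Terminal states are
caller-supplied label sets (terminal-state *discovery* is out of scope);
they are made absorbing and absorption probabilities are computed by the
exact linear solve `(I - T) B = R`, not power iteration.

**Spatial mapping.** A dissociated reference maps onto spatial units by
FGW: the linear term compares expression on shared features, `C^X` is
molecular similarity among reference cells (multimodal inputs enter by
variance-normalised concatenation), `C^Y` is physical similarity
(squared Euclidean on coordinates, or a spatial-graph geodesic).
Imputation and annotation transfer use the **column-normalised** plan, so
every imputed value is a convex combination of reference values and
annotation likelihood rows sum to one. The raw-plan projection `P^T X`
applied to probability-mass couplings would rescale all values by roughly
`1/M`; the normalised convention is the one that makes likelihoods
interpretable, and the divergence from the literal projection formula is
deliberate.

**Spatial correspondence.** The diagnostic that justifies the structural
term: `n` quantile thresholds discretise the pairwise spatial distances,
each pair is assigned the smallest covering threshold, and the statistic
is the Pearson correlation between pairwise expression distance and the
assigned threshold over all pairs. An alternative — correlating the
per-threshold *means* of the cumulative pair sets against the thresholds —
was evaluated and rejected: nested cumulative means form a smooth
stochastic drift whose correlation with any monotone sequence is
scale-free, so even spatially structureless expression scores high
(|rho| up to ~0.9 observed under an i.i.d. null). The pair-level form
concentrates near zero under the null and above 0.9 for
coordinate-coupled constructions.

**Spatial alignment.** Slides couple pairwise by FGW (expression linear
term; within-slide coordinate distances in the quadratic terms, after
centering and scaling to unit median pairwise distance per slide — the
original frame is restored on output). Policies: sequential (consecutive
pairs) or star (all queries against one reference). Coordinates transfer
by the nonlinear warp — each source point goes to the row-normalised
plan-weighted barycenter of its partners, hence always inside the target's
convex hull (row normalisation is again the deliberate reading of the raw
projection) — or by a weighted least-squares affine map minimising
`sum_ij P_ij ||A z_j + t - z_i||^2`, the closed-form solution of which is
a weighted cross-covariance times the inverse weighted target covariance.
How the affine map should be extracted from a soft coupling is not
canonical; weighted least squares is this package's documented choice. A
second W-type solve on the aligned coordinates ("refinement") sharpens
blurred or low-rank first passes. For affine registration the package
additionally provides an alternating polish (`refine_affine`): a rigid
map extracted from the FGW coupling by weighted orthogonal Procrustes
seeds repeated rounds of an unbalanced W solve on the transformed
coordinates followed by a refit, and the final coupling yields the full
least-squares affine. The internal rounds are rigid because the free
least-squares fit of a blurred coupling attenuates scale (regression to
the weighted centroid), which corrupts the next round's neighbour
matching; the orthogonal fit has no scale to attenuate. The left marginal
is relaxed (`tau_a = 0.5` by default) so source points with no true
partner — inevitable when the partner slide is subsampled — shed mass
instead of distorting the fit; three rounds reduce
rotation-recovery errors from degrees to hundredths of a degree on the
rigid-motion fixtures. The rotation check in the acceptance suite uses
the full pipeline FGW → affine → alternating refinement.

**Spatiotemporal.** The alignment model applied across time: expression in
the linear term, within-time-point spatial structure in the quadratic
terms, growth-adjusted left marginal. `alpha = 0` reduces exactly to the
temporal model. Annotations present only at the latest time point
propagate backward: per coupling, each earlier observation takes the
argmax of its plan mass aggregated over current target annotations; ties
break by larger pre-normalisation mass, then lower label index.

**Sparse Monge maps.** From a converged balanced Sinkhorn solve with the
translation-invariant cost `h(z) = 0.5 ||z||^2 + gamma ||z||_1`, the
target-side dual potential defines a deterministic map: softmax weights
`p^j(x) ∝ exp((g_j - h(x - y_j)) / eps)` and
`T(x) = x - ST_gamma(x - sum_j p^j(x)(y_j + gamma sign(x - y_j)))` with the
soft-threshold `ST_gamma(z) = (1 - gamma/|z|)_+ z`. At `gamma = 0` this is
exactly the squared-Euclidean entropic map. Coordinates whose displacement
the threshold zeroes are exactly unchanged, so each cell acquires a sparse
set of "important" features (displacement above `1e-6` by default);
per-annotation relevance is the fraction of that annotation's cells
carrying the feature. Neighbourhood dissimilarity is one minus the mean
pairwise Jaccard similarity between a cell's set and each of its k nearest
neighbours' sets (the set-vs-union variant is available as an option; the
phrase "similarity to the neighbourhood" is ambiguous between the two and
the mean-of-pairwise reading is the default). The map-fitting Sinkhorn
uses an L1 marginal tolerance of `1e-4`: at `eps` far below the cost scale
the tail of Sinkhorn convergence is slow, and the softmax weights are
insensitive at that level.

## Evaluation metrics

**Transition accuracy.** For a row-normalised transition table and a
curated set of allowed (source, target) label pairs: edges below 0.05 are
dropped, and the score is the weight of allowed retained edges over the
weight of all retained edges. The germ-layer variant is the same operation
after mapping labels to layer ids, with exceptions supplied by the caller.

**clTOME baseline.** A cell-level kNN coupling: over repeated subsamples
(default 500 draws of 80% of both time points), each target cell gives
`1/k` mass to its k nearest source cells in a shared representation;
subsamples weigh equally and the accumulated matrix is column-normalised
so every target cell receives unit incoming mass.

**Cell-cycle direction score.** For the 5x5 row-normalised phase table
over (G1S, S, G2M, M, MG1), `score = sum_i (A[i,i+1] - A[i,i-1])` with
cyclic indices. The permutation null shuffles the 20 off-diagonal values
uniformly among off-diagonal positions (whether rows should be preserved
is unspecified; the global shuffle is the documented choice); the
one-sided p-value uses add-one smoothing. Calibration (type-I error
0.05 ± 0.02 at nominal 0.05 over 500 null replicates, n_perm = 999) is
checked in the acceptance suite.

**Alignment gene-consistency.** Per gene, cells with zero expression are
dropped; each reference cell gathers its k nearest query cells in aligned
space, and the 1-D L1 Wasserstein distance between the neighbour
expression values and the reference expression values is reported,
together with the correlation of distance against mean expression as a
robustness diagnostic.

## Synthetic fixtures

The generators are pure functions of their arguments (including the seed)
and store the planted ground truth needed by every recovery metric.

* **Temporal mixtures**: Gaussian clusters with centres equispaced on a
  line (`k * sep` along the first axis, isotropic noise `noise_sd = 1`,
  `sep = 6` by default, i.e. six noise standard deviations). Cluster sizes
  evolve by a planted row-stochastic transition with per-cluster growth;
  sizes at each time point are multinomial draws. Centres are collinear by
  design: with squared-Euclidean cost on a line, the cluster-level
  transport optimum is the unique monotone rearrangement, so forward-chain
  transition matrices are identifiable from the coupling. With equidistant
  (simplex) centre configurations the cluster-level optimum is degenerate
  and no particular planted matrix could be recovered by any transport
  method — recovery tests would be meaningless. The default planted
  transition is a forward developmental chain (70% stay, 30% advance).
* **Spatial grids**: `side x side` coordinates with either i.i.d. normal
  expression (no spatial structure; the null case) or coordinate-coupled
  expression — an isometric (orthonormal-loading) linear readout of the
  coordinates plus mild sinusoidal curvature and noise, so expression
  distance tracks spatial distance.
* **Slide pairs**: a rigid motion (rotation + translation) of a common
  point set with expression noise and subsampling; the correspondence is
  stored.
* **Multimodal blocks**: two modalities as linear readouts of one latent
  factor matrix plus independent noise.
* **Cycle chains**: five phases on a circle; each time-2 cell advances one
  phase with probability `forward_bias`, making the ground-truth phase
  table computable in closed form.

What passing on these fixtures does **not** show: the generators draw
Gaussian (not count-distributed) expression with no dropout, no batch
effects, no doublets and no library-size variation, and planted structure
is low-dimensional and well separated. Recovery results demonstrate the
correctness of the algorithms under their own assumptions, not performance
on real single-cell or spatial data.

## Problem sizes and tolerances

The test and acceptance workloads run at desk scale by design: solver
oracle checks at n ≤ 6 (where exact LP optima are enumerable), structural
recovery at 40–80 observations, temporal recovery at 200 cells per time
point over 20 seeds, and permutation/null calibrations at 100–500
replicates. Key defaults: `eps = 1e-2` on mean-scaled costs for
production-style solves, solver tolerance `1e-6`, GW/FGW plan-change
tolerance `1e-6` with annealed regularisation, `lr_gamma = 100`,
`w_ot = 0.9` for kernel assembly, edge threshold 0.05 for transition
scoring. Degenerate inputs are handled explicitly: all-zero cost matrices
pass scaling untouched (single-observation problems), zero-mass transition
rows stay zero, empty important-feature sets get dissimilarity 1 and are
flagged, and disconnected geodesic graphs raise with component sizes
rather than returning infinities.

## Known limitations

* Costs are always materialised densely; there is no on-the-fly cost
  evaluation, so memory is quadratic in observations. The low-rank solver
  reduces plan storage, not cost storage.
* The unbalanced FGW inner solves relax marginals per iteration; the
  composite objective for the unbalanced fused case is reported from its
  parts rather than from a single variational formulation.
* Mirror descent on GW/FGW finds local optima; annealing makes recovery
  reliable on the fixture geometry used here but carries no global
  guarantee.
* The heat-kernel diffusion distance is not implemented; the graph
  geodesic (shortest paths on a symmetrised kNN graph, union
  symmetrisation, ties by observation index) is the documented
  manifold-respecting cost.
* Backward annotation propagation assigns hard argmax labels; uncertainty
  is not propagated between steps.
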
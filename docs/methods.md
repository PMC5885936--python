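# Methods

## Data model and assumptions

The pipeline consumes a cohort of `n` subjects × `p` cortical regions of
thickness (mm, strictly positive), a numeric covariate matrix (binary
covariates coded 0/1), and a per-subject group label. It assumes thickness is
approximately multivariate normal within groups after linear covariate
adjustment — the Pearson machinery underlying partial correlations — and
that subjects are exchangeable within groups. Missing covariate values are a
hard error: silent imputation would make the residualization, and therefore
every downstream network, irreproducible from the shipped inputs. Subject
alignment across the three input tables is by id intersection, with the
thickness table's row order winning, so assembly is deterministic and
auditable.

## Variance screen

Regions whose thickness variance differs between any pair of groups are
excluded before network construction (two-sample F test,
`F = s²_x/s²_y`, two-sided p by doubling the smaller tail of
`F(n_x−1, n_y−1)`, default α = 0.01, no multiple-testing correction). The
"any pair fails ⇒ drop globally" rule keeps the region set identical across
all downstream comparisons. The exclusion list is data-dependent by design;
`variance_alpha = 0` disables the screen, which is appropriate when a
variance difference is itself the effect under study (the synthetic
planted-hub experiments are an example: a planted loading λ inflates the
planted group's variances by construction).

## Partial correlations and wiring-cost matching

Partial correlation is computed by residualizing each region on
`[intercept, covariates]` via QR least squares and Pearson-correlating
residual columns. This is the standard regression definition, is exactly
reproducible, and is invariant to affine rescaling of covariates (asserted
to 1e−10 in tests). The residual degrees of freedom `n − k − 2` are recorded
and must be ≥ 1; groups must satisfy `n ≥ k + 3`.

Only strictly positive partial correlations are edge-eligible. Each group's
minimum edge count `E_min` is the percolation point: adding positive edges
in descending order, the count at which the graph first spans all `p`
regions (union-find; an error is raised if the positive edges cannot connect
the graph). Groups are binarized at `E_target = max_g E_min(g)`, so edge
counts — hence wiring costs — are exactly equal across groups and any
centrality difference is topological rather than a density artifact.
Matching is done in integer edge counts, not real-valued costs, to avoid
rounding ambiguity. Ties at the binarization cutoff are broken by
lexicographic node-pair order, making networks bit-identical across
platforms.

## Centrality conventions

All four measures are computed on the same adjacency, with fixed conventions
for disconnected graphs (a degree-0 node scores 0 on every measure):

- **degree** — row sums of the adjacency;
- **betweenness** — unnormalized fractional shortest-path counts over
  unordered pairs (Brandes semantics; unreachable pairs contribute 0),
  delegated to igraph's C implementation for speed; bounded by
  `(p−1)(p−2)/2`;
- **closeness** — Wasserman–Faust component rescaling
  `((r−1)/(p−1)) · ((r−1)/S)` with `r` the node's component size and `S` its
  summed distances (BFS via scipy.sparse.csgraph), giving values in [0, 1]
  and 0 for isolated nodes; reduces to `(p−1)/S` on connected graphs;
- **eigenvector** — entrywise non-negative, unit-Euclidean-norm principal
  eigenvector of the full (possibly disconnected) adjacency via dense
  symmetric eigen-decomposition; an edgeless graph yields all zeros. On
  disconnected graphs mass concentrates on the component with the largest
  spectral radius. If two components tie exactly for the largest spectral
  radius the principal eigenvector is mathematically non-unique; the
  implementation is deterministic but the value is then convention-dependent
  (a measure-zero situation for estimated correlation networks).

All four are verified to 1e−9 against independent brute-force oracles
(shortest-path enumeration, layered path-count recursion, hand-rolled BFS,
general eigen-decomposition) on every connected graph with ≤ 7 nodes and on
500 random graphs with ≤ 30 nodes.

## Jackknife reliability

For each group, every subject is left out once and the full construction
(partial correlations → top-`E_target` network → centralities) is rerun.
The envelope is `mean ± z·SE` with
`SE = sqrt(((n−1)/n) Σᵢ (θᵢ − θ̄)²)` and `z = 2.576` (99%). Reliability is
reported, not enforced: node-measures whose observed value falls outside
their envelope are flagged in the report.

A property worth knowing: the raw jackknife SE of these statistics does
**not** shrink as `n` grows in realistic regimes. Removing one subject flips
a few near-tied edges at the binarization cutoff — a discrete O(1) change in
centrality — so `Σ(θᵢ − θ̄)²` grows roughly linearly in `n` and the SE
scales like √n (a smooth statistic would have O(1/n) replicate deviations).
The per-replicate RMS deviation `SE/√(n−1)` does shrink with `n`, and that
is the property the test suite asserts. The practical consequence is that
99% jackknife envelopes are wide and observed values essentially always fall
inside them (coverage ≈ 1.0 in simulation), which should be read as a
necessary sanity check rather than a powerful validation.

## Permutation tests and exactness

For a group pair, subjects are pooled and reshuffled into pseudo-groups of
the original sizes, covariates traveling with their subjects; partial
correlations, networks, and all four centralities are rebuilt per reshuffle.
Two-sided p-values use the add-one rule, so they lie in (0, 1] and can never
be zero. One master seed drives per-comparison substreams; swapping the two
groups negates every observed difference and leaves every p-value unchanged
(the null stream is anchored to a canonical group ordering).

**Edge-count handling inside replicates.** Each replicate — including the
observed split — derives its own pairwise-matched edge count
(`max` of the two pseudo-groups' percolation points). This keeps the test
statistic a single label-symmetric function of the pooled data, which is
what makes the permutation test exact. The alternative of anchoring all
replicates at the observed `E_target` evaluates the observed networks at
their own percolation point — a point *chosen from the observed labeling*,
where path-based measures are systematically extreme — and was measured to
be anti-conservative for betweenness (null rejection rate 0.075 instead of
0.050 at α = 0.05 in a 200-dataset calibration). The anchored mode is kept
behind `recompute_cost_in_permutations = False` for sensitivity analyses.
Replicates whose pseudo-groups cannot supply the required positive edges are
redrawn (logged; capped at 10× the permutation count).

Calibration at the defaults is nominal for the continuous measures. Degree
differences are integers, so the tie-inclusive add-one p-value is
conservative for degree (per-node null rejection ≈ 0.03 at α = 0.05 with
200 permutations) — a generic property of permutation tests on discrete
statistics, not a defect of the resampling.

## Multi-measure decision rule

A node is declared different between two groups when at least three of the
four permutation p-values are ≤ α (two of four for a-priori regions). Under
independence the 3-of-4 chance bound would be α³ = 0.000125 at α = 0.05; in
reality the four measures derive from the same two networks and are strongly
correlated, so the realized null decision rate is roughly a three-fold
reduction of the single-measure rate (0.014 vs 0.046 in the 200-dataset
calibration), not a 400-fold one. The product bound is reported as stated,
never as the attained error rate. The direction of a significant difference
is the sign majority among passing measures ("mixed" on a tie).

## Synthetic cohorts

The generator emulates exactly the structure the analysis assumes: per
subject, thickness is `μ + βᵀc + star + ε` with Gaussian noise σ and an
optional planted star per group — independent factors `f_m ~ N(0,1)` per
member, member `m` receiving `λ·f_m` and the hub `λ·Σf_m/√|M|`, so
asymptotically `var(hub) = σ² + λ²`, `cov(hub, member) = λ²/√|M|`, and
member-member covariance vanishes. A star (rather than a clique) makes
exactly one node the degree/betweenness target. Covariates are age
`N(40, 10)` years, Bernoulli 0/1 for configured binary covariates, standard
normal otherwise. Defaults mirror the motivating study's shape: three groups
of 181/35/101 subjects, 148 regions (74 per hemisphere), eight covariates,
2.5 mm baseline thickness, 0.25 mm noise, and a mild age-thinning slope of
−0.005 mm/yr.

Worth noting when choosing loadings: the hub-member *population* correlation
is `λ²/(√|M|·(σ² + λ²))`, which is bounded by `1/√|M|` no matter how large
λ gets (0.41 for six members). With λ = σ = 1 and six members it is ≈ 0.20 —
at n = 80/group this is comparable to noise-correlation fluctuations and is
not reliably detectable by any test; power experiments in this package use
λ = 3 with 12 members, where detection is essentially certain. The generator
does not simulate scanner effects, segmentation error, non-Gaussian tails,
or spatial autocorrelation of neighboring regions, so passing tests
demonstrate the statistical machinery, not robustness to those real-data
features.

`generate_null_cohort` plants one shared structure in every group, making
all between-group topology differences null by construction — the basis of
the calibration experiments.

## Problem sizes and numerical choices

The shipped experiments are sized for a single CPU: calibration uses 200
null datasets × 200 permutations at p = 20, n = 50/group; power uses 50
seeds × 500 permutations at p = 30, n = 80/group; reliability uses ten
groups of n = 60 at p = 30; oracle sweeps cover all 996 connected graphs on
≤ 7 nodes plus 500 random graphs on ≤ 30 nodes. Symmetry of correlation
matrices is enforced by averaging with the transpose and clipping to
[−1, 1]; residualization rejects rank-deficient designs
(`min |diag R|| < 1e−10` of the QR factor); oracle agreement is asserted at
1e−9, affine-invariance at 1e−10, and exact round-trips bit-for-bit.

## Known limitations

- The closeness adaptation for disconnected graphs follows the
  Wasserman–Faust form; other toolboxes make different choices, so absolute
  closeness values are convention-dependent (rankings are not, within a
  component).
- The wiring-cost match presumes every group's positive correlations can
  connect all regions; cohorts violating this abort with a diagnostic rather
  than silently switching thresholding strategy.
- Jackknife envelopes inflate like √n (see above) and should not be read as
  confidence intervals for the population centrality.
- No correction across nodes is applied beyond the multi-measure rule; the
  per-node decision rate under the null is ~0.014, not 0.000125.
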
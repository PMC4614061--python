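# Methods

## The analysis model

The pipeline treats each subject × condition scan as a volumes × ROIs matrix
of BOLD time courses. After cleanup, the statistical dependence between every
ROI pair is summarized by the Pearson correlation, and two complementary
inferential routes are taken:

1. **Edge level (NBS).** For a directed contrast A > B, a one-sided paired
   *t* statistic is computed per edge on the per-subject differences of the
   raw correlation matrices. Edges with *t* ≥ τ form a graph; its connected
   components are the candidate subnetworks, sized by edge count. The null
   distribution of the maximal component size is generated by randomly
   flipping the sign of each subject's whole difference matrix (subjects are
   their own controls, so sign flips are the exact permutation group for a
   paired design), and each observed component receives
   p = (1 + #{null ≥ size}) / (K + 1). Because sign flips leave per-edge
   squared sums invariant, all K permutation t-maps reduce to one matrix
   product; the permutation stream is shared across the τ sweep within a
   contrast. Results on raw matrices are by construction independent of any
   sparsification. The contrast battery enumerates baseline vs the pooled
   narrative mean, baseline vs each narrative, and every narrative pair, in
   both directions (14 directed contrasts for four conditions), with a
   Bonferroni-adjusted significance level (0.05/4 = 0.0125 for the four
   primary contrast families).

2. **Node level (graph metrics).** Each correlation matrix is thinned to a
   weighted, undirected, connected graph at a grid of edge densities
   (12–28 % in 2 % steps) and summarized by nodal metrics; condition effects
   are tested nonparametrically per node and density, with BH-FDR across
   ROIs.

### Sparsification

Edges are examined in ascending signed weight (ties broken by lexicographic
node pair) and removed one at a time; an edge whose removal would disconnect
the graph is kept and the next weakest is removed instead, until
m = round(density · N(N−1)/2) edges remain. With a strict total edge order
this is the classical reverse-delete procedure: the edges ever retained as
bridges are exactly the maximum-spanning-tree edges under that order, and the
removable edges are removed in ascending order. The implementation therefore
runs one Kruskal pass to mark the spanning tree and drops the weakest
non-tree edges — exact, deterministic, and a whole density grid follows from
a single ranking, which also makes the nestedness of edge sets across the
grid explicit. Negative correlations rank weakest and are removed first; a
bridge-retained edge with non-positive weight is floored at 1e-6 for metric
computation, with a warning (weighted metrics need positive weights; the
choice of how to treat negative edges is otherwise open).

### Nodal metrics

Conventions follow the Brain Connectivity Toolbox defaults: path lengths are
l = 1/w; global efficiency is the mean inverse shortest-path length over
ordered pairs; local efficiency of node i is the global efficiency of the
subgraph induced on i's neighbors (zero below two neighbors); LEGE divides
local by global efficiency. Clustering is Onnela's form,
C_i = 2/(k_i(k_i−1)) Σ (ŵ_ij ŵ_ih ŵ_jh)^{1/3} with weights normalized by the
network maximum. Betweenness is Brandes' algorithm on the same lengths,
normalized by (N−1)(N−2)/2 so values lie in [0, 1]; geodesic ties are counted
under exact floating-point equality (with continuous weights, near-ties are
measure-zero). The participation coefficient requires a module partition,
which no part of the design pins down; we use Louvain modularity maximization
at resolution 1, best of 10 seeded restarts, with canonical relabeling —
deterministic given the seed. Metric curves over the density grid are
summarized by the trapezoidal AUC.

### Group statistics

A Shapiro–Wilk gate (α = 0.05 per group; constant samples are non-normal by
convention) routes metrics to nonparametric tests. The omnibus condition test
is Friedman's rank sum by default (the design is within-subject);
Kruskal–Wallis is available for the independent-samples reading. Post hoc
pairwise tests are Wilcoxon signed-rank (scipy's exact small-sample
distribution whenever there are no ties, normal approximation with
correction otherwise), Mann–Whitney U, or paired t. Correction scope follows
the two families in the design: Bonferroni over the condition pairs, or
BH-FDR across the tested ROIs (per metric and density).

### Dynamic intervals

The cleaned series is cut into three contiguous, nonoverlapping, equal-length
windows by floor division (230 volumes → 3 × 76, remainder dropped from the
end). Filtering is done once on the full series before cutting: re-filtering
a 76-volume window at a 0.01 Hz low edge would be ill-posed. Per window,
connectivity and an 18 %-density graph are rebuilt and degree and strength
recorded; values are normalized by subtracting the baseline condition's group
mean per interval (making the baseline group mean zero by construction and
leaving condition differences untouched). Narrative-condition pairs are then
compared per interval with paired t tests (Wilcoxon fallback if the
normality gate fails, with a warning), BH-FDR over the whole family of
pair × interval × metric tests.

### Connectivity pattern

For a focal node, the consistency profile counts, per condition and partner
ROI, the subjects whose 18 %-density graph contains that edge; partners
reaching an absolute count of 13 subjects are "consistent neighbors". Overlap
between such neighbor sets and NBS subnetwork nodes is assessed with the
hypergeometric upper tail P(X ≥ k) for k marked items in n draws from N
without replacement; the simpler sequential "all draws marked" product
∏ (a−i)/(N−i) is reported alongside, since published overlap figures are not
always computed the same way.

## The synthetic-data generator

The generator emulates the reference design: 23 subjects × 4 conditions
(baseline, secure, dismissing, preoccupied), 104 ROIs, 240 volumes at
TR 2.61 s. The target correlation matrix has 8 equal communities
(within ρ = 0.4, between ρ = 0.1) and a hub node tied to 20 neighbors at
ρ = 0.45. In the dismissing condition a 9-node / 9-edge subnetwork around the
hub (8 hub–neighbor edges plus one neighbor–neighbor edge) has its
correlations multiplied by the effect scale δ (default 0.5). Since no
effect size on the correlation scale is reported for the phenomenon being
emulated, δ is a free parameter. Each target is projected to the PSD cone by
eigenvalue clipping and diagonal rescaling; the projection must not move any
non-effect entry by more than 0.05 (measured drift at the defaults:
≤ 0.006). Subjects get a shared-across-conditions symmetric perturbation of
the target (sd 0.02), so the paired design carries genuine subject effects.

Time series are Cholesky-mixed AR(1) innovations (φ = 0.3; the 0.01–0.08 Hz
band is imposed by the preprocessing filter downstream, keeping generator and
filter independently testable), contaminated with a linear trend, a
motion-correlated component driven by a simulated random-walk 6-parameter
rigid-body trace, and white-matter/CSF proxy signals, each with per-ROI
Gaussian loadings (sd 0.3/0.2/0.3/0.3 signal units — contamination large
enough that skipping the regression visibly biases correlations, small
enough that the OLS cleanup is comfortably within its linear regime). With
`dynamic_only`, the reduced-correlation mixing applies only to the 76
post-discard volumes of the first analysis window. Everything is
deterministic in (seed, subject, condition) via seed-sequence spawning.

What the generator does **not** emulate: hemodynamic response shapes, spatial
(voxel-level) structure and parcellation error, physiological noise beyond
the WM/CSF proxies, scanner drift nonlinearity, distance-dependent artifact
structure, or heavy-tailed motion. Passing tests therefore demonstrate that
the pipeline recovers effects planted on the correlation scale under
realistic sampling noise — not that any particular real dataset would yield
the same inferences.

## Numerical and design choices

- Nuisance regression precedes band-pass filtering (the common
  toolbox order; the design lists both steps without an order). Both the
  order and the ideal-filter dialect are bit-reproducible.
- The band-pass is an ideal (brick-wall) DFT-domain filter, zeroing DC;
  exactly idempotent.
- Raw Pearson r (no Fisher z) feeds all downstream analysis; a z-transform
  would be monotone and leave ranks, thresholdings and sign-flip tests
  essentially unchanged.
- NBS permutations use the +1 convention (p is never exactly zero);
  component size is edge count ("extent").
- Statistics: identically-tied samples return p = 1 (no evidence) rather
  than erroring; zero-variance edgewise differences give signed-infinite t,
  treated as suprathreshold in their direction.
- Internal node indexing is 0-based; all file formats carry 1-based ROI
  indices. The ROI count is a parameter (default 104).
- Desk-scale problem sizes in the test suite: replicate-based checks use 50
  replicate studies at the full design size (and 200 null studies at 12
  subjects × 30 ROIs for the FWE calibration), which gives the rate
  estimates a Monte-Carlo standard error of a few percent.

## Known limitations

- At the reference design size, correlation estimates from 230 band-passed
  volumes carry sampling noise of roughly σ_r ≈ 0.11 (≈ 0.19 for 76-volume
  windows), and this noise is correlated across edges sharing a node. Two
  consequences, both documented quantitatively in the test suite: the NBS
  null produces large max-components at low primary thresholds (a 9-edge
  planted subnetwork is only separable from the null at τ ≈ 3.5 and above,
  which is exactly the regime where the core subnetwork is isolated), and
  nodal degree/strength contrasts at δ = 0.5 are significant at the sparse
  end of the density grid but not uniformly across it — at 26–28 % density
  the reduced hub edges (correlation 0.225) still clear the global retention
  cutoff, so no degree effect exists there even in the noise-free limit.
- Sliding-window dynamics, partial-correlation/tangent-space connectivity,
  volumetric preprocessing and atlas construction are out of scope.
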
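# Methods

`connmkl` classifies subjects from multi-weight white-matter structural
networks. This note records the models, the numerical choices, and what the
synthetic test bed does and does not establish.

## The data model

Each subject carries three weighted 90-node networks built on one binary
topology (an edge exists wherever at least one streamline connects the two
regions):

- **FN** — the streamline (fiber) count between the two regions;
- **FA** — the mean fractional anisotropy over the voxels traversed by all
  streamlines of that edge;
- **MD** — the mean diffusivity over the same voxels (mm²/s, ≈0.7×10⁻³ in
  healthy white matter).

With n = 90 nodes there are n(n−1)/2 = 4,005 node pairs, hence
3 × 4,005 = 12,015 edge features per subject. The canonical column order is
FN, FA, MD blocks; within a block, upper-triangle pairs (i, j), i < j,
1-based, lexicographic. This order is arbitrary but fixed, so provenance
(network kind, node pair) survives every round trip.

**Network construction choices.** Streamline endpoints are the first and last
voxels of the track; no dilation or search radius is applied. Streamlines
ending in background are discarded (counted in the log); streamlines with
both endpoints in one region are discarded, because edges are defined on
pairs and the diagonal is structurally zero. The FA/MD voxel aggregate is a
*set* by default — a voxel traversed by several streamlines of an edge counts
once; `voxel_multiset=True` (CLI `--voxel-multiset`) switches to the multiset
reading that weights voxels by visit count. Both are defensible readings of
"the voxels on the fibers"; the set reading is the default because it treats
the phrase as a region of space rather than a sampling scheme.

## Feature selection

The F-score of feature i is

    F(i) = [(x̄ᵢ⁺ − x̄ᵢ)² + (x̄ᵢ⁻ − x̄ᵢ)²] / [s²ᵢ⁺ + s²ᵢ⁻]

with group-sample variances using n−1. Degenerate cases: zero denominator
with non-zero numerator (constant within groups, means differ — a perfect
separator) scores +∞ and ranks first; 0/0 scores 0. Ties rank the lower
column index first so reruns are deterministic. A fraction f of the p
candidate columns maps to k = max(1, round(f·p)); for the multi-kernel and
fused modes p is the pooled 12,015, for `single_network:<kind>` runs the
candidate set is that network's 4,005 columns, matching how a single-network
classifier is actually trained.

Lasso selection regresses the ±1 labels on standardized features under an L1
penalty (penalized least squares). The penalty grid holds 30 log-spaced
values from the smallest all-zero penalty α_max = max|Xᵀy|/n down four
decades; fivefold shuffled CV picks the penalty with the smallest mean
squared prediction error (ties resolve toward the larger penalty, i.e. the
sparser model). If the chosen penalty zeroes every coefficient, the largest
grid penalty with at least one non-zero coefficient is used — the sparsest
non-empty model, i.e. the smallest departure from the CV optimum.

## The multiple-kernel SVM

For per-network kernels k⁽ᵐ⁾ the classifier solves the soft-margin dual

    max_α Σᵢαᵢ − ½ ΣᵢⱼαᵢαⱼyᵢyⱼΣₘβₘk⁽ᵐ⁾(xᵢ⁽ᵐ⁾, xⱼ⁽ᵐ⁾)
    s.t. Σᵢαᵢyᵢ = 0, 0 ≤ αᵢ ≤ C,   βₘ ≥ 0, Σₘβₘ = 1,

and predicts sign(f(x)) with f(x) = Σᵢαᵢyᵢ Σₘβₘk⁽ᵐ⁾(xᵢ⁽ᵐ⁾, x⁽ᵐ⁾) + b and
sign(0) = +1. The simplex constraint on β is the simpleMKL convention.

**Optimization.** For fixed β the mixed-kernel dual is an ordinary SVM solved
by libsvm's SMO (through scikit-learn) at tolerance 1e-8 with an iteration
cap of 10⁶ (degenerate low-rank kernels can cycle for a very long time at
tight tolerances). The dual optimum J(β) is convex in β with gradient
∂J/∂βₘ = −½(α∘y)ᵀKₘ(α∘y) at the inner optimum; β is updated by reduced-
gradient descent on the simplex with a backtracking line search bounded by
the largest feasible step. Stopping: max |Δβ| < 1e-4, |ΔJ| < 1e-5, a KKT
point, or 200 outer iterations (then the best iterate is returned with a
warning). Tests verify the final objective against an exhaustive β grid
(step 0.01) with a QP at every point, and against an independent SLSQP
solution of the inner dual.

**Kernel bookkeeping.** Each training kernel is divided by its mean diagonal
entry before mixing, so β compares networks of different scales; the same
factor is applied at test time. Kernels: linear x·y, polynomial
(x·y + coef0)^degree with degree 3 and coef0 1 by default, RBF with
γ = 1/d by default (d = the network's selected feature count). A network
whose fold-selected feature set is empty is dropped from the mixture for
that fold (β forced to 0; the remaining weights still sum to 1). For linear
kernels the per-network hyperplane is materialized as
w⁽ᵐ⁾ = (1/normₘ) Σᵢαᵢyᵢxᵢ⁽ᵐ⁾ (before β weighting, on the normalized-kernel
scale), so Σₘβₘ(w⁽ᵐ⁾·x⁽ᵐ⁾) + b reproduces the kernel decision values
exactly; nonlinear models refuse the primal extraction rather than
approximating it.

## Evaluation protocol

Leave-one-out cross-validation with strict fold hygiene: per fold, the
z-score normalization (mean, n−1 SD; zero SD → 1) is fitted on the training
rows only, feature ranking and selection run on the training rows only, and
the held-out subject is scaled with the training statistics. A regression
test corrupts the held-out row and asserts the fold's trained model is
bit-identical. The positive class is the patient group.

Accuracy, sensitivity and specificity come from the pooled confusion counts;
ROC/AUC pool the per-fold decision values, with AUC computed by the
Mann–Whitney rank statistic (ties ½) — decision values, not calibrated
probabilities. Grid search re-runs the complete LOOCV at every cell of
C ∈ {0.5, 1.0, …, 5.0} × fraction ∈ {0.0014, 0.00145, …, 0.0028} (defaults)
and optimizes the same LOOCV it reports; this replicates the optimistic
protocol of small-sample connectome studies deliberately, and the optimism
is visible in the permutation-null test below. Ties prefer the smaller
feature count, then the smaller C.

## Discriminative-feature report

Features selected in **every** fold are the consensus set. A consensus
feature's weight in a fold is |w⁽ᵐ⁾ⱼ| · βₘ with the fold's own trained β,
averaged over folds. Edge weights sum a node pair's consensus weights across
the three networks; network totals sum per network; the partition identity
(network totals = edge totals = grand total) is asserted in tests. The
report is defined only for linear-kernel runs.

## Synthetic cohorts

The generator emulates the classifier's input distribution, not diffusion
physics. One binary topology at 25% density (typical of deterministic-
tractography 90-node networks) is shared by all subjects; per-edge baselines
are drawn once (FN lognormal, median ≈20 streamlines; FA uniform in
0.25–0.75; MD normal around 0.7×10⁻³) and subjects add independent Gaussian
noise with between-subject SDs of 0.15·baseline+0.5 streamlines (FN), 0.04
(FA) and 0.03×10⁻³ (MD) at `noise_sd = 1` — realistic inter-subject spreads
for single-edge summaries. Group effects shift the patient group's affected
edges by a stated number of between-subject SDs, so the injected effect *is*
the standardized group difference (verified by Monte-Carlo). The default
cohort split is 51 controls / 36 patients, the size of the comparison the
pipeline was designed around; the seeded recovery experiments use balanced
40+40 groups with 12 affected edges and an MD-only +1.5 SD shift, i.e.
a patient group with elevated mean diffusivity and untouched FA/FN.
FN values are rounded to integers ≥1; FA is clipped to (0, 1]; with the
default baselines and SDs the clipping is essentially never active.

One global seed drives separate sub-streams (topology, baselines, noise,
jitter, affected-edge draw) so each ingredient is reproducible in isolation.
`topology_jitter` optionally flips a stated fraction of edges per subject to
probe the shared-topology assumption; real cohorts have subject-specific
topologies, which the default generator does not emulate. Passing tests
therefore show that the pipeline recovers known effects under its own
assumptions (shared topology, Gaussian noise, edge-local effects) — they do
not certify performance on real diffusion MRI, where registration error,
tractography bias and topology variability add structure the generator
omits.

## Problem sizes in the shipped checks

The test suite and the acceptance script run the full 90-node, 80-subject
recovery condition (one complete LOOCV over 12,015 features), a 200-replicate
label-permutation null on a 20-node, 60-subject cohort, a 60-cohort
Monte-Carlo calibration of the null t-test rate on 8-node cohorts, and
oracle comparisons at n ≤ 30. These sizes keep a full run in a few minutes
while leaving every statistical contract testable; the cohort generator
scales to larger runs unchanged.

## Known limitations

- The inner SMO tolerance is a KKT-violation bound, not literally a duality
  gap; oracle tests confirm dual objectives to better than 1e-6 relative.
- Grid search is not nested; reported accuracies inherit the protocol's
  optimistic bias by design.
- The lasso path uses squared error on ±1 labels, not logistic loss.
- Self-connections and endpoint tolerance radii are not modelled.
- The discriminative-feature report requires linear kernels.
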
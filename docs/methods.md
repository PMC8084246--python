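# Methods

## Problem and model

CDSML classifies cell line–drug pairs as *sensitive* (1) or *resistant*
(0). The observable is an IC50 response matrix I over m cell lines and
n drugs (natural-log molar scale, missing entries allowed), together
with cell-line feature matrices (expression, copy number, binary
mutation), a binary drug-fingerprint matrix, chemical–protein and
protein–protein interaction networks, a drug→target-protein map, and a
per-drug maximum plasma concentration C_max. A pair is labeled
sensitive iff I(c, d) < C_max(d), strictly; equality is resistant. The
C_max threshold is pharmacokinetic: if half-maximal inhibition needs
more drug than plasma can carry, the line is resistant in any
clinically meaningful sense.

The binary response B (m×n) is approximated by a low-rank double
decomposition. One fit factorizes B ≈ X Yᵀ, a second, independently
initialized fit factorizes Bᵀ ≈ Z Wᵀ, and the predicted score matrix is
B̃ = ½(X Yᵀ + W Zᵀ), which symmetrizes the role of cell lines and drugs.
Each fit minimizes

    L = ½ Σ_{(i,j)∉Missing} (B_ij − X_i·Y_j)²
        + α/2 (‖X‖_F² + ‖Y‖_F²)
        + β/2 (Σ_{i,j} ‖X_i − X_j‖² SC_ij + Σ_{i,j} ‖Y_i − Y_j‖² SD_ij)

where SC and SD are cell-line and drug similarity weight matrices and
Missing is the set of unobserved pairs (empty after imputation, so the
same code path serves the imputed and the missing-aware modes).
Scenario flags drop either or both conservation terms, giving the
double-, single- and no-similarity variants.

## Preprocessing

Sparse-sample filtering runs in a fixed order: drugs whose response
column is missing for strictly more than half the cell lines, then
feature columns missing for strictly more than half the cell lines,
then cell lines missing strictly more than half of the remaining
columns in the response or any feature matrix. All thresholds default
to 0.5 and are configurable; the cell-line axis stays identical across
all surviving matrices, and every removal is logged with its missing
fraction.

Remaining gaps are filled by expression-distance-weighted KNN. The
distance between two cell lines is the squared Euclidean norm of their
expression profiles (the expression matrix is required complete); a
missing entry is the weighted mean of its k = 10 nearest neighbours'
values in that column. As published, each neighbour is weighted by its
*distance*, so farther neighbours weigh more — the opposite of
conventional KNN imputation. We implement the published form as the
default for faithfulness and provide `weighting="inverse-distance"` for
the conventional variant; the choice is logged at call time. Neighbours
missing the queried column are skipped in favour of the next nearest,
distance ties break lexicographically by cell-line id, and an all-zero
distance set (duplicate profiles) falls back to the unweighted mean.

## Similarities

Cell lines: Pearson correlation of expression (SC_E) or copy-number
(SC_V) profiles; Jaccard index of binary mutation profiles (SC_M).
Drugs: Jaccard of chemical fingerprints (SD_S); Jaccard of the
immediate (first-order) neighbourhoods in the chemical–protein network,
edge weights ignored (SD_N); and the total weight of a maximum-weight
bipartite matching between the two drugs' target-protein sets, with
edge weights from the protein–protein network (SD_P). Empty-set Jaccard
ratios (0/0) are defined as 0 — no evidence of similarity — except the
profile-Jaccard diagonal, which is 1. The matching similarity is
unbounded above (a sum of positive weights), so it is rescaled onto
[0, 1] by its maximum entry before standardization; without this the
standardization map below would leave [0, 1]. Matching is solved as a
zero-padded linear assignment; since all weights are positive, padding
with zero columns/rows never changes the optimal total.

Standardization maps every similarity entry through (S + 1)/2, placing
Pearson values from [−1, 1] and Jaccard values from [0, 1] on a common
[0, 1] scale while preserving entry order. The symmetric normalized
Laplacian S̄ = D^{−1/2}(D − S̄td)D^{−1/2}, with D the diagonal of row
sums of the standardized matrix, is available as a further transform;
it is symmetric positive semidefinite with spectrum in [0, 2] and
annihilates D^{1/2}1.

### Choice of conservation weights

The conservation penalty needs a weight matrix. Two modes are
provided via `prepare_similarity(..., weights=...)`:

- `standardized` (default): the standardized similarity itself weighs
  the pairwise differences. The penalty equals 2β·tr(Xᵀ L X) with L the
  (unnormalized) graph Laplacian of a non-negative matrix, hence
  positive semidefinite: the loss is bounded below and the optimizer is
  well behaved.
- `laplacian`: the normalized Laplacian operator itself is used as the
  pairwise weights. Because its off-diagonal entries are negative, the
  per-entry curvature of the penalty, 2β(Σ_j S̄_ij − S̄_ii), is negative,
  and at the reference coefficients (α = 3.5, β = 4.5) the total
  curvature goes negative: the loss is unbounded below. The damped
  optimizer then cannot descend and stops at its initialization (it
  emits a warning when this happens). The mode is kept for completeness
  and for spectral use of the transform, but it is not the default
  precisely because of this degeneracy.

## Optimization

X and Y start from seeded uniform(0, 1) draws and alternate entry-wise
(diagonal-Hessian) Newton updates x ← x − g/max(h, 1e−8). A full
Hessian solve is neither needed nor intended: the update divides a
gradient array by a curvature array. Because the simultaneous
entry-wise update is a Jacobi-type iteration, the raw step can diverge
(we verified this empirically even without similarity terms), so each
step is damped: if the candidate raises the loss the step is halved, up
to 20 times, and the best candidate — including the unchanged factor —
is kept. This guarantees a non-increasing loss trace. Iteration stops
when ‖X⁽ᵗ⁺¹⁾ − X⁽ᵗ⁾‖_F + ‖Y⁽ᵗ⁺¹⁾ − Y⁽ᵗ⁾‖_F < 0.01 or after max_iter =
500 sweeps (then a warning is attached). The latent dimension is
K = floor(k′·min(m, n)), minimum 1. The transpose fit uses seed + 1 and
swaps both the similarity matrices and the scenario flags, since cell
lines are columns of Bᵀ. Defaults α = 3.5, β = 4.5, k′ = 0.7 are the
grid-search optimum reported for the GDSC screen; on other data they
should be re-tuned with `grid_search`.

Gradients are derived directly from the loss (per-entry curvature of
the conservation term is 2β L_ii) and validated against central
differences to < 1e−5 relative error for all four scenarios and the
transpose fit.

## Scores to labels, ranking

The continuous B̃ is binarized at the precision–recall elbow: among all
distinct score thresholds, the one whose (recall, precision) point lies
closest in Euclidean distance to the ideal corner (1, 1); pairs with
score ≥ threshold are sensitive. In cross-validation the threshold is
learned on training pairs only — computing the elbow on test labels
would leak. Unobserved pairs are ranked by descending score (ties by
cell id, then drug id) to propose novel sensitive associations.

## Evaluation protocol

Stratified pairwise cross-validation: the observed sensitive and
resistant pair lists are shuffled independently (seeded) and dealt
round-robin into 5 folds, so per-class fold sizes differ by at most one
and each fold's sensitive fraction tracks the global one. For each
fold, test pairs are masked as missing and the model is fitted in
missing-aware mode on the rest. Metrics: Accuracy, F1, Precision,
Recall from the sensitive-positive confusion table; AUC by the
Mann–Whitney pairwise formulation with ties counting ½; AUPR by the
precision step-curve integrated over recall. The protocol repeats the
5-fold split (30 repetitions in the full setting; grid search defaults
to 3 repetitions for desk-scale runtime, with the full count behind a
flag). Vector-agreement metrics (Jaccard, cosine, binary cross-entropy
with probabilities clipped to [1e−7, 1 − 1e−7], RMSE, range-normalized
RMSE under either vector's range, MAE) support comparisons of imputed
versus predicted label/score vectors.

## Synthetic data

The generator plants the structure the learner assumes. Latent factors
U (m×k_true) and V (n×k_true) are standard Gaussian; continuous scores
UVᵀ are split at each drug's median, so a consistent C_max table exists
by construction: the IC50-like matrix is −UVᵀ plus a per-drug offset
and C_max is the offset minus the median, which makes
binarize-against-C_max reproduce the noiseless labels exactly
(equality falls on the resistant side in both constructions). Labels
then flip independently with probability `noise`, and entries go
missing uniformly at rate `missing_frac`. Similarities mix the cosine
similarity of the planted factor rows with symmetrized uniform noise at
weight `sim_fidelity`. Feature matrices (expression, CNV with a few
missing entries, binary mutation, drug fingerprints) are linear or
logistic transforms of the factors; drugs target the proteins nearest
their latent position, giving networks whose neighbourhood and matching
similarities correlate with the planted structure.

Defaults — m = 60, n = 30, k_true = 4, noise = 0.05, missing_frac =
0.2, sim_fidelity = 0.9 — are the package's study conditions: large
enough to exercise stratified folding and rank recovery, small enough
that the full test suite runs in seconds. The median split yields
balanced classes (≈50% sensitive, comparable to the 59–65% reported for
real screens), which stresses the stratified folding machinery.

What the generator does *not* emulate: unbalanced per-drug class
fractions (every drug is exactly half sensitive by construction),
tissue structure, batch effects, heavy-tailed IC50 noise, or realistic
network topology. Passing the recovery tests therefore shows the
machinery recovers planted low-rank structure under noise and
missingness; it does not certify performance on real screens.

## Known limitation: similarity conservation on balanced synthetic data

On this generator the similarity-conservation penalty does not improve
held-out recovery; it degrades it monotonically in β, and at β = 4.5
the double-similarity fit collapses (held-out AUC ≈ 0.46 versus ≈ 0.90
without similarities). The mechanism is structural: conservation
shrinks latent rows toward a weighted consensus, so predictions retain
mostly between-drug differences — and the median-split construction
makes every drug exactly half sensitive, so between-drug differences
carry no class information. On real screens, where per-drug class
fractions vary widely, the same shrinkage moves predictions toward
informative row/column effects, which is consistent with similarity
terms helping there. We verified the collapse is not an optimization
artifact: warm-starting the β = 4.5 fit from the β = 0 optimum reaches
the same loss and the same collapsed AUC. Users applying the method to
data with balanced per-drug classes should tune β with the provided
grid search and expect small values to win.

## Numerical choices

- Curvature floor 1e−8 before the Newton division; overflowing
  candidate losses are treated as +∞ by the damping search.
- Similarity matrices are re-symmetrized as (S + Sᵀ)/2 on construction
  and must be symmetric within 1e−8.
- The PR-elbow threshold scans distinct scores in descending order and
  keeps the highest threshold among distance ties; identical scores
  everywhere yield a warning and the trivial labeling.
- Degenerate inputs fail loudly: single-class label sets, zero row sums
  in the Laplacian, constant rows under Pearson, zero-norm vectors
  under cosine, missing entries with no usable imputation neighbours.
- All randomness flows through explicit integer seeds
  (`numpy.random.default_rng`); the transpose fit derives seed + 1, and
  cross-validation derives one seed per repetition × fold.
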
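# Methods

## Problem setting

`stageopt` implements a two-tier classification framework for grading
dementia severity from brain MRI slices into four stages — no dementia (0),
very mild (1), mild (2), moderate (3) — together with the metaheuristic
that tunes it. Tier 1 (L1) is a deliberately lightweight convolutional
network trained end-to-end on 32×32 RGB images; after training it is
truncated at its dropout layer and the activations feeding the dropout are
used as per-sample feature embeddings. Tier 2 (L2) is a gradient-boosted
tree classifier (XGBoost or LightGBM) trained on those embeddings, split
70 % / 30 % with class stratification. Every tunable hyperparameter of
both tiers is a dimension of a box-constrained, mixed integer/continuous
search space, and the search is driven by QSAVNS, a variable neighborhood
search variant described below. The optimization objective throughout is
the multiclass Matthews correlation coefficient (MCC).

## The optimizer

### Baseline VNS

The population is a set of N independent VNS trajectories sharing one
elite. Each iteration, every agent perturbs ("shakes") its genotype inside
its current neighborhood N_k and accepts the candidate on strict
improvement, resetting k to 1; otherwise it advances to the next
neighborhood (wrapping at k_max). Neighborhood k draws each dimension
uniformly in ±(k/k_max)·r₀·(ub_j − lb_j) around the current value, with
base radius r₀ = 0.3 and k_max = 3 by default; the result is repaired into
the box (integer dimensions round half-up, then clip). k_max is kept small
because the hyperparameter searches run for only 3–10 iterations, so there
is no room for a long neighborhood ladder.

Cost is counted in fitness-function evaluations (FFEs): one FFE is one
train-and-validate cycle of a candidate model. With the first-improvement
local search disabled (the default) the budget is exactly N·(T+1): N
initial evaluations plus one shake evaluation per agent per iteration.
Enabling `local_search_tries = t` raises the cap to N·(1 + T·(1 + t)).
The default is 0 because the N·T evaluation budget of the study protocol
leaves no room for refinement evaluations; the optimizer property test
that demands fine convergence (1e-2 on a smooth 2-D objective) enables
two tries, since the smallest shake neighborhood moves about one box-unit
per dimension and cannot resolve 1e-2 on its own.

### QSAVNS

Two mechanisms are added:

* **Quasi-reflexive initialization.** Half of the initial population
  (floor(N/2) agents) is drawn uniformly in the box; each remaining agent
  is the quasi-reflexive image of one uniform draw: per dimension j, a
  uniform sample between the box midpoint m_j = (lb_j + ub_j)/2 and the
  source value x_j (interval order-normalized). This spreads the initial
  population toward the opposite half of the box from each uniform draw.
* **Stagnation-aware elitist rollback.** A counter s_count increments on
  every iteration without strict improvement of the global best and resets
  on improvement. When it reaches s_tresh = ceil(T/3), the best-so-far
  solution is retained verbatim and the other N−1 agents are regenerated by
  the initialization scheme; the counter resets. The ceiling convention
  means a rollback can never fire before a full third of the run has
  elapsed; on a flat objective rollbacks fire exactly at iterations
  ceil(T/3), 2·ceil(T/3), …

Regenerated agents carry no fitness; they adopt the first candidate
evaluated for them on the next iteration, so a rollback adds no FFEs and
the budget identity above is preserved exactly.

Ties do not reset the stagnation counter (strict `>`), which matters for
plateaued objectives. Every stochastic draw of a run flows from a single
seeded generator; run i of a repeated experiment uses seed base_seed + i.

### Design notes

The population-based arrangement (independent trajectories + shared elite)
was chosen over a single-trajectory VNS because the study protocol
describes a population of agents with per-agent hyperparameter encodings;
the rollback's "most recent productive configuration" is realized as
elite-plus-reinitialization rather than population snapshotting, matching
the elitist description of the mechanism. Maximization is the convention
throughout; minimization objectives are negated by the caller (the bundled
benchmark objectives — sphere, Rastrigin, Rosenbrock — are returned
negated for this reason).

## The two-tier classifier

### Tier-1 CNN

Topology: `n_conv` blocks of [3×3 same-padded convolution → ReLU → 2×2
max-pool] with per-block widths, flatten, `n_dense` ReLU dense layers, one
dropout, 4-way softmax. Search ranges: learning rate [1e-4, 3e-3], dropout
[0.05, 0.2], epochs [10, 30], 1–2 conv and dense layers, widths [32, 96].
The genotype always carries four width slots (conv1, conv2, dense1,
dense2); widths of disabled layers stay in the genotype but are ignored at
decode time, keeping the genotype length fixed for the optimizer.

Training: Adam at the genotype learning rate, one-of-K cross-entropy,
batch size 512, early stopping on validation loss with patience
floor(epochs/3) and best-weight restoration. The validation split is an
internal stratified 20 % of the training data; the MCC on that split is
the fitness surfaced to the optimizer, so the final test split never
influences the search. The block structure itself (3×3 kernels, 2×2
pools, single dropout immediately before the softmax) is the minimal
standard lightweight design consistent with embeddings being defined at
the dropout input.

The network is implemented directly on numpy in float32. Convolutions run
as GEMMs: the first layer (3 input channels) materializes a patch matrix
once per fixed batch and uses a single wide GEMM; deeper layers use nine
accumulated per-tap GEMMs, which avoids memory-bound im2col buffers at
larger channel counts. All randomness (init, shuffling, dropout) flows
from one seeded generator, so training is bitwise reproducible on a fixed
BLAS. Max-pool gradients route to the first maximal corner of each window
(deterministic tie-break).

### Embeddings and tier 2

`transform`/`truncate_and_embed` run the network in inference mode
(dropout inactive) up to the dropout input; the embedding width equals the
last dense width. Embeddings of the full dataset are split 70/30 with
class stratification; the booster trains on the 70 % side. Boosters are
configured with exactly the genotype's values and library defaults
otherwise, with three reproducibility/effectiveness exceptions: both
libraries are pinned to one thread and the pipeline seed, and LightGBM's
`bagging_freq` is set to 1 so the tuned bagging fraction actually
participates (at the library default frequency of 0 the parameter is
inert). The XGBoost space has 6 dimensions, the LightGBM space 10
(including the boosting-round count [5, 20]).

The L2 search objective is the MCC on an internal stratified 20 %
validation split of the training embeddings; reported tables always come
from the held-out 30 %.

## Synthetic data

The image generator emulates the staged-MRI structure statistically: each
class renders a centered bright disc with an interior cavity whose radius
and interior intensity shift monotonically with the class index, scaled by
a single `separability` parameter (units of template-geometry shift per
stage; 0 makes all classes identical, 2 is the default study condition).
Per-image variation comes from ±2 px random translation and Gaussian pixel
noise (sd 0.08 on the 0–1 intensity scale). Grayscale is replicated to 3
channels. Default fixture counts (384/336/300/300) mirror the evaluation
split supports of the study, so report tables are shape-identical to the
published ones. The geometry was chosen so that a 1–2-conv-layer network
can learn it at moderate separability while leaving headroom for the
tier-2 booster — the qualitative L1→L2 relationship of interest. What the
generator does **not** model: anatomy, bias fields, scanner noise
structure, inter-subject variability; passing tests on it demonstrate the
pipeline's mechanics and the optimizer's behavior, not clinical
performance.

The tabular surrogate (for L2-only tests) draws class-conditional Gaussian
clusters with mean `separability·k` along a per-class random unit
direction, unit covariance. The directions define the population, so an
optional `direction_seed` pins them while the sample seed varies —
necessary whenever independent train/test samples must come from the same
distribution.

## Metrics

One-vs-rest precision/recall/F1 per class, accuracy = trace/total,
error rate = 1 − accuracy, macro (unweighted) and support-weighted
averages, and the Matthews correlation coefficient: the binary form on
(TP, TN, FP, FN) and the K-class generalization (Gorodkin's R_K) on
confusion-matrix marginals. Any rate with a zero denominator is reported
as 0, matching the zero entries printed for collapsed classes in the
published tables. R_K needs only the diagonal, row totals and column
totals, which is what makes the published per-class tables checkable:
`reconstruct_marginals` recovers diagonal_k = round(recall_k · support_k)
and column_k = round(diagonal_k / precision_k), rejects reconstructions
that violate sample conservation by more than K (one rounding unit per
class), and the R_K of the reconstruction reproduces the published
best-run MCC values to 5e-5 (rounding of six printed decimals compounds
through the division, hence the looser tolerance than the 5e-6 used for
direct identities).

## Experiment protocol and statistics

`run_repeated` executes each algorithm n_runs times (30 in the study
protocol), run i seeded base_seed + i, and stores a tidy results table
with full seed provenance. Summaries use the population std/var convention
(the published summary tables are consistent with var = std² under that
convention); ddof is configurable. The statistics battery delegates to
scipy.stats: Levene across groups, Shapiro–Wilk per group, and paired
Wilcoxon signed-rank of the reference algorithm against each competitor
(zero-difference pairs discarded per the standard convention; an all-zero
difference vector is degenerate and reported as p = 1 with a flag).
Levene is computed per experiment; pooling across experiments is the
caller's choice.

## Attribution

Shapley values explain single predictions of the tier-2 model over
embeddings, against the class-probability output. Missing features are
marginalized interventionally over a background set (a seeded subsample of
at most 100 training embeddings is the recommended background).
`shapley_exact` enumerates all 2^d coalitions (d ≤ 12) and is the
reference; `shapley_kernel` samples coalitions proportional to the Shapley
kernel weight, fits a weighted least-squares linear model to the coalition
values, and enforces the efficiency axiom (base value + attributions =
prediction) by constraint elimination, so efficiency holds exactly on
every estimate. When the budget covers all 2^d − 2 non-trivial coalitions
the estimator enumerates them with analytic weights and coincides with the
exact values to solver precision.

## Problem sizes used in the test suite

Desk-scale test sizes are chosen to exercise every mechanism while keeping
the suite practical: the optimizer property suite runs 30 seeds on 5-D
benchmarks; CNN learnability checks use 200 images/class at separability 3
(the easy-problem floor) and 30/class for structural checks; the
end-to-end experiment runs at counts (48, 42, 36, 36) with separability 2,
tier-1 search N=4/T=3, tier-2 search N=6/T=5, 10 seeds, comparing median
tier-1 and tier-2 MCC on a common held-out split.

## Known limitations

* The CNN is single-threaded numpy; it is adequate for the lightweight
  search ranges above but not for larger architectures or datasets.
* The synthetic generator's monotone geometry makes class ordering
  learnable by design; ordinal structure in real staging data is noisier.
* Early stopping monitors loss on a small internal split; with very small
  datasets the patience floor(epochs/3) can stop before convergence.
* The Wilcoxon battery applies no multiple-comparison correction, matching
  the study protocol it mirrors.
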
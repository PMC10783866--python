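# Methods

`mutstrat` stratifies tumors into survival-relevant subtypes using nothing
but binary somatic mutation calls, a protein–protein interaction network
and a collection of pathway gene sets. This note describes the model at
each stage, the tunable parameters and their defaults, what the synthetic
cohort generator does and does not emulate, and the known limitations —
including one bias in the randomized-mutation control that users should
understand before interpreting its p-value.

## Network propagation

A panel-sequenced tumor typically carries a handful of mutated genes out
of hundreds, so the raw profile is too sparse to compare across patients.
Each patient's profile is smoothed by a random walk with restart over the
interaction network:

    p_{t+1} = (1 − r) · W · p_t + r · p_0

* `W` — column-normalized weighted adjacency of the network after
  filtering edges at combined score > 700 (STRING convention). Isolated
  nodes are dropped; duplicate/reciprocal edges collapse to the maximum
  score. Edge weights are used in the normalization; `binarize_edges`
  switches to the unweighted reading.
* `p_0` — uniform mass 1/m over the patient's m mutated genes that map to
  network nodes (case-insensitive exact id match); mutated genes absent
  from the network are dropped with a logged count. A patient with no
  mapped mutation is an error by default (`on_unmapped_sample="exclude"`
  relaxes this); the generator guarantees ≥ 1 mutation per sample by
  rejection resampling precisely so the seed is always defined.
* `r = 0.75`, stopping when the max-norm change between successive
  iterates falls below `tol = 1e-6` (iteration cap 10 000). The fixed
  point is `r (I − (1−r) W)^{-1} p_0`; tests verify the iterative solver
  against this direct solve to < 1e-8 on random graphs.

Because `W` is column-stochastic and `p_0` sums to one, every iterate —
and hence every smoothed profile row — sums to one.

## Pathway activity (single-sample enrichment)

Each smoothed profile is scored against each gene set with a
single-sample GSEA statistic: genes are ranked descending; walking the
ranked list, in-set genes contribute their rank weight `(N − pos + 1)^α`
normalized by the set's total rank weight, out-of-set genes subtract
`1/(N − |set|)`; the enrichment score is the sum of the running
difference over all positions (the integrated running-sum form). Scores
for a cohort are normalized by the global (max − min) of that cohort's
score matrix, so training and testing cohorts are normalized separately.

* `α = 0.25` (the common default for this statistic's weighted variant);
  exposed as a parameter.
* Ties in the heavily tied smoothed values resolve by stable order, i.e.
  gene-id order for matrices stored with sorted columns — deterministic.
* Monotonicity caveat: for `α = 0` the score is provably monotone in any
  in-set gene's value. For `α > 0` a rising in-set gene increases the
  set's total rank weight, which can lower the early running sum enough
  to reduce the integral slightly; the test suite asserts monotonicity
  for the unweighted statistic only.
* The gene-level profile (every gene its own singleton set) reduces to a
  closed form linear in the gene's rank position, so it is a rank-perfect
  (Spearman ρ = 1) monotone transform of the smoothed values; it is
  computed by that closed form and cross-checked against the generic
  scorer.

## Prognostic screening

One univariate Cox proportional-hazards fit per pathway column against
overall survival; pathways with Wald p < 0.05 are retained and labeled
risk (HR > 1) or protective. No multiple-testing correction is applied by
default, matching the screening convention this pipeline follows; a
Benjamini–Hochberg `fdr=True` flag is available. Model fitting is
delegated to lifelines (Efron tie handling; with continuous simulated
times ties do not occur). The score test at β = 0 is implemented directly
with the hypergeometric variance, making the classical identity with the
two-group log-rank test exact, ties included — the suite asserts it to
1e-6.

## Structural deep clustering

Patients are clustered on the standardized (zero-mean, unit-variance per
pathway) activities of the retained pathways. Two branches train jointly,
full batch, in plain NumPy with manual backpropagation (verified against
finite differences):

* an autoencoder (ReLU hidden layers, linear embedding/output) trained
  for reconstruction;
* a graph convolutional network over a union-symmetrized
  k-nearest-neighbor patient graph whose layer l input is
  `(1 − ε) Z_l + ε H_l` — its own representation mixed with the
  autoencoder's layer-l activation (ε = 0.5) — ending in a softmax over
  clusters.

Soft assignments `q_ij` come from a Student's-t kernel (one degree of
freedom) between the embedding and learnable centers initialized by
k-means on the pretrained embedding; the sharpened target
`p_ij ∝ q_ij² / Σ_i q_ij` supervises both branches through KL(P‖Q) and
KL(P‖Z). Loss weights default to (1, 0.1, 0.01); hard labels come from
the GCN branch (an `head="ae"` switch exists). Optimization is full-batch
Adam at 1e-3; the GCN branch uses a 10× learning-rate multiplier —
with its 0.01 loss weight the softmax head otherwise tracks the target
too slowly and can leave clusters empty for k ≥ 3 even on trivially
separable data. An empty cluster at convergence triggers one center
re-initialization, then an error (recorded and skipped during k
selection).

The architecture defaults follow the original recipe
(encoder 500-500-2000, embedding 10, 10 neighbors); the shipped analyses
use a compact profile (encoder 64-32, embedding 10, 300 pretraining and
300 training epochs) appropriate for ~100-feature activity matrices —
feature spaces this small do not need the full-width encoder, and the
compact profile keeps the demonstration analyses fast.

The number of clusters is chosen by training at every k in 2..10 and
keeping the highest average silhouette width, Euclidean, on the same
standardized features. For two-cluster solutions, labels are oriented so
cluster 1 has the worse Kaplan–Meier median survival (ties: the larger
cluster becomes cluster 1); the orientation is idempotent, and k ≠ 2
assignments pass through unchanged. Testing cohorts are re-clustered with
the training-derived pathway list rather than label-transferred.

All randomness (initialization, k-means, generators) flows from explicit
seeds; with a fixed seed every stage is byte-reproducible, which the
suite checks by hashing every intermediate twice.

## Cohort operations

Samples lacking survival time or event status are excluded, and the
mutation matrix is inner-joined to the surviving clinical records with
logged counts. The training/testing split draws one standard-normal
number per patient, sorts descending and takes the top `n_train` — an
exchangeable split kept in this literal form for procedural fidelity.

## Randomized-mutation null

The control asks whether the pipeline invents subtypes when the
genotype–phenotype linkage is destroyed: patients are resampled with
replacement (survival records travel with their rows; resampled ids get a
suffix), then each row's m ones are reassigned to m genes drawn uniformly
without replacement across the panel. Row sums are preserved exactly;
column frequencies are destroyed. The null cohort then runs through the
full chain — smooth, score, screen, fixed k = 2 clustering (falling back
to all pathways if the screen retains nothing), log-rank.

**Known bias.** The null log-rank is computed on clusters built from
pathways that were screened for survival association *on the same data*.
Even with all signal destroyed, the ~5% of pathways retained by chance
correlate with survival by construction, and any clustering of patients
on those columns partially inherits that correlation. In a controlled
comparison on identical null cohorts (15 seeds, n = 250), a random
two-way split gave p > 0.05 in 93% of seeds and clustering on *all* 114
pathways in 100%, but clustering on the screened pathways — the
procedure as specified — in only ~50%. The null p-value is therefore
anti-conservative and should be read qualitatively (screen retention
collapses from ~60 pathways to ~5; the subtype signal disappears), not as
a calibrated test. A selection-free null (clustering on all pathways, or
sample-splitting between screening and testing) is calibrated but is a
different procedure from the one this pipeline mirrors.

## Synthetic cohort generator

The generator exists so every stage is testable without downloads. It
emulates the statistical shape of a panel-sequenced cohort, not any real
dataset:

* **Network** — stochastic block model over consecutive 30-gene
  communities, 80% of expected degree within the block (average degree
  8), chained into one component if sampling leaves stragglers; edge
  scores uniform in (700, 1000], the post-filter dialect. A
  preferential-attachment alternative (`wiring="ba"`) provides the
  heavy-tailed-degree regime. Modularity matters: network propagation
  only concentrates signal when pathway neighborhoods are denser than the
  background, which is the premise of smoothing mutations at all.
* **Pathways** — 114 sets of 5–20 genes; each draws ~80% of members from
  the personalized-PageRank neighborhood of a seed node (essentially its
  community) and the rest uniformly, so sets are local, overlapping and
  imperfect. Small sets reflect what pathway collections look like after
  restriction to a few-hundred-gene panel.
* **Mutations** — heterogeneous per-gene rates: each community's anchor
  gene is a recurrent "driver" carrying 70% of the mutation budget
  (capped at rate 0.35), passengers share the rest; the mean per-gene
  rate equals `baseline_mutation_rate` (default 0.015 → ~9 expected
  mutations per sample on 600 genes, with the drivers recurrent across
  patients as on real capture panels). The subtype signal is
  *compositional*: of the 10 informative pathways, the first five are
  mutated at `enrichment_factor` (default 3) times the base rate in
  subtype A, the other five in subtype B. This balances expected total
  burden between subtypes — deliberately, because the permutation null
  preserves per-patient burden, so a burden-coupled subtype signal could
  never be erased by it — and produces both risk and protective
  prognostic pathways, as real screens do. An optional
  `burden_dispersion` lognormal multiplier adds patient-level burden
  heterogeneity (default off: it buries the compositional signal long
  before it changes any null behavior).
* **Survival** — exponential proportional hazards, baseline median 24
  months, linear predictor `hazard_log_ratio · 1[subtype A]` (default
  0.7); independent uniform censoring whose horizon is calibrated by
  bisection so the expected censored fraction hits `censoring_rate`
  (default 0.3).

What the generator does **not** emulate: mutational signatures, panel
version heterogeneity, copy number or structural variation, non-modular
interaction topology mixed with modular, non-proportional hazards,
informative censoring, or the extreme TMB tails of hypermutated tumors.
Passing tests show the pipeline recovers the structure it assumes when
that structure is present at realistic strength — not that any particular
real cohort contains it.

## Problem sizes used by the shipped studies

The validation studies run at sizes chosen to exercise each property
clearly: 50 random graphs up to 200 nodes for the solver oracle; 200
random instances for the scorer oracle; 1 000 replicates of n = 100 for
log-rank type-I error; 50 replicates of n = 1 500 for Cox coefficient
recovery; 10 activity cohorts of n = 1 500 (10 informative / 104 null
pathways) for screening operating characteristics; 10 demo cohorts of
n = 500 for full-pipeline subtype recovery; 20 null replicates at
n = 250 for the randomized-mutation control. The reproduction script
(`scripts/acceptance.py`) uses the same studies, some at slightly fewer
seeds.

## Numerical choices and degenerate inputs

* Max-norm on successive iterates as the walk's convergence criterion —
  the strictest elementwise reading of "change below threshold".
* Gene-id reconciliation is exact string match after upper-casing; no
  fuzzy matching, unmapped ids are counted and logged, never silent.
* A gene set intersecting the profile nowhere is dropped with a warning;
  a set covering *every* profile gene has an undefined out-of-set step
  and is an error.
* Constant covariates, zero-event cohorts, single-group log-rank calls,
  empty post-filter networks and non-stochastic transition matrices all
  raise typed errors (`ParameterError`, `DataError`, `ConvergenceError`,
  `TrainingError`) rather than propagating NaNs.
* Cox non-convergence (e.g. monotone likelihood) returns a flagged
  result (`converged=False`, NaN summaries) rather than raising, so a
  screening loop can skip and continue.
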
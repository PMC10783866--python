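# mutstrat

Metabolic stratification of tumors from somatic mutation profiles alone.

Panel sequencing yields, for each patient, a short list of mutated genes —
a binary vector far too sparse and high-dimensional to cluster directly,
and with no quantitative value to hand to expression-style tooling.
`mutstrat` implements a network-propagation pipeline that turns those
vectors into continuous pathway-activity profiles and discovers
survival-relevant patient subtypes from them:

1. **Smooth** — each patient's 0/1 mutation vector seeds a random walk
   with restart on a protein–protein interaction network (edges filtered
   at combined score > 700), iterating
   `p_{t+1} = (1 − r) W p_t + r p_0` with restart probability `r = 0.75`
   to convergence (max-norm change < 1e-6), where `W` is the
   column-normalized weighted adjacency. The stationary distribution is a
   continuous "mutation influence" profile over all network genes.
2. **Score** — a single-sample GSEA statistic (integrated running sum,
   rank-weight exponent α = 0.25) scores every patient against every
   metabolic pathway gene set, giving a patients × pathways activity
   matrix; singleton sets give a gene-level surrogate profile.
3. **Screen** — one univariate Cox proportional-hazards fit per pathway
   against overall survival retains prognosis-associated pathways
   (p < 0.05), split into risk (HR > 1) and protective (HR < 1).
4. **Cluster** — a structural deep clustering network (autoencoder +
   graph convolution over a patient KNN graph, dual self-supervision via
   a sharpened Student's-t target distribution; NumPy implementation)
   clusters patients on the retained pathways' standardized activities;
   the cluster number k ∈ 2..10 is selected by average silhouette width,
   and for k = 2 cluster 1 is relabeled to the poor-prognosis group.
5. **Validate** — Kaplan–Meier curves, log-rank tests and Cox models per
   subtype, plus a randomized-mutation control (patient bootstrap, then
   within-patient permutation preserving each patient's mutation count)
   that should find no subtype survival signal.

Everything runs on a built-in synthetic cohort generator (modular gene
network, network-local pathway sets, recurrent driver genes, planted
compositional subtype signal, proportional-hazards survival), so the full
pipeline is testable end-to-end with no downloads. The science and the
design choices are documented in [docs/methods.md](docs/methods.md).

## Worked example

The numbered scripts under `analysis/` run the whole study on the
synthetic demonstration cohort (500 patients, 600 genes, 114 pathways, 10
carrying a planted subtype signal with log hazard ratio 0.7):

```bash
python analysis/01_simulate_cohort.py
python analysis/02_smooth_mutations.py
python analysis/03_score_pathways.py
python analysis/04_screen_prognostic.py
python analysis/05_cluster_subtypes.py
python analysis/06_validate_survival.py
python analysis/07_null_model.py
```

Output of the run at seed 1 (abridged):

```
network: 600 genes, 2438 edges (score > 700)
converged in 7 iterations
activity matrix: 500 patients x 114 pathways
retained 65/114 pathways at p < 0.05
  30 risk (HR > 1), 35 protective (HR < 1)
average silhouette by k: {2: 0.265, 3: 0.272, 4: 0.179, ...}
selected k = 3; cluster sizes: {2: 237, 3: 231, 1: 32}
cluster 1: n=32, median OS 9.0 months
cluster 2: n=237, median OS 24.4 months
cluster 3: n=231, median OS 13.8 months
log-rank: chi2=24.93 (df=2), p=3.86e-06
ARI vs planted subtypes: 0.795
screen: real cohort retained 65 pathways, null retained 10
null log-rank p = 0.036 (bootstrap seed 11, permutation seed 12)
```

Reading the numbers: more than half the pathways screen as prognostic
because the planted signal propagates through overlapping, network-local
gene sets; the discovered clusters separate survival sharply
(p ≈ 4e-06) and agree with the hidden subtype labels (adjusted Rand
index 0.8). On this particular seed the silhouette prefers k = 3 by a
hair (0.272 vs 0.265), splitting one subtype in two; across ten seeds
the selection lands on k = 2 in nine (the reproduction script below
measures this). Under the randomized-mutation control the screen
collapses from 65 pathways to 10 — and the null log-rank p, here 0.036,
is anti-conservative by construction and should be read qualitatively;
see the methods note.

The same pipeline runs from files via a single config:

```python
from mutstrat import PipelineConfig, run_pipeline
results = run_pipeline(PipelineConfig(
    edges="results/demo_data/edges.tsv",
    mutations="results/demo_data/mutations.tsv",
    clinical="results/demo_data/clinical.tsv",
    gmt="results/demo_data/pathways.gmt",
    outdir="results/pipeline",
    n_train=350,          # random-normal-sort training/testing split
))
```

which persists every intermediate as TSV plus a JSON manifest of seeds,
parameters and stage hashes (re-running a config reproduces the hashes
byte for byte).

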
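# gnmfclust

Unsupervised discovery of tumor genomic subtypes from genome-wide
copy-number profiles, and selection of cell lines representative of each
subtype.

Tumors of the same histological type carry very different DNA copy-number
aberrations, and those genome-wide aberration patterns — not single genes —
often determine clinical behaviour and drug response. `gnmfclust`
implements a consensus genomic non-negative matrix factorization (gNMF)
workflow that classifies tumors and cell lines from segment-smoothed
copy-number data: quality control against normal-tissue contamination,
pilot hierarchical clustering to bracket the number of clusters,
multi-initiation NMF consensus clustering, model selection by cophenetic
correlation and BIC, a 10-fold cross-validation stability test, and
correlation-based assignment of new samples with survival validation.

## The model

Given a positive matrix **V** (n segments × m samples, diploid = 2), NMF
finds nonnegative **W** (n × r subgroup profiles) and **H** (r × m sample
weights) with V ≈ WH, by minimizing the generalized Kullback–Leibler
divergence

    D(V ‖ WH) = Σᵢⱼ [ Vᵢⱼ ln(Vᵢⱼ/(WH)ᵢⱼ) − Vᵢⱼ + (WH)ᵢⱼ ]

with multiplicative updates that never increase D. Iteration stops when,
checked every 100 steps, D fails to drop by more than 0.001% of its value
at the previous checkpoint. Because a single factorization depends on its
random start, the clustering is a consensus: the Pearson correlation matrix
of H's sample columns is averaged over many seeded runs (default 200), and
average-linkage hierarchical clustering of 1 − (mean correlation), cut into
r groups, gives the assignment.

The number of clusters is chosen by scanning candidate r values and
scoring each with (a) the cophenetic correlation of the consensus
dendrogram and (b) BIC = −2 ln L + 2·r·m·ln(n), where L is a
segment-independent lognormal likelihood of the hard clustering. Minimum
BIC is the primary rule; the greatest cophenetic decrease is the secondary
rule, and disagreements are reported. Details, including the handling of
degenerate variances and the contamination filter, are in
[docs/methods.md](docs/methods.md).

## Worked example

Recover three planted genomic subtypes from a simulated 60-sample cohort
(examples/01_simulate_and_cluster.py):

```python
from sklearn.metrics import adjusted_rand_score
from gnmfclust import default_benchmark_designs, run_gnmf_consensus, simulate_cohort

design = default_benchmark_designs(seed=42)["separable-3"]
matrix, truth, _ = simulate_cohort(design)
result = run_gnmf_consensus(matrix.values, r=3, n_runs=20, base_seed=17)
ari = adjusted_rand_score([truth[s] for s in matrix.sample_ids], result.assignment)
```

This prints:

```
cohort: 200 segments x 60 samples
consensus clustering at r=3 over 20 runs
cluster sizes: [20, 20, 20]
adjusted Rand index vs planted truth: 1.000
```

An adjusted Rand index of 1.0 means the consensus partition reproduces the
planted subtypes exactly. Model selection on the same cohort
(examples/02_model_selection.py) prints the score table and the choice:

```
 r  cophenetic          BIC
 2      1.0000       -12292
 3      0.9989       -17426
 4      0.9973       -16376
 5      0.9950       -15057
min-BIC rule selects r = 3
```

The remaining examples cover contamination QC (03), stability testing
(04), and new-sample assignment with logrank validation (05); each prints
the numbers it computes and a line on how to read them.

## Command line

Every stage is also a subcommand of the `gnmfclust` CLI — `simulate`,
`qc`, `pilot`, `cluster`, `select-model`, `stability`, `assign`,
`validate`, and `run-all` (full workflow from a YAML config, with a JSON
run manifest for reproducibility). `gnmfclust --help` lists options.

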
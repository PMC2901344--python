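# Methods

`gnmfclust` discovers genomic subtypes of tumors from segment-smoothed DNA
copy-number profiles and selects representative samples (e.g. cell lines)
for each subtype. This note documents the model, the algorithmic choices,
the synthetic benchmark the package is validated on, and the limits of what
that validation shows.

## Input model

The universal input is a matrix **V** (n segments × m samples) of positive
copy numbers on the linear scale, diploid = 2. Segments are genomic
intervals of approximately constant copy number produced by upstream
segmentation of array data; segmentation itself (and probe-level
processing) is out of scope, although the conventional segmentation control
parameters (≥ 100 probes per region, p < 1e-5 between adjacent regions,
signal/noise > 0.1) can be carried as provenance metadata. Files use
1-based inclusive coordinates; internally coordinates are 0-based
half-open. Because both the NMF divergence objective and the lognormal
likelihood require strictly positive entries, values at or below a floor
(default 0.01 copies) are clamped at load time; homozygous deletions can
legitimately reach 0, so the floor is a numerical guard, not a biological
statement.

Aberrations are called with strict thresholds: copy number below 1.65 is a
loss, above 2.65 a gain, boundary values normal. The per-sample count of
aberrant segments (the "burden") feeds the QC training-set choice.

An optional dimension-reduction step drops segments whose across-sample
range does not exceed a configurable `min_range` (default 0 = off). This
is a deliberate stand-in: variability filtering is the simplest defensible
reduction, and the package makes no claim that it reproduces any particular
published segment count.

## Contamination QC

Tumor specimens diluted by normal stroma drift toward a flat diploid
profile and blur cluster structure. The QC step trains a forest classifier
on two extremes — the `n_top` highest-burden tumors (default 25% of tumor
samples) versus annotated normals — and reads the fraction of trees voting
"normal" as the sample's contamination probability. Samples strictly above
50% are excluded; normals never enter the clustering matrix. With fewer
than two annotated normals QC is skipped with a warning rather than
inventing a normal class.

The forest is an extremely-randomized-trees ensemble (500 trees, default
feature subsampling, fixed seed). The variant matters: with
impurity-optimal thresholds each split lands midway between pure tumors and
pure normals, an intermediate mixture falls on an essentially arbitrary
side, and vote fractions collapse toward the training prior. Random split
thresholds integrate over cut points, so the normal-vote fraction rises
smoothly with the normal fraction of the sample — which is exactly the
quantity the 50% cutoff is applied to. On the bundled contaminated
benchmark (mixtures with ≥ 70% normal content) this yields exclusion
sensitivity and specificity ≥ 0.9 across seeds.

## Pilot hierarchical clustering

Average-linkage (UPGMA) clustering on Pearson dissimilarity (1 − r between
sample profiles) gives a dendrogram whose large merge-height gaps suggest
how many clusters to scan. The bracket heuristic flags cut levels whose
gap exceeds 10% of the total tree height; if none does, the full requested
range is returned with a low-confidence flag. The dendrogram itself is the
primary output — the heuristic is advisory, and a user-supplied range
always takes precedence. Average linkage is used because it is monotone
and standard for copy-number correlation matrices; the linkage is shared
with the consensus step for consistency.

## Consensus NMF clustering

The factorization V ≈ WH (W: n × r subgroup profiles, H: r × m sample
weights, both nonnegative) is fitted by minimizing the generalized
Kullback–Leibler divergence D(V‖WH) = Σ V ln(V/WH) − V + WH with the
classical multiplicative updates, which provably never increase D.
Numerical choices:

- **Initialization**: W, H i.i.d. uniform on (0, 1] per seeded run.
- **Stop rule**: divergence is evaluated every 100 update steps; iteration
  stops at the first checkpoint whose decrease is ≤ 1e-5 (0.001%) of the
  previous checkpoint's divergence. The step-0 divergence is recorded for
  diagnostics but is not a checkpoint, so comparisons start at step 200.
  A `max_steps` safety valve (default 20,000) warns if reached.
- **Guards**: a 1e-12 additive epsilon in update denominators, inert for
  floored inputs.

A single factorization depends on its initialization, so the clustering is
a consensus over many runs (default 200; run i uses seed base_seed + i):
the Pearson correlation matrix of H's columns is averaged over runs, and
average-linkage clustering of 1 − (mean correlation), cut at exactly r
groups, gives the assignment. A run whose H column is constant (a
collapsed component) would leave the correlation undefined; such runs get
a deterministic 1e-9 ramp added and are counted in the log. A per-run
maximum-weight assignment (argmax over H rows) is available for
diagnostics, but the consensus path is the default.

## Model selection

For each candidate r, two scores:

- **Cophenetic correlation** between the consensus distances (1 − mean
  correlation) and the join heights of the consensus dendrogram, over all
  sample pairs. Values near 1 mean the consensus is tree-like; the value
  typically falls sharply once r exceeds the true cluster number.
- **BIC** = −2 ln L + k ln(n), with k = 2·r·m (a mean and a standard
  deviation per cluster per segment, m segments) and n samples. L is a
  segment-independent lognormal likelihood: within cluster i, the log copy
  numbers of segment t are Gaussian with the cluster's empirical mean and
  standard deviation. The Gaussian normalization constant is included, so
  reported magnitudes are interpretable; it shifts all candidates equally.
  Natural logarithms throughout.

Degenerate variances need care. A σ estimated as 0 (constant segment) is
floored at 1e-3 on the log scale. A singleton cluster is different: its
maximum-likelihood σ is identically 0, and substituting any tiny constant
hands the cluster a large spurious likelihood bonus (the lone sample sits
exactly at its own mean), which rewards splitting off outliers and biases
BIC toward larger r. Singleton clusters therefore borrow the size-weighted
pooled within-cluster σ of the clusters with ≥ 2 samples, per segment,
falling back to the floor only when no informative cluster exists. With
this treatment, minimum BIC recovers the planted cluster number reliably on
the benchmark.

Selection applies two rules: minimum BIC (primary; ties break toward
smaller r) and greatest cophenetic decrease (the r before the largest drop;
requires consecutive candidates). When they disagree, minimum BIC wins and
the report says so prominently. On strongly separated data all candidates
can have cophenetic ≈ 1, making the decrease rule uninformative — another
reason BIC is primary.

## Stability testing

10-fold cross-validation of a chosen model: each repeat holds out 10% of
samples uniformly at random (seeded), re-runs the full consensus procedure
on the remaining 90% at the same r and parameters, maps the new labels onto
the reference by the optimal one-to-one assignment on the confusion matrix
(scipy's linear-sum assignment, optimal for all r), and counts retained
samples whose mapped label disagrees with the reference. The error rate is
total disagreements over total retained assignments across repeats
(default 200). Errors are counted among retained samples only, following
the procedure's literal description; held-out samples are not re-assigned.
If a repeat produces fewer than r clusters, unmatched reference labels
count their samples as errors.

## Assignment of new samples and outcome validation

A new sample joins the cluster of its single best Pearson-correlated
representative (1-nearest-neighbor), with ties broken toward the earlier
representative in input order and logged. Representatives default to all
reference samples and must cover every cluster; restricting them to cell
lines reproduces the "cell-line panel" use case. Clinical relevance is
tested with a k-group logrank test across clusters (lifelines), with
Kaplan–Meier median survival per group reported as "not reached" when
fewer than half the group has events, and optional pooling of small
clusters before testing.

## Synthetic benchmark

The simulator plants r* clusters by giving each a blueprint: diploid
everywhere except disjoint aberrant blocks (default gain to 3.2, loss to
1.2 copies — shifts of +1.2/−0.8 against diploid). Observed values are
blueprint × exp(N(0, σ²)) per cell, i.e. multiplicative lognormal noise
with σ = 0.1 on the log scale by default — the same noise family the BIC
likelihood assumes, which is what makes parameter recovery a closed loop.
Normals are flat diploid blueprints; contaminated samples are convex
mixtures w·normal + (1−w)·tumor blueprint before noise, w uniform in
[0.7, 0.9]. The segment grid is 22 pseudo-chromosomes of uniform 1 Mb
segments.

Named designs: `separable-3` (3 × 20 samples, 200 segments, strong
aberrations — the anchor for exact recovery), `overlapping-4` (weaker
shifts, more noise), `null` (no structure), `contaminated` (72 clean
tumors, 18 mixtures, 10 normals). Test and benchmark problem sizes (10–20
consensus runs, 10 selection replicates, 20 stability repeats) are scaled
for quick desk-side iteration; they are smaller than the 200-run defaults
a production analysis would use, and the defaults remain 200.

What the simulator does **not** emulate: probe-level noise and waviness,
allele-specific signal, chromosome-arm correlation structure, recurrent
but partially overlapping aberrations across subtypes, and segment grids
that differ between samples. Passing recovery tests therefore shows the
machinery is correct under its own model assumptions, not that any
particular real cohort will cluster cleanly.

## Known limitations

- The dimension-reduction filter is a stand-in; no published segment count
  is reproduced.
- Consensus determinism is tied to the base-seed + offset scheme; running
  runs independently in parallel with other seeds gives statistically
  equivalent but not bit-identical results.
- BIC with k = 2·r·m treats all segment parameters as free; with strongly
  correlated segments this overcounts, penalizing large r more than an
  effective-parameter count would.
- Real cohort-scale results (hundreds of samples × thousands of segments,
  200 runs × several ranks) are compute-heavy; the implementation is plain
  vectorized NumPy on one core.
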
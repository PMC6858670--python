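# Methods

This note records the models, estimands, numerical conventions and design
choices behind `codaplot`, and what the synthetic-data tests do and do not
demonstrate about real data.

## Compositional model

Counts are treated as multinomial draws from per-sample proportion vectors
whose total is an instrument artifact. All analysis therefore happens in
log-ratio coordinates. The centered log-ratio (CLR) uses **log base 2
throughout**, so `diff.btw` values read directly as log₂ fold changes and
the Aitchison distances reported here are √(Σ Δlog₂²). The base is a
parameter (`log_base`) but every documented number assumes 2.

### Zero handling

* **CZM (count-zero-multiplicative), the default.** For a sample with
  total depth *n* and *Z* zero cells, each zero receives the proportion
  δ = frac/(n+1) with frac = 0.65 by default, and each non-zero count
  x_j becomes (x_j/n)·(1 − Zδ). Ratios between observed counts are
  preserved exactly — the property that makes the replacement
  "multiplicative". If Zδ ≥ 1 the sample is too sparse for its depth and
  the error message directs the user to filter first. Some published
  multiplicative-replacement implementations add a post-hoc adjustment
  when an imputed value exceeds an observed minimum; this package pins
  the plain formula above as normative, applied per sample with no
  cross-sample information.
* **Pseudocount.** Adds 0.5 to every cell; faster and simpler but
  perturbs observed ratios slightly. CLR is scale-invariant, so no
  re-closure is needed.

### Filtering

Rules apply in a fixed order — metadata selection, then sample totals,
then feature totals over the *retained* samples, then maximum per-sample
proportion — because feature totals change when samples are dropped and
the order is therefore observable. Thresholds keep-if-≥. All defaults are
0: the package never filters silently. Every removal is recorded with the
rule that triggered it.

## Dirichlet Monte-Carlo differential abundance

For each sample, K = 128 (default) posterior proportion vectors are drawn
from Dirichlet(x + γ) with prior γ = 0.5, then CLR-transformed. The draw
uses normalized gammas from a single `numpy` Generator seeded explicitly;
identical seeds give bit-identical ensembles. K and γ are parameters
(`mc_instances`, `prior`).

### Effect estimands

Within each group the CLR values of a feature are pooled across samples
and instances (|A|·K and |B|·K values). The estimands are defined by
**full pair enumeration**:

* `diff.btw` = median of b − a over all ordered between-group pairs,
* `diff.win` = max over groups of the median |u − v| over unordered
  within-group pairs,
* `effect` = `diff.btw`/`diff.win`, with 0/0 → 0 and x/0 → signed
  infinity (exact zeros have measure zero except for degenerate constant
  input, which should not crash),
* `overlap` = the smaller of the fractions of between-group differences
  above and below zero; differences exactly zero are split evenly between
  the two tails, so a fully degenerate feature reports 0.5.

The enumeration definition is order-independent and testable against a
brute-force oracle. Because enumerating (10·128)² pairs per feature is
wasteful at production scale, the default mode subsamples
`max_pairs` = 10 000 seeded random pairs per estimand; it converges to
the exact values as the budget grows and is itself deterministic given
the seed. `mode="exact"` remains available and is what the oracle tests
exercise.

### Hypothesis tests and expected BH

Per instance and feature, two-sided Welch unequal-variance t and Wilcoxon
rank-sum tests compare the groups across samples; p-values are
Benjamini–Hochberg adjusted across features within the instance, and the
reported `*.ep` / `*.eBH` are arithmetic means over instances. Averaging
over posterior instances is what makes the values "expected" and is
deliberately conservative: a feature must be significant in typical
posterior draws, not merely in the point estimate.

Conventions: Welch with zero pooled variance reports p = 1 when the means
agree and p = 0 otherwise (the limit behaviour, avoiding NaNs in the
mean). The rank-sum test uses an exact tie-free null distribution (a
cached subset-sum table) when the combined sample size is ≤ 20, and the
normal approximation with tie and continuity correction otherwise; the
threshold is a parameter. BH is the standard step-up with NaNs excluded
from m and propagated.

## Ordination and clustering

CLR-PCA centers each feature across samples and takes the SVD of the
centered samples × features matrix; variance fractions are s²/Σs². Form
scaling (scores = U·S) is the default so score distances approximate
Aitchison distances; covariance scaling is available. Singular-vector
signs are fixed by making each loading vector's largest-magnitude element
positive, for backend-independent output. Because CLR vectors sum to zero
and centering removes one more degree of freedom, at most
min(n−1, D−1) singular values are non-negligible.

Hierarchical clustering is implemented with Lance–Williams updates
(single, complete, average, Ward in the Ward.D2 squared-distance
convention) rather than delegated, because the package guarantees
deterministic tie-breaking by the smallest (row, column) cluster pair;
the implementation is cross-checked against `scipy.cluster.hierarchy` on
tie-free instances via cophenetic matrices. `aitchison` and
`euclidean_clr` distances are identical by construction and both offered
for discoverability; `jaccard_presence` works on raw presence/absence.

## Synthetic data generator

The generator emulates a two-condition sequencing study: a log₂-normal
base composition (mean 0, sd 1.5 — proportions spanning roughly two
orders of magnitude around 1/D, as in functional GO-slim profiles);
spiked features multiplied by the fold change in group B *in proportion
space before re-closure*, deliberately reproducing the compositional
confound whereby an absolute change in some features shifts the apparent
abundance of all others while leaving non-spiked pairwise ratios intact;
replicate variability as Dirichlet(dispersion × target) with dispersion
500, i.e. per-feature replicate CVs of roughly 0.2–1.4 across the
abundance range; and sequencing as a multinomial at a depth uniform on
5 000–20 000 reads. Defaults: 200 features, 10 + 10 samples.

What it does **not** model: phylogenetic or co-occurrence correlation
between features, batch effects, variable library preparation efficiency,
or overdispersion beyond the Dirichlet. Passing the calibration and
recovery tests therefore shows the statistics behave correctly under the
compositional sampling model, not that real studies with structured noise
will achieve the same sensitivity.

Test scale: the calibration check uses 20 replicate null tables and the
recovery check 10 spiked replicates at the default scale; a full set runs
in well under a minute on one CPU, which is why the suite can afford to
run them unconditionally.

## Pipeline reproducibility

A run is a pure function of (inputs, config): the flat-YAML config names
every threshold and seed, unknown keys are errors, and all data artifacts
(TSV/JSON/Newick) are byte-identical across reruns. Each rendered plot
has a sidecar TSV carrying exactly what is drawn — for effect plots this
includes per-feature quantiles (2.5–97.5%) of the per-instance effect
distribution, the uncertainty detail an interactive display would show on
hover — and an exported, commented Python script that regenerates the
sidecar byte-identically from the original inputs.

## Known limitations

* Two-group, unpaired designs only; no repeated measures, covariates or
  >2 groups.
* No ANOSIM/PERMANOVA-style whole-community tests.
* CZM variants with post-hoc minimum adjustment, isometric/additive
  log-ratios, and Bayesian-multiplicative replacement families are out of
  scope.
* The effect estimands are the pooled-pair-enumeration definitions stated
  above; other software computes closely related but not identical
  quantities (e.g. instance-paired medians), so numeric agreement with
  such tools is approximate by design.
* `signed infinity` effects (zero within-group dispersion with a non-zero
  between-group difference) propagate as ±inf; downstream ranking treats
  them as largest.
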
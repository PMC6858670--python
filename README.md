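# codaplot

Compositional exploration of high-throughput sequencing count tables.

## The problem

A sequencing instrument fixes the total number of reads it returns, so a
count table — features (genes, OTUs, transcripts, GO terms) by samples —
carries only *relative* information: it is a composition. Comparing raw
counts or naively normalized counts across samples can invert effects and
fabricate correlations. `codaplot` implements the standard compositional
alternative for exploratory and differential-abundance analysis of
microbiome, metagenome, metatranscriptome and functional (GO-slim)
profiles, for analysts who want the whole workflow — filtering, zero
handling, transformation, ordination, clustering, effect sizes — behind
one consistent, scriptable surface.

## The method

Each sample's counts **x** are mapped to a strictly positive composition
(count-zero-multiplicative replacement, which gives each zero the
proportion δ = frac/(n+1) and shrinks non-zeros multiplicatively so their
ratios are exact; or a uniform pseudocount), then to the centered
log-ratio

> clr(x)ⱼ = log₂ xⱼ − (1/D) Σₖ log₂ xₖ ,

a zero-sum vector in which Euclidean geometry is meaningful: the Euclidean
distance between CLR vectors is the Aitchison distance, PCA of the CLR
matrix gives the compositional biplot, and hierarchical clustering of
Aitchison distances groups samples.

Count uncertainty is propagated by Dirichlet Monte-Carlo sampling: K
posterior instances of each sample's proportions are drawn from
Dirichlet(x + ½) and CLR-transformed. For a two-group comparison the
per-feature statistics are computed over the pooled posterior values:

* `diff.btw` — median between-group difference (log₂ units);
* `diff.win` — the larger within-group median absolute pairwise difference;
* `effect`  — `diff.btw / diff.win`, a standardized effect size;
* `we.eBH`, `wi.eBH` — Welch-t and Wilcoxon rank-sum p-values computed per
  instance, Benjamini–Hochberg adjusted across features within each
  instance, and averaged over instances ("expected BH").

Effect plots (`diff.win` vs `diff.btw`; the diagonals are |effect| = 1)
and MA plots (abundance vs difference) visualize the result.

## Worked example

Generate a synthetic two-group study (100 features, 8 + 8 samples, five
features spiked 8-fold in group B) and test for differential abundance:

```bash
codaplot synth --out-prefix toy --n-features 100 --samples-per-group 8 \
    --n-spiked 5 --fold-change 8 --seed 42
codaplot effects toy_counts.tsv --metadata toy_metadata.tsv \
    --group-variable group --out toy_effects.tsv --seed 1
```

The six features with the largest |effect|:

```
            rab.all  diff.btw  diff.win  effect  wi.eBH
feature_id
F003          3.015     3.190     0.307  10.383   0.004
F004          3.764     2.806     0.500   5.611   0.004
F002          0.484     3.796     0.853   4.447   0.004
F001          2.668     3.006     0.717   4.191   0.004
F005         -1.770     3.346     2.126   1.574   0.035
F093         -0.663    -1.039     0.692  -1.502   0.746
```

The five spiked features (F001–F005) lead the ranking with between-group
differences near the true log₂ 8 = 3 and expected-BH values well below
0.05; the best background feature (F093) sits just past |effect| = 1.5
with an insignificant `wi.eBH`, illustrating why calling features on the
effect size *and* the expected test value together is the conservative
choice.

The same analysis is available as a library (`codaplot.aldex_effects`),
as sklearn-style estimators that compose with pipelines
(`CZMImputer() | CLRTransformer() | CLRPCA()`, `DirichletEffectEstimator`),
and as a one-shot configured run:

```bash
codaplot run --config run.yaml   # writes tables, SVG/PNG plots, sidecar
                                 # data and a reproduction script per plot
```

Every plot's `reproduce_<kind>.py` regenerates that plot's sidecar data
byte-identically, with every user-chosen parameter as a commented variable
at the top.

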
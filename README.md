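# ccprog

Composition-aware prognostic gene screening for heterogeneous tumor samples:
per-gene mixture-of-regressions clustering against measured cell-type
fractions, chi-square relapse correlation, SAM/NSC signature building, and
survival evaluation of the resulting risk groups.

## The problem

Bulk expression profiles of prostate tumor tissue mix signal from several
cell populations — predominantly tumor epithelium and stroma — in proportions
that vary widely from sample to sample. A gene whose expression marks
aggressive disease in tumor cells can look flat, or even inverted, in bulk
data because the tumor-cell fraction differs between samples more than the
biology does. `ccprog` addresses this by modelling each gene's bulk
expression as a composition-weighted sum of cell-type coefficients:

```
y_i = Σ_d p_id · β_{z_i, d} + ε_i ,   ε_i ~ N(0, σ²)
```

where `p_id` is the measured fraction of cell type `d` in sample `i` and
`z_i` is a latent two-level cluster label. The model is a finite mixture of
linear regressions fit by EM; the cluster labels are then cross-tabulated
against observed biochemical relapse, and genes whose clustering correlates
with relapse (chi-square p < 0.005) are kept. Restricted model variants in
which only the tumor (or only the stroma) coefficient differs between
clusters are compared by BIC to attribute each selected gene to the cell
type driving the signal (differences of 2 or more counted as strong
evidence).

Downstream, samples with tumor-cell fraction strictly above 50% are retained,
a SAM-style moderated d-statistic with permutation p-values ranks the
tumor-attributed genes between relapse and non-relapse groups, and a
nearest-shrunken-centroid (NSC) classifier — optionally augmented with the
Gleason sum as one evenly weighted extra feature — is trained on the top
genes and evaluated by exhaustive cross-validation over every train/test
split with fixed per-class training counts. Risk groups are compared with
Kaplan-Meier curves, the logrank test, and a Breslow partial-likelihood
hazard ratio.

## Worked example: the core model

`MixtureRegression` follows the familiar model/results shape: construct from
aligned expression and composition tables, call `.fit()`, inspect the
results object.

```python
import numpy as np
from ccprog import generate_dataset, SyntheticConfig, MixtureRegression, MixtureSpec

ds = generate_dataset(SyntheticConfig(seed=42))          # 500 genes x 130 samples
model = MixtureRegression.from_tables(ds.expression, ds.composition,
                                      "gene1", MixtureSpec(seed=1))
res = model.fit()
print(res.summary())
```

Output (real, reproducible):

```
Mixture of linear regressions (EM)
  clusters: 2   samples: 130
  varying: tumor, stroma
  log-likelihood: -115.7006   BIC: 260.6064
  converged: True in 43 iterations
  sigma2: 0.141442
  cluster   weight  beta[tumor]  beta[stroma]
        1   0.579      5.0755     11.2949
        2   0.421      7.1835     11.8482
```

`gene1` is a planted tumor-differential gene: the two clusters differ by
about 2 log2 units in the tumor coefficient and agree in the stroma
coefficient. `res.responsibilities`, `res.hard_labels`, `res.beta`,
`res.loglik` and `res.bic` expose the fitted quantities; `fit_gene_batch`
runs the same EM over thousands of genes at once through a compiled kernel.

## Worked example: the pipeline CLI

```
$ ccprog simulate --seed 42 --out data
wrote 500 genes x 130 samples to data

$ ccprog screen --expr data/expression.tsv --composition data/composition.tsv \
                --clinical data/clinical.tsv --seed 1 --out screen.tsv
selected 7 gene(s) at p<0.005 (6 attributed to tumor)

$ ccprog signature --expr data/expression.tsv --composition data/composition.tsv \
                   --clinical data/clinical.tsv --genes screen.tsv --seed 1 --out sig.json
signature of 3 gene(s): gene5, gene3, gene6

$ ccprog predict --model sig.json --expr data/expression.tsv --out pred.tsv
classified 130 sample(s)

$ ccprog survival --pred pred.tsv --clinical data/clinical.tsv --out surv.tsv
logrank chi2=6.722 p=0.0095 HR=5.35 (O/E ratio 5.08)
```

`ccprog normalize` quantile-normalizes an external test set onto a reference
cohort's distribution over their common probes, for cross-platform
prediction.

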
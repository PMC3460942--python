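# Methods note

## Model

For one gene, the bulk log2 expression of sample `i` is modelled as

```
y_i = Σ_d p_id · β_{z_i, d} + ε_i ,   ε_i ~ N(0, σ²_{z_i})
```

- `p_id`: measured fraction of cell type `d` (tumor, stroma) in sample `i`;
  rows of the composition table sum to 1.
- `z_i ∈ {1, …, K}`: latent cluster label with mixing weights `π_k`
  (default `K = 2`).
- `β_{k,d}`: cell-type coefficient of cluster `k` — the expected expression
  contribution of a pure cell-type-`d` sample in that cluster.
- No intercept by default: the composition columns already sum to 1, so an
  intercept would be collinear with the coefficient block.
- Shared variance across clusters by default (`σ²_k ≡ σ²`); per-cluster
  variance is available via `MixtureSpec(shared_variance=False)`.

Restricted variants hold a subset of coefficients equal across clusters:
the tumor-restricted model lets only `β_{k,tumor}` vary (stroma tied), and
symmetrically for stroma. Free-parameter counts used in BIC
(`BIC = −2·loglik + q·ln n`): `q = K·|varying| + |tied| + (K−1) + 1` with
shared variance (full K=2 two-cell-type model: q = 6; each restricted
model: q = 5).

## Estimation

EM with responsibilities in log space (log-sum-exp; no underflow to NaN) and
a weighted-least-squares M-step whose design ties the non-varying
coefficient columns across clusters. Conventions:

- `max_iter = 500`, convergence when the log-likelihood changes by less
  than `tol = 1e-6`.
- 10 seeded restarts: restart 0 splits at the median residual of a pooled
  fit (a deterministic hard split), the rest draw random soft
  responsibilities. The best final log-likelihood wins.
- Variance floor `1e-8` (degenerate zero-variance solutions are clipped); a
  cluster whose total responsibility falls below `1e-6·n` marks the restart
  invalid.
- Clusters are reported in canonical order (ascending tumor coefficient),
  so labels are reproducible up to this convention; mixture labels are
  otherwise defined only up to permutation.
- Singular M-step systems (e.g. perfectly symmetric responsibilities) fall
  back to the minimum-norm least-squares solution.

The batched driver (`fit_gene_batch`) runs the identical algorithm for all
(gene, restart) pairs in one numba-compiled kernel with a hand-rolled
partial-pivot solve; the pure-numpy E/M steps remain the reference
implementation and are what the unit-test oracles check. The kernel exists
only for speed (a 500-gene screen takes seconds on one CPU).

## Screen

Per gene: full-model EM fit → hard cluster labels → 2×2 contingency of
cluster vs observed relapse (samples with missing relapse excluded) →
Pearson chi-square with 1 df, no continuity correction (a flag warns when
any expected count is below 5) → selected iff p < 0.005. For selected genes
only, both restricted models are fit and the gene is attributed to the cell
type with the smaller BIC; |ΔBIC| ≥ 2 is flagged as strong evidence. Ties
attribute to tumor. No multiple-testing adjustment is applied to the
selection (the threshold is a raw p-value); a Benjamini-Hochberg FDR column
is emitted for information. Per-gene EM failures are recorded in a failure
column, never raised.

## Signature

- Enrichment filter: samples with tumor fraction strictly greater than the
  threshold (default 0.5).
- SAM-style selection: `d = (mean₁ − mean₀) / (s + s₀)` with `s` the pooled
  two-sample standard deviation scaled by `sqrt(1/n₁ + 1/n₀)`. The
  exchangeability constant `s₀` minimizes the coefficient of variation of
  the median absolute deviation of `d` across `s`-quantile windows,
  searched over the percentiles of `s` in 5% steps (median of `s` when
  fewer than 20 genes). Permutation p-values enumerate the label
  assignments exhaustively when `C(n, n₁) ≤ n_perm` (p = exact fraction
  with |d| at least as extreme); otherwise `n_perm` seeded random
  assignments with `p = (1 + #extreme)/(1 + n_perm)`. Top genes are taken
  by |d| rank among those with p below the gate (defaults: 7 genes,
  p < 0.002).
- NSC: standardized centroid differences
  `d_jk = (c_jk − c_j)/(m_k (s_j + s₀))`, `m_k = sqrt(1/n_k − 1/n)`,
  `s₀ = median(s_j)`, soft-thresholded by Δ; classification minimizes the
  squared standardized distance to the shrunken centroid minus
  `2 log π_k`, ties toward the first class. When Δ is not given it is
  chosen by deterministic stratified inner cross-validation (round-robin
  folds) minimizing misclassifications, ties resolved toward the larger
  (sparser) Δ.
- The Gleason sum can be appended as one extra feature; NSC's per-feature
  standardization then weights it like each gene ("even weighting").
- Exhaustive cross-validation enumerates all
  `Π_c C(n_c, k_c)` train/test splits in lexicographic order and pools
  predictions; sensitivity is recall on the relapse class, and a metric
  with an empty denominator is reported as undefined (NaN), never 0.

## Survival

Kaplan-Meier product-limit curves and the two-group logrank statistic are
computed via lifelines; the reported median is the smallest event time with
S(t) ≤ 0.5 (NaN with a warning when the curve never reaches 0.5; exact 0.5
tolerated to 1e-12 for floating-point round-off). The hazard ratio is a
hand-written Newton maximization of the Breslow partial likelihood for the
binary group covariate — Breslow tie handling is the stated convention
here, whereas lifelines' Cox fitter uses Efron (the two coincide without
tied event times, which the tests exploit as a cross-check). Monotone
likelihoods are capped at |log HR| = 20 with a warning. The cruder
observed/expected ratio `(O₁/E₁)/(O₀/E₀)` is reported alongside.

## Synthetic generator

The generator exists to exercise the pipeline under its own modelling
assumptions at a realistic scale; it is a stated emulation, not a
reproduction of any real cohort. Defaults (the study conditions used by the
tests and the acceptance script):

| parameter | default | rationale |
| --- | --- | --- |
| samples | 130 | screening-cohort scale |
| genes | 500, of which 7 tumor-differential | desk-scale gene pool with a signature-sized planted truth |
| composition | Dirichlet(0.8, 1.6) over (tumor, stroma) | tumor-fraction spread ~0–1, mean 1/3, ≈20–25% of samples above 0.5 |
| baselines | β ~ U(6, 12) per cell type | typical log2 microarray range |
| effect size | 2.0 log2 units on the tumor coefficient, random sign | a 2-fold observed change at 50% tumor content, within reported signature fold-change ranges |
| residual σ | 0.5 log2 units | effect = 4σ at the coefficient level |
| relapse prevalence | 0.6 | relapse-enriched screening cohort |
| survival | exponential, baseline median 35 months, HR 2.6 between groups, ~30% uniform censoring | matches the effect sizes the survival module is designed to detect; the censoring horizon is solved numerically so the censored fraction hits the target in expectation |
| Gleason | 6 + Binomial(3, 0.7/0.3 by group) | higher grades in the relapse group |

The latent group equals relapse status unless `label_noise` is set. Scope
limits: no probe-level artifacts, batch effects, platform differences, or
more than two latent groups.

## Numerical conventions and interpretation choices

- Coefficient-recovery error is summarized as the mean absolute error over
  the 2×2 coefficient matrix, averaged over replicate fits. The coefficient
  of the cell type with the smaller composition share is weakly identified
  in any single fit, so the max-entry error is substantially larger than
  the mean even when estimation is working as intended.
- Label agreement between fitted hard labels and generating groups takes
  the better of the two label assignments (mixture labels are defined up to
  swap).
- Cluster separation is quoted in units of the residual σ at the
  coefficient level. Because bulk expression observes coefficients through
  the composition weights, a separation carried by a single cell type is
  attenuated by that cell type's fraction: a tumor-only separation of kσ
  looks like ~k·p_tumor·σ to a typical sample (mean tumor fraction 1/3).
  Identifiability of tumor-only effects is therefore intrinsically weaker
  than the coefficient-level separation suggests, which is visible in the
  screen's per-gene power and is a property of the model, not of the
  optimizer (EM restarted from the generating labels reaches the same
  likelihood).

## Limitations

- The chi-square selection relies on the large-sample approximation; with
  130 samples and balanced clusters this is adequate, but heavily skewed
  cluster sizes trigger the low-expected-count warning.
- The composition table is treated as known and noise-free.
- The hazard model is univariate; no adjustment for clinical covariates.
- Exhaustive cross-validation is capped at 10⁶ rounds; larger designs must
  use sampling (not implemented).
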
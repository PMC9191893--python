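# Methods

This note documents the statistical model, the synthetic study design, the
numerical conventions that are frozen for reproducibility, and the known
limitations.

## Confounder-adjusted association networks

Expression co-variation between an lncRNA and an mRNA can be driven by
shared copy-number alterations or by promoter methylation rather than by
regulation.  The core model therefore regresses each gene's z-scored
expression on three z-scored covariates — its representative
promoter-methylation probe, its gene-level copy number, and one lncRNA —
and tests only the lncRNA coefficient (two-sided t, n − 4 df).  Per-pair
ordinary least squares is used deliberately: no shrinkage, no interaction
terms, no joint multi-lncRNA model.  The Benjamini–Hochberg family is all
fitted pairs of a dataset (not per-lncRNA), with the significance cutoff at
adjusted p < 10⁻³.

`build_network` evaluates the ~10⁶ pairs per cohort via the
Frisch–Waugh–Lovell decomposition: per gene, the response and all lncRNA
vectors are residualized once against [1, methylation, copy number], after
which each lncRNA coefficient, its standard error, and the full coefficient
vector follow from scalar operations.  This path is algebraically identical
to the per-pair normal equations; the test suite asserts agreement with
`fit_pair` to 10⁻⁸ on sampled pairs, and `fit_pair` itself against an
independent normal-equation oracle on 1,000 random instances.

Degenerate designs (collinear covariates, zero-variance residualized
lncRNAs) yield flagged records with p = 1 rather than exceptions, so a
pathological feature cannot abort a network build.  Cis (same-chromosome)
pairs are included by default; `exclude_cis=True` removes them without any
claim about which convention is "correct".

## Preprocessing conventions (frozen)

* mRNA filter: normalized expression ≥ 1 in ≥ 75% of samples, boundary
  inclusive.
* lncRNA filter: median > 0 AND 90th percentile > 0.1, evaluated on the
  input scale as given (the package does not guess whether inputs are log
  scale); percentiles use numpy's linear-interpolation definition.
* Probe selection: per gene, the probe with the most negative Spearman
  correlation (average ranks for ties) to that gene's expression; score
  ties break by lexicographic probe id, making the choice independent of
  probe order.  The most negative probe wins even when it is non-negative.
* z-scores use the sample (n − 1) standard deviation; zero-variance
  features are dropped with a warning.
* Missing values are rejected outright — no imputation policy is silently
  applied.

## Module filtering, annotation, and assignment

Modules arrive with precomputed density scores (they are consumed, never
recomputed from screen profiles).  Filtering keeps non-syntenic modules
with density ≥ 0.5 (inclusive).  Re-annotation runs upper-tail
hypergeometric over-representation of module members against each gene-set
collection, BH within the collection, and reports the top five significant
sets; a module is proliferation-linked when any significant annotation is
one of the configured proliferation signatures (MYC targets V1/V2, E2F
targets, G2/M checkpoint, mitotic spindle, cell cycle).

An lncRNA joins a module when two independent tests both pass BH-adjusted
p < 0.05 over all candidate (lncRNA, module) pairs (separate BH families
per test):

1. **Enrichment** — upper-tail hypergeometric overlap between the lncRNA's
   significant partner genes and the module members, with the universe
   being the genes actually fitted for that lncRNA (the conservative
   standard when no universe is prescribed).
2. **Randomization** — the statistic is |mean of the lncRNA's fitted
   coefficients over the module members|, compared with 1,000 same-size
   gene sets drawn uniformly without replacement from the fitted universe.
   All fitted coefficients enter the mean, not only significant ones:
   restricting to significant pairs would inject selection bias into the
   null comparison (a signed-mean statistic is available via
   ``statistic="mean"``).  The empirical p uses the add-one
   (Davison–Hinkley) formula, so its minimum is exactly 1/(n_draws + 1) and
   it can never be zero.

Null draws are implemented as rejection-sampled distinct index rows with a
shared cumulative-sum trick across module sizes; this is an exact uniform
without-replacement sampler, just organized for speed.  Direction is the
sign of the (signed) average coefficient.  Candidate lncRNAs are those with
at least one significant network partner — others cannot pass test 1 by
construction.

## Robust rank aggregation

For each module with assigned lncRNAs, the positive-direction lncRNAs are
ranked by descending average coefficient and the negative-direction ones by
ascending (ties break by id).  Aggregation over the per-module lists uses
the order-statistic method: each item's normalized rank vector r (rank/N,
with 1 for absent lists) is sorted, the score at position k is the binomial
upper tail P(U₍ₖ₎ ≤ r₍ₖ₎) = Σ_{j≥k} C(m,j) r^j (1−r)^{m−j}, rho is the
minimum over k, and p = min(rho·m, 1) bounds the selection over k.  The
normalized-rank universe is the full set of network lncRNAs, not only the
assigned ones — the meta-analysis asks "which of all candidate lncRNAs
consistently rank high", and a small universe would make the normalized
ranks too coarse to resolve.

Stability: the aggregation is re-run m times leaving one list out, and the
m p-values are averaged (arithmetic mean by default; geometric exposed as
an option, off by default), then BH-corrected over the universe at
α = 0.05.  Positive and negative aggregations form separate BH families.
Exact binomial summation is used throughout (m ≤ 1000 in any realistic
setting); the test suite checks the scores against both the regularized
incomplete-beta identity and a 10⁶-draw Monte-Carlo order-statistic oracle.

## Downstream analytics

* **Treatment screen** — log2 fold changes from total-count-normalized
  means with pseudocount 0.5; features at ≥ 2-fold form ranked up/down
  lists that feed the rank aggregation across datasets.  This is a
  deliberate simplification: only the ≥ 2-fold flags and the fold-change
  *rankings* matter downstream, so a dispersion-modelling count fit is not
  re-implemented.  Total-count normalization carries a small composition
  bias (a planted 2-fold shift is estimated slightly below 2 when shifted
  features make up a noticeable library fraction); the planted default is
  therefore a 3-fold shift, and tests assert the estimator's accuracy
  rather than an exact threshold crossing.
* **TSS proximity** — peaks are 0-based half-open; the 1-based TSS is
  converted to a 0-based point t, and a dataset counts when any peak
  intersects the closed window [t − w, t + w] (w = 10 kb default).  The
  window is symmetric, hence strand-independent.  Candidate vs background
  dataset counts are compared with a two-sided rank-sum test.
* **Proliferation activity** — per-sample mean expression over the union of
  configured proliferation sets; bottom/top floor(n/4) samples form the
  lower/upper activity groups (ties by sample id), compared per feature by
  rank-sum with a median fold change (pseudocount = half the smallest
  positive matrix value).
* **Quartile contrast** — identical grouping keyed to one anchor feature's
  expression.
* **Utilities** — one-way ANOVA on category × cohort count tables (the
  all-equal table returns F = 0, p = 1), Tukey's fences with linear-interp
  quartiles, and Fisher's method for one-tailed p-values.

## Survival

The log-rank test is implemented directly because a *signed* Z with a fixed
orientation is required: Z = (E₁ − O₁)/√V for the high-expression group, so
Z > 0 means fewer events than expected in the high group, i.e. better
survival.  "Favorable" (Z > 1.96) therefore literally means overexpression
associates with longer overall survival; this convention is frozen because
a sign error silently flips the biology.  Ties use the standard aggregated
hypergeometric variance (no Efron correction — this is log-rank, not Cox).
Median split: strictly above the median → high; features with more than
half their values tied at the median cannot be split with acceptable
balance and are classified `none` with a warning.  The implementation is
cross-checked against lifelines (chi-square equality) and a hand-computed
six-sample fixture.

## The synthetic study

The generator produces every input the pipeline consumes, with planted
truth:

* **Cohort** (defaults: 300 samples × 3,000 genes × 300 lncRNAs).  Gene
  expression is built exactly as the regression assumes: a baseline of 5,
  minus β_DM times the z-scored true methylation probe, plus β_CNV times
  z-scored copy number, plus driver-lncRNA terms, plus Gaussian noise
  (β_DM = β_CNV = 0.5, β_lnc = 0.5, noise SD 1 — moderate standardized
  effects typical of expression QTL-scale signals).  Methylation is
  generated on the β-value scale (logistic transform of a latent normal),
  three probes per gene with exactly one anti-correlated true probe, so
  probe selection is genuinely exercised.  Copy number is continuous
  log-ratio-like; the exact scale is immaterial after z-scoring.
* **Confounder-only negatives** — 10% of genes receive methylation/CNV
  signal only, with their copy-number track set to the genomic locus of a
  paired lncRNA (lncRNA expression couples to its locus copy number at
  ρ = 0.7).  Naive lncRNA–gene correlation is fooled on these pairs; the
  adjusted model must stay at the nominal error rate.  This contrast is the
  package's headline calibration check.
* **Driver wiring** — 10 inducers and 10 suppressors.  The first half of
  the 20 driver modules is induced by *all* inducers (+β each), the second
  half suppressed by *all* suppressors (−β each).  Keeping the two
  regulator classes on disjoint module halves bounds the number of driver
  terms per gene (and hence the residual variance a single-lncRNA
  regression must absorb) while preserving the cross-module consistency the
  rank aggregation detects.  Driver expression profiles are drawn exactly
  orthogonal in-sample (random rotation, centered, unit sample SD), so each
  planted coefficient is estimable without leakage from co-planted drivers.
  Real regulators are collinear; the synthetic cohort is a controlled
  experiment in which planted effects are identifiable by construction, and
  a pass here demonstrates correctness of the machinery, not power under
  arbitrary collinearity.
* **Decoy modules** — syntenic decoys (all members from one chromosome) and
  low-density decoys (density < 0.5) that the filter must reject, plus
  plain null modules that carry no planted signal and must not be
  proliferation-annotated.
* **Gene sets** — proliferation-named sets drawing 80% of members from the
  driver-module gene pool (so driver modules annotate as
  proliferation-linked), plus random background sets spread over the other
  seven broad hallmark categories.
* **Treatment counts** — negative binomial (dispersion 0.1, lognormal mean
  ≈ 200) with a 3-fold planted shift for the consistently up/down lncRNAs
  in ceil(0.8 × 10) datasets, and single-dataset decoys that the
  meta-analysis must not call.
* **Survival** — exponential event times with hazard
  λ₀·exp(Σ sign·0.7·z_gene) over planted prognostic genes; independent
  exponential censoring calibrated to a ~30% censor fraction.
* **Peaks** — planted lncRNAs receive a peak within 80% of the 10-kb
  window of their TSS in ~80% of the 12 datasets; backgrounds are uniform.

Determinism: one master seed; each generator derives an independent child
stream (`default_rng([stream_offset, seed])`), so identical config + seed
gives byte-identical outputs and stages can regenerate independently.

### What the generator does not emulate

Read-level sequencing, isoform structure, realistic copy-number
segmentation and linkage, collinear regulator programs, batch effects, and
non-exponential survival.  Passing tests demonstrate that the estimators
and decision rules are correct under the generative model they assume — not
that the biological conclusions transfer to any particular real cohort.

## Problem sizes used in checks

The end-to-end recovery check runs the full default cohort (300 × 3,000 ×
300, 40 modules, 1,000 randomization draws) in a few seconds on one CPU.
Calibration checks use 2,000 null pairs at n = 200; parameter recovery uses
β ∈ {0.2, 0.5} at n ∈ {100, 400}; the randomization null uses 500 replicate
modules; the rank-aggregation oracle uses 10⁶ Monte-Carlo draws; survival
calibration uses 400 null replicates at n = 200.  These sizes give binomial
standard errors small enough for 3·SE tolerance bands around every
stochastic assertion.

## Known limitations

* Per-pair OLS ignores correlation between lncRNAs; jointly regulating
  lncRNAs split credit in real data.
* The fitted-universe convention for hypergeometric tests is conservative;
  a genome-wide universe would produce smaller p-values.
* Total-count normalization in the treatment screen is biased under strong
  composition shifts (documented above).
* The randomization statistic |mean| cannot distinguish a module half
  positive / half negative from a null module; the signed-mean option
  exists for that case.
* The prognostic caller is univariate; no adjustment for clinical
  covariates or competing risks.
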
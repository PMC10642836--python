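# Methods

This note documents the statistical procedures `rbdge` implements, the
choices made where the design was genuinely open, and what the synthetic
cohorts do and do not establish about real data.

## Normalization model

nCounter lanes differ by hybridization efficiency and scanner yield, which
scale every probe in a lane multiplicatively, and by a small additive
background from nonspecific binding, measured by probe-free negative
controls.  The pipeline therefore applies, in a fixed order:

1. **Technical scaling.**  For lane *l*, `g_l` is the geometric mean of the
   positive-control counts and `f_l = mean(g)/g_l`, anchored to the cohort's
   arithmetic mean of the per-lane geometric means so that identical lanes
   get `f_l = 1`.  By default all six ladder probes (128 → 0.125 fM) enter
   `g_l`; a config switch (`basis="exclude_lowest"`) drops the 0.125 fM
   probe, whose counts sit nearest background.
2. **Background subtraction.**  On the scaled lane, `τ_l = μ_l + 2σ_l` from
   the negative controls (SD with the n−1 denominator) is subtracted from
   every endogenous and housekeeping probe, floored at zero.  Genes are
   never dropped here — flooring keeps the matrix dense and leaves the
   expressed/not-expressed decision to the noise filter.  Control probes
   pass through scaled but unsubtracted so audit output can recompute the
   thresholds on any later scale.  The alternative order (subtract on the
   raw scale, then scale) is exposed as a config switch; the default
   computes the threshold on the scaled lane so that `τ` and the counts it
   is subtracted from share units.
3. **Biological scaling.**  `r_l = mean(h)/h_l` with `h_l` the geometric
   mean of the lane's positive-count housekeeping probes, again
   mean-anchored.  A lane whose housekeeping counts are all zero is a
   hard error naming the lane.

The composition is equivariant under per-lane rescaling up to one global
factor: multiplying a raw lane by *c* changes the cohort anchor, so all
normalized values shift by a single common constant while every ratio,
*t* statistic and noise call is unchanged.  The test suite asserts exactly
this form.

**Noise filter.**  Per endogenous gene, a one-sided one-sample *t*-test of
its normalized counts against `μ0`, the mean over lanes of `τ_l` recomputed
from the negative-control rows of the normalized matrix (a per-lane variant
is available via `per_lane=True`, which subtracts each lane's own threshold
and tests against zero).  `above_noise ⇔ p ≤ 0.05`, df = n−1.  Zero-variance
genes get p = 0 if their mean exceeds `μ0` and p = 1 otherwise, so
degenerate input yields a decision rather than an exception.  At the
boundary null (true mean exactly `μ0`) the flag rate is the test's size:
~95% below-noise, which the acceptance battery verifies with Gaussian
counts planted at the threshold.  A gene generated at the raw background
level sits far below `μ0` after subtraction and is flagged below-noise
essentially always; the 95% figure applies only at the detection boundary.

## Differential expression

Tests run on log2(x+1)-transformed normalized counts; the transform makes
the parametric branch plausible for overdispersed counts and fold changes
symmetric.  Per gene: Shapiro–Wilk on each group (needs n ≥ 3 and nonzero
variance, otherwise the gene goes to the rank test with Shapiro p recorded
as NaN); both groups p > 0.05 → classical pooled-variance two-sided
Student's *t*; otherwise the Wilcoxon–Mann–Whitney rank-sum test, exact by
enumeration when the pooled sample is tie-free with n ≤ 12 and otherwise
the normal approximation with tie and continuity corrections.  A parametric
request on pooled-zero-variance data is rerouted to the rank test.  Only
above-noise endogenous genes are tested, controls excluded, and
Benjamini–Hochberg runs over exactly the tested set; significance is
q ≤ 0.05.  Fold change is `log2((mean_URB+1)/(mean_DRB+1))` on the
normalized scale, positive = higher in URB.

QC flags genes off the mean–variance trend: a quadratic least-squares fit
of log2 variance on log2 mean (counts with var = μ + φμ² are curved in
log–log, so a line would flag trend curvature at the extremes), residuals
beyond 3 robust SDs (MAD × 1.4826) flagged; lane totals are screened by the
same rule.  PCA centers genes and decomposes by SVD; clustering is
agglomerative (complete linkage, Euclidean on log2 counts) with a
supervised mode that clusters within subtype and concatenates leaf orders.

## Clinical covariate battery

Dichotomous covariates × subtype: Pearson χ² *without* continuity
correction — the uncorrected statistic is the convention this package fixes
because it exactly reproduces the reference laterality p-value (0.5051)
where the Yates-corrected one does not.  Germline status: two-sided Fisher
exact with the point-probability rule (sum of all tables at fixed margins
whose probability is ≤ the observed table's, with 1e-7 relative slack on
the comparison), which reproduces 0.1827; odds-ratio-based two-siding does
not.  Ordinal stages are coded 0/1/2 and compared across subtypes by
tie-corrected Kruskal–Wallis (all-tied input returns H = 0, p = 1 by
convention); age in months uses the shared Mann–Whitney engine.  The
published sex p-value of 0.04 is the truncation of 0.0488, which the suite
asserts at four decimals; the published N-stage value (0.06) is not
recoverable from the printed counts by any of these tests (tie-corrected KW
gives ≈ 0.30) and is deliberately left out of the exact-reproduction set.

## Marker scoring

ROC curves take URB as the positive class, thresholds at midpoints of
adjacent distinct values plus ±∞; AUC is the Mann–Whitney pair-counting
form (ties ½), identical to the trapezoidal area and to U/(n₁n₀).  Internal
validation is a percentile bootstrap (default B = 1000) over full-cohort
resamples; a resample missing a class is redrawn and the redraw count
logged.  Cutoffs maximize Youden's J = sens + spec − 1 (the standard
ROC-derived choice; ties resolve toward the pooled median); a marker with
AUC < 0.5 is flipped and reported as down-in-URB, so its binarized
indicator is 1 on the URB side either way.  The composite score is the
per-sample sum of indicators, S ∈ {0..G}.  Panel selection takes
significant genes ranked by AUC, top K (default 5), falling back to all
tested genes when fewer than K are significant so small cohorts still
produce a panel.

The probability model P(URB | S) = 1/(1+exp(−(a+bS))) is fitted by
*(weighted) nonlinear least squares* — explicitly not maximum-likelihood
logistic regression — with unit default weights, start (0,0), relative
tolerance 1e-8, ≤ 500 evaluations, and the slope capped at |b| ≤ 50.
Perfectly separated scores drive the objective to zero before the cap is
reached; the fit is flagged `"boundary"` whenever the cap binds *or* the
residuals vanish, signalling a step function rather than an estimated
curve.

## Conditional inference trees

The minimal two-class instance with identity influence functions: for
covariate x and binary response y, the linear statistic T = Σxᵢyᵢ with
conditional moments E[T] = (Σx)(Σy)/n and
V[T] = Σ(x−x̄)² · Σ(y−ȳ)² / (n−1), standardized to z.  Below
`exact_permutation_n` (default 8) the two-sided p-value comes from full
enumeration of label placements; at or above, from the normal
approximation.  Variable selection Bonferroni-adjusts over the m candidate
covariates and requires min p_adj ≤ α (default 0.05) to split — so tree
growth is controlled at a familywise error rate and no pruning is needed.
Split points maximize |z| of the left-indicator two-sample statistic over
admissible midpoints (children ≥ `min_leaf` = 2; nodes below
`min_node_to_split` = 4 become leaves; defaults sized for ~21-sample
cohorts).  Ties in selection break by covariate order, in splitting toward
the smaller threshold; samples at a threshold route left.  Leaf prediction
is the majority class with ties resolved by the parent's majority, then the
training prevalence, then lexicographic order.  Evaluation is leave-one-out
cross-validation, fully deterministic.

Because the statistic is linear in x, trees are invariant under affine
covariate transforms (thresholds map accordingly) but not under general
monotone transforms.

## Pathway overlay

Node states are a majority vote: among a node's member genes, count
significant-up vs significant-down (URB-positive sign convention); +1, −1
or 0 on ties/no-signal.  Weighting votes by fold change was considered and
rejected as opaque.  Enrichment is the upper-tail hypergeometric
(over-representation) test of the node's membership among significant
genes — a deliberate, documented stand-in for ranking-based set-enrichment
methods, since nothing in the analysis requires a ranking statistic.  The
bundled gene-set JSON maps diagram node labels (NGF, NT3/4, CDK4/6, …) to
standard HGNC symbols and is user-overridable; it is a curated best effort,
not a ground-truth annotation.

## Synthetic cohorts

The generator emulates the study conditions: 11 URB-like + 10 DRB-like
tumors plus 2 non-tumor controls (the controls are generated but consumed
by no analysis stage, mirroring their role in the cohort design), 770
endogenous + 30 housekeeping probes, a 6-probe positive ladder and 8
negatives.  Endogenous counts are negative-binomial via a gamma–Poisson
mixture (Var = μ + φμ², φ = `nb_dispersion` = 0.1) around
lane-scaled log2 baselines drawn uniformly on [6, 12]; housekeeping genes
sit in the upper half of that range.  Lane factors are log-normal
(σ = 0.2).  A `de_fraction` (default 0.2) of expressed genes carries a
±`lfc_magnitude`/2 (default 1.5) effect split symmetrically across groups
with Bernoulli(½) sign, keeping library sizes balanced and volcanos
two-sided.  A `background_fraction` (default 0.06) of genes is generated at
the negative-control level (Poisson, mean 10 per unit lane factor) so the
noise filter has true negatives; positive controls are Poisson at
400 counts/fM — a max-sensitivity scan puts the 0.125 fM probe near 50
counts, keeping its geometric mean well-defined.  Clinical covariates are
drawn at the observed subtype-conditional frequencies of the reference
cohort; they make the clinical battery exercisable end to end and are
illustrative, not inferential.  One seeded RNG drives everything; a config
determines its dataset bitwise.

What the synthetic cohorts do **not** model: FFPE RNA degradation and
probe-level GC or length bias, cross-cartridge batch effects, correlated
gene modules (genes are independent given lane factors), and any real
association between expression and the clinical covariates.  Passing
calibration here shows the statistics behave as designed under their own
assumptions — not that those assumptions hold in patient tissue.

## Problem sizes and numerical conventions

The calibration batteries use: 20 cohorts per condition (null and powered),
200 cohorts × B = 1000 for bootstrap coverage of a known AUC
(Φ(δ/√2) with δ = 1), 500 null simulations (n = 21, m = 10) for tree-level
familywise control, and 2000 boundary-planted genes for the noise-filter
size.  These sizes keep Monte-Carlo error well inside the asserted margins
(3 binomial SDs where a rate is checked).  Within one cohort the 770
per-gene tests share lane factors and are therefore correlated; binomial
bands for rejection rates are asserted only where genes are independent
(no lane variation) or after normalization has removed the shared scale.

Geometric means error out on zero counts (positive controls) or exclude
zeros (housekeeping).  BH adjustment is the standard step-up; note it is
not idempotent in general (re-adjusting [0.5, 1.0] gives [1.0, 1.0]), so
q-values must be computed once from raw p-values.  All stochastic
operations take explicit seeds; the pipeline fans one global seed out to
stages by fixed offsets.
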
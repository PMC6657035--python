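# Methods

This note documents the statistical procedures implemented in `ewasforest`,
the assumptions behind them, the synthetic data model used to exercise
them, and the numerical and design choices that were genuinely open.

## Data model and scales

Methylation arrives as beta values β ∈ (0, 1), the proportion methylated at
a CpG. Betas are clipped into [ε, 1 − ε] with ε = 10⁻⁶ on construction
(counted and logged), which bounds M-values to |M| ≤ log₂((1 − ε)/ε) ≈ 19.93
while preserving order. Association models run on
M = log₂(β / (1 − β)), which stabilizes the strong mean–variance coupling
of proportions; the traditional linear EWAS deliberately keeps β as the
dependent variable so its coefficients read as methylation-proportion
differences. Interchange is plain TSV (samples × features, `NA` for
missing) for painless round-tripping through R; read/write is lossless to
1 × 10⁻¹² (shortest-round-trip float formatting).

Missing values propagate through the β→M transform and are handled
per procedure: association models are complete-case per CpG (the number of
samples used is reported per fit); the random forest mean-imputes per
feature, because trees need rectangular input and the imputation only
affects ranking, not inference.

## Outlier trimming (adjusted boxplot)

Before the stage-2 logistic fits, each CpG's M-values are trimmed with the
skew-adjusted boxplot: with quartiles Q1, Q3 (linear, "type-7"
interpolation — the most common default, fixed for reproducibility), IQR,
and the medcouple MC (a robust skewness statistic in [−1, 1]),

* MC ≥ 0: [Q1 − 1.5·e^(−4·MC)·IQR, Q3 + 1.5·e^(3·MC)·IQR]
* MC < 0: [Q1 − 1.5·e^(−3·MC)·IQR, Q3 + 1.5·e^(4·MC)·IQR]

Values outside the fences become missing (trimmed, not winsorized).
Trimming is applied per CpG across the full analysis sample, not within
case/control strata, and only ahead of the logistic stage. The medcouple is
computed by the O(n²) pairwise kernel (delegated to statsmodels; the test
suite carries an independent loop-based enumeration as an oracle), with the
standard sign kernel for observations tied with the median; a degenerate
(constant) sample returns MC = 0 with a flag, and a zero IQR collapses the
fences to [Q1, Q3].

Two properties worth knowing. First, one-pass trimming is *not* exactly
idempotent: fences re-estimated on the truncated sample shrink, so a second
pass would remove a few more values (measured: the second pass removes
fewer values than the first and well under 2% of cells on Gaussian
columns). The procedure is deliberately single-pass. Second, with ~300
samples the adjusted fences trim roughly 0.5–1.5% of a clean Gaussian
column — the price of robustness to the heavy tails the rule targets.

## Cell-type deconvolution

Bulk blood β at a panel of discriminating CpGs is modelled as a convex
combination of cell-type mean profiles, and per-sample fractions solve

min‖β − wᵀP‖²  s.t.  w ≥ 0, Σw = 1.

The sum-to-one *equality* constraint (rather than the ≤ 1 convention some
array-deconvolution code uses) is chosen because downstream models treat
the fractions as compositional covariates. The solver enumerates supports:
for each subset of cell types it solves the equality-constrained KKT system
(factorized once, applied to all samples simultaneously) and keeps the
feasible candidate with the smallest residual — exact for ≤ 8 cell types,
recovering noiseless mixtures to machine precision. Missing panel CpGs are
dropped with a warning; below 80% panel coverage (overall or per sample)
estimation refuses. Panels: `adult7` (CD8T, CD4T, NK, B, Mono, Eos, Gran)
and `cord7` (CD8T, CD4T, NK, B, Mono, Gran, nRBC). Reference construction
picks, per cell type, the CpGs with the largest one-vs-rest F-statistic,
split between hyper- and hypomethylated directions when possible.

In adjusted regression models one fraction (granulocytes, the largest) is
dropped: the seven fractions sum to one and would otherwise be collinear
with the intercept.

## Stage-1 recursive random-forest selection

Each forest grows `ntree` (default 7500) sklearn decision trees; each tree
fits a *balanced bootstrap* — n_minority draws with replacement from each
class — so the rare case class is not swamped; `mtry = max(1,
⌊0.10 · n_features⌋)` candidate features per split. OOB votes are
aggregated per sample (majority, ties to the control class) into overall
and per-class misclassification. The VIM is permutation importance: per
tree, each feature used in that tree has its OOB column permuted and the
mean decrease in OOB accuracy accumulated (features unused by a tree
contribute zero for that tree, as in the classical forest implementation);
a Gini (impurity) VIM is available as an option. Tree traversal for OOB
and permutation predictions is a vectorized numpy walk over the fitted
tree arrays, which is what makes the per-tree permutation VIM affordable
at thousands of features.

The recursion halves: iteration k keeps ⌊n_start / 2^(k−1)⌋ features (ties
in VIM broken by feature order, stable), stopping before the count would
fall below `min_features` (default 10). "Levelling off" is operationalized
deterministically: the selected iteration is the *largest* (fewest
features) whose case-class OOB misclassification is within
`level_off_tolerance` (default 0) of the minimum across iterations —
further reductions would lose information about the case class.

A property of balanced minority-size bootstraps worth stating plainly:
they mitigate, but do not equalize, class-specific error. Bootstrapping
n_min from n_min minority samples leaves ~0.63·n_min unique in-bag points,
while n_min draws from a much larger majority stay nearly all unique, so
fully grown trees on pure noise still vote majority-ward; the null
case-class OOB error sits near 0.6 here (R's reference forest
implementation shows the same direction, more strongly, at the same
settings), versus near-total case misclassification without balancing.
Tests assert this measured behaviour, not the folklore 50%.

## Stage-2 association and FDR

Per selected CpG, a maximum-likelihood logistic regression of case status
on M (crude, and adjusted for sex plus six cell fractions) gives an odds
ratio per 1-unit M with a Wald 95% CI (exp(coef ± 1.96·SE) — Wald rather
than profile likelihood, matching conventional EWAS reporting). Perfect or
quasi-complete separation is flagged (`converged = False`, estimates
withheld) rather than raised, so one degenerate CpG cannot abort a scan.
The per-unit-M OR scale is an interpretation choice recorded here: printed
ORs in this literature are consistent with unit-M scaling.

Storey q-values: π₀ is estimated on the λ-grid 0.05, 0.10, …, 0.95 via
π₀(λ) = #{p > λ}/(m(1 − λ)) smoothed by a natural cubic smoothing spline
with 3 effective degrees of freedom (numerically equivalent to R's
`smooth.spline(df = 3)`, the smoother used by the canonical q-value
implementation), read off at λ = 0.95 and clamped into (0, 1]; then
q₍ᵢ₎ = min_{j ≥ i} π₀·p₍ⱼ₎/(j/m). With π₀ = 1 this reduces *exactly*
(bitwise, same evaluation order) to Benjamini–Hochberg step-up. Below 100
features π₀ estimation is too unstable and is fixed at 1 (BH fallback,
logged). Note the single-replicate π₀ estimate has sd ≈ 0.027 at
m = 10,000 even for the reference smoother, so recovery checks average
replicates. Discovery = crude-model q < 0.05, strict inequality; adjusted
models are reported but do not gate discovery.

Replication joins discovery and replication fits per (CpG, model):
direction consistency is log-OR sign agreement (only when both fits
converged) and replication significance is p < α (strict, default 0.05).

## Cord-blood follow-up

Expression arrays are percentile-shift normalized: each sample's 75th
percentile of log2 intensities (the common array-software convention; the
anchor percentile is configurable) is subtracted, making the per-sample
anchor exactly zero — idempotent and shift-invariant. DNAm–expression
coupling is Spearman's rho with asymptotic p. Infant wheeze (wheeze
without cold; any wheeze) is modelled with three nested logistic models:
crude; + infant sex and season of birth (three dummies, winter reference,
empty levels dropped with a warning); + cord cell fractions (nRBC
retained, granulocytes dropped).

## Synthetic cohort generator

The generator is the package's test bed and defines its study conditions;
defaults mirror the motivating adolescent cohort: n = 370, prevalence
0.139, 66.2% female, case/control eosinophil means 0.045/0.021.

* **Composition.** Per-sample fractions are Dirichlet with total
  concentration 30 (reproducing observed dispersion of estimated blood
  fractions, e.g. control eosinophil sd ≈ 0.026, granulocyte sd ≈ 0.11);
  the group mean vector moves the shifted cell (Eos for adult blood, nRBC
  for cord) to its target and renormalizes the rest proportionally, and
  after drawing, the shifted-cell column is re-centred multiplicatively so
  the *empirical* group means hit their targets exactly while staying on
  the simplex.
* **Methylation.** Cell-type profiles: reference CpGs near 0.05 in one
  type and 0.95 elsewhere (half in each direction per type, ± small
  jitter); background CpGs share a Uniform(0.1, 0.9) mean across types.
  Bulk mean β is the composition-weighted mixture. On the M scale,
  non-reference CpGs get per-sample biological noise (sd `bio_m_sd`,
  default 1.0 — inter-individual variability; reference CpGs are modelled
  as tightly regulated, as reference panels select for), and planted CpGs
  an additional case shift `planted_effect` (default −1.5: cases
  hypomethylated). Measured β is Beta-distributed around the mixed mean
  with concentration `beta_precision` (default 600, measurement sd ≈ 0.02
  at β = 0.5).
* **Calibration.** With σ_M ≈ 1.0 and shift −1.5, normal theory
  (log-OR ≈ δ/σ²) puts crude per-unit-M ORs near 0.22, inside the 0.1–0.4
  band typical of reported discovery tables; the measured median at the
  default scale is ≈ 0.21.
* **Expression and wheeze.** Probe 0 couples to the first planted CpG's
  measured M through a Gaussian copula on normal scores with the Pearson
  coefficient r = 2·sin(π·ρ_s/6) for the target Spearman ρ_s (default
  −0.22); other probes are N(8, 1) noise. Infant wheeze outcomes are
  Bernoulli with logit linear in the coupled probe (log-OR 1.1 per unit
  log2 expression for wheeze-without-cold).
* **Seeding.** Two generators: a structure stream (profiles, planted CpG
  identities) and a sample stream. Identical seeds give byte-identical
  cohorts; sharing `structure_seed` across different `rng_seed`s yields
  independent cohorts with common planted truth — the replication setting.
* **Null cohorts** set `planted_effect = 0` *and* equal shifted-cell means
  across groups: with a case-shifted eosinophil mean, reference CpGs are
  genuinely case-associated through composition, so a composition-shifted
  "null" would not be null.

What the generator does not emulate: probe-type chemistry, batch/chip
effects, genotype-driven methylation QTLs, correlated CpG neighbourhoods,
or realistic genomic annotation. Passing recovery tests therefore show
that the pipeline's logic is sound at realistic effect and noise scales,
not that real 450k data would behave this way.

## Problem sizes and determinism

The shipped end-to-end checks run a scaled-down version of the discovery
design — 370 samples, 5000 CpGs, 10 planted, 500 trees per forest (the
halving schedule then runs 5000 → 19 over nine iterations) — a size chosen
so the full suite iterates comfortably on a laptop-class single CPU while
preserving every structural feature of the full-scale analysis (the 91/279
split, class imbalance, FDR control at the selected-set size). Null-cohort
batches reuse the same size. All pipeline outputs are written
deterministically (seeded generators end to end, shortest-round-trip float
text), and reruns with the same seed are byte-identical; the run manifest
records the config hash (excluding the output directory), seed and package
version.

One honest caveat: under the global null, any FDR-controlling rule
discovers something in ≈ 5% of runs by construction (Simes equality), so
"zero discoveries" is a per-run event with probability ≈ 0.95, not a
certainty; batch checks should be read accordingly.

## Known limitations

* The forest consumes features as independent columns; correlated CpG
  blocks share importance and can shoulder each other out of the halving.
* Wald CIs misbehave near separation; affected fits are flagged rather
  than repaired (no Firth correction).
* The deconvolution assumes the reference profiles are measured without
  error and on the same scale as the bulk data; no probe-level weighting.
* π₀ estimation below a few hundred p-values is noisy; the BH fallback
  below 100 features is conservative.
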
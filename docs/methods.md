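# Methods

## Scope and data model

The package analyses two kinds of trial data on the log2 scale throughout:
long-format serum analyte concentrations (pg/ml; Olink NPX values are
already log2 and are never re-logged) for two treatment arms plus a
separately procured healthy-control panel, and gene-level RNA-seq count
matrices from paired lesional (L) and nonlesional (NL) skin biopsies, with
NL sampled at baseline only and L at baseline and follow-up weeks. All
subject identifiers are strings, weeks are integers, and every stage
communicates through serialized tables rather than shared state.

## Serum statistics

Group cells (arm × week × analyte) are summarized as the mean and variance
of log2 concentrations and compared with healthy controls by Welch's
two-sample t-test from summary statistics, with Satterthwaite degrees of
freedom. The reported `log2ratio_vs_hc` is exactly the difference of the
two means; zero-variance cells use the conventions p = 1 for equal means
and p → 0 (flagged `degenerate`) otherwise, since the asymptotics are
meaningless there.

The longitudinal PD model takes, per analyte, each subject's log2 ratio to
their own baseline at every post-baseline week. Fixed effects are the full
set of week × arm cell means plus the centred baseline log2 value as a
covariate; a subject-level random intercept carries the repeated-measures
correlation (the baseline measurement error is shared by all of a
subject's ratios, so the component is nonzero even though subject-level
abundance cancels in the ratio). Fitting is REML via statsmodels MixedLM
with its default optimizer chain. When the random-intercept variance
estimate is numerically zero, when any subject contributes only one
post-baseline observation (variance unidentifiable; the model is then
exactly a per-week ANCOVA), or when the fit fails outright, the engine
falls back to ordinary least squares and logs a warning.

Wald tests use a between-within degrees-of-freedom approximation:
between-subject contrasts (arm differences, responder effects) on
`n_subjects − p_between` df, within-subject cell means on
`n_obs − n_subjects − p_within` df; in the OLS fall-back both collapse to
the residual df. The approximation is documented rather than exact —
nothing downstream depends on df beyond p-values, and the null-calibration
tests bound the practical consequence.

Benjamini–Hochberg adjustment is applied per analysis family: across
analytes within each (arm, week) for within-arm effects, across analytes
per week for between-arm contrasts, and across analytes for responder
effects. A protein shows a PD effect in an arm when its estimated log2
ratio is negative with magnitude > log2(1.25) at FDR < 0.05 (strict
inequalities); the two arms' flag lists are also reported as
both / A-only / B-only sets.

Responders are defined from the PASI table as absolute PASI < 3 at every
visit inside the window (default weeks 20–48); the responder contrast
refits the longitudinal model with responder status as an additional
between-subject factor. Analyte–severity association uses Pearson
correlation of log2 level with PASI over pooled (subject, week) visits.

## Disease transcriptome

Counts are transformed to `log2((c + 0.5) / (libsize + 1) · 1e6)`; genes
with CPM ≥ 1 in at least 25% of samples are retained (a documented default
— no filter is prescribed by the design). The baseline L-vs-NL comparison
uses the paired log2 differences per gene, so the effect estimate is the
log2 geometric-mean fold change by construction.

The moderated paired t shrinks per-gene variances toward a mean–variance
trend: with `s_g²` the sample variance on `d = n − 1` df and `A_g` the
gene's average log2 expression, a lowess curve (span 0.4) is fitted to the
bias-corrected log variances `log s_g² − ψ(d/2) + log(d/2)`; the residual
spread in excess of the χ² sampling noise `ψ′(d/2)` determines the prior
df `d₀` by inverting the trigamma function, and the posterior variance is
the convex combination `(d₀ s₀²(A_g) + d s_g²)/(d₀ + d)`. The statistic
`t = d̄_g / √(s̃_g²/n)` is referred to a t distribution on `d + d₀` df.
Setting `prior_df=0` disables shrinkage and reproduces the classical
paired t exactly; `prior_df=inf` uses the trend variance alone. Genes with
zero sample variance are excluded from the trend fit and inherit the
nearest-by-abundance trend value. Observation-level precision weights (as
in count-specific variance-modelling pipelines) are deliberately omitted;
the tests treat this as a statistical approximation and verify its
behaviour by calibration rather than by matching another implementation.

The disease transcriptome is `{g : |d̄_g| > log2(fc) and FDR_g < α}` with
defaults fc = 2, α = 0.05, ordered by (FDR, p, gene id) for determinism;
up/down direction is the sign of `d̄_g`.

The transcript-level PD model reuses the longitudinal engine with the
lesional log2 ratio to the subject's baseline lesional value as response
and the subject's baseline L−NL difference as the covariate. The covariate
coding is a design choice (the subject-level baseline differential is the
natural per-subject severity measure); a gene-level alternative was not
pursued.

## Percent improvement and normalization

For each disease transcript, arm and week,
`improvement = 100 · (L̄₀ − L̄_t) / (L̄₀ − N̄L₀)` on group-mean log2
expression, where N̄L₀ is the arm's own baseline nonlesional mean
(a pooled-arms reference is available via `pooled_nl=True`). The formula
is affine-invariant per gene and handles up- and downregulated transcripts
identically because numerator and denominator change sign together; the
transcriptome's fold-change gate guarantees a nonzero denominator. Values
are not clipped: < 0 means worsening, > 100 overshoot. Group means (not
per-patient ratios) are the primary definition because follow-up biopsy
subjects are a subset of baseline subjects; a `per_patient=True` variant
exists for sensitivity analysis. A transcript is "normalized" when
improvement exceeds the threshold (default 75, strict); a transcript is
"better normalized" by one arm when its improvement there exceeds 50 and
the margin over the other arm exceeds 25 (both strict), which makes the
two differential sets disjoint by construction.

The heatmap export orders genes up-block first, each block by average-
linkage hierarchical clustering on correlation distance of baseline
lesional profiles (zero-variance genes get zero distance to everything,
so identical profiles stay adjacent), and columns by tissue, arm, week.

## Gene-set variation scores

Per gene, expression is converted to a relative statistic by a Gaussian-
kernel CDF across samples with bandwidth `sd/4` (constant genes fall back
to 0.5); per sample, genes are ranked by decreasing statistic with ties
broken by input order, weighted by the symmetric rank statistic
`|p/2 − rank|^τ` (τ = 1); a weighted KS-like random walk steps up by the
normalized weight inside the set and down by `1/(p − m)` outside. The
`max_diff` score — maximum positive plus minimum negative deviation — lies
in [−1, 1] and is the default; `max_abs` is available. Sets are
intersected with the expression universe and dropped below 2 members.
Group comparisons use Kruskal–Wallis with tie correction and the
conventional star annotation; all-identical scores return p = 1.

## Over-representation

One-sided hypergeometric tail `P(X ≥ k)` for the overlap of the query with
each term, BH across terms, sorted by (adjusted p, term name). The
universe is the post-filter expressed gene set, not the genome — a
documented, configurable choice. Query genes outside the universe are
dropped with a warning; depletion is not tested.

## Synthetic cohorts

The generator plants exactly the structure the estimators assume, at the
study's scale:

* **Serum** (`analyte_params`): healthy controls are
  `N(μ_HC, σ_HC²)` on log2; patients sit `disease_offset` above μ_HC at
  baseline, share a subject intercept (`serum_subject_sd`, 0.6 log2), and
  at week w in arm a the mean offset is scaled by `1 − decline_frac[a][w]`
  with residual sd 0.5 log2. The default five-analyte panel (IL-23,
  IL-17A, IL-17F, IL-22, BD-2) uses the published healthy-control log2
  means, disease offsets of 0.78–5.0 log2, and decline kinetics digitized
  from the published per-week log2 ratios: the IL-17A-blocker-like arm A
  clears IL-23/BD-2 fast but barely moves IL-17F/IL-22, the
  IL-23-blocker-like arm B drives IL-17F to near-healthy levels by week
  24. Visit grids default to {0, 4, 24, 48} for serum and {0, 4, 24} for
  skin. PASI is `intercept + Σ coeff · log2(conc) + N(0, 4²)`, clipped at
  zero, coupled to BD-2 by default. Assay censoring at the lower limit of
  quantification is not modelled; concentrations are strictly positive by
  construction.
* **Skin**: gene base abundances are `N(4, 2²)` on log2, converted to
  per-sample proportions; disease genes (default 300 of 10,000) carry a
  lesional offset `sign · max(N(2.5, 0.7), 0.1)` log2, scaled per subject
  by a severity factor `N(1, 0.15²)` and reduced at week w by the arm's
  improvement fraction (`norm_frac`, defaults A: 0.80/0.85 and B:
  0.45/0.85 at weeks 4/24). Counts are negative binomial with dispersion
  0.1 and log-normal library sizes (mean 1e6, CV 0.2). Because
  proportions renormalize, planted up-genes impose a small shared
  compositional shift on all other genes — a real RNA-seq phenomenon the
  tests account for. Library sizes are kept at 1e6 (not sequencing-scale)
  so that whole cohorts can be regenerated cheaply; dispersion and
  variance components are stated defaults, not estimates of any trial.
* Per-gene improvement fractions equal the arm-level value exactly (no
  gene-level spread), so the fraction of transcripts crossing a 75%
  threshold is steep in the planted value: an arm planted at 0.45 scores
  near 0% normalized, one at 0.80 scores most transcripts. Real cohorts
  spread improvement across transcripts and land between these extremes,
  which is why the recovery tests assert the between-arm ordering and
  convergence rather than specific percentages.
* Everything derives from `numpy.random.default_rng` seeded from
  `(stream, seed)` pairs, so serum, skin, and gene-set draws are
  independently reproducible and the whole bundle is byte-identical under
  a fixed config.

What the generator does **not** emulate: batch effects, library-prep
artifacts, assay plate effects, NPX normalization internals, missing
visits, dropout, correlated gene modules beyond the planted set, and
free-vs-bound analyte interference (the IL-17A masking is an analysis
option, not a generative one). Passing recovery tests therefore shows the
estimators are correct for the assumed data-generating process, not that
the pipeline is robust to real-data artifacts outside it.

## Problem sizes and numerical choices

The test-suite and acceptance-script cohorts use 10,000 genes × 35 pairs
for transcriptome recovery, 2,000 genes × 17 subjects/arm × 100 replicates
for normalization-fraction recovery, and 200 (tests) / 50 (script)
replicate serum cohorts for null calibration — sizes chosen to estimate
each property to well inside its assertion margin on a single CPU.
Tie-breaks are deterministic everywhere (gene id in FDR ordering, input
order in GSVA ranking); BH is order-invariant; lowess span 0.4; the
trigamma inversion uses Newton iterations to 1e-10 relative tolerance.

## Known limitations

* The moderated paired t omits observation-level precision weights, so it
  is an approximation to count-aware variance-modelling pipelines at very
  low expression; the expression filter limits the consequence.
* The between-within df approximation is crude for unbalanced designs.
* The published between-arm analyte contrast table cannot be matched
  cell-by-cell: some published rows are not the simple difference of the
  per-arm columns (covariate adjustment details are unstated), and two
  published serum table cells are internally inconsistent with their own
  mean columns; the bundled reference data documents this and the tests
  assert the reproducible identity instead.
* Gene-level analysis only; transcript-isoform resolution and everything
  upstream of the count matrix (alignment, quantification) are out of
  scope, as are curated signature contents (users supply GMT files).
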
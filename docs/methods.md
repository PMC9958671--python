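# Methods

## Study design and data model

The pipeline targets a paired-biofluid exercise-challenge design: two cohorts
(`control`, `mecfs`), urine at baseline (U1) and 24 h post-exercise (U3),
plasma at four draws (P1 baseline, P2 shortly post-exercise, P3 at 24 h, P4
shortly after a second challenge). Abundances are vendor peak areas —
non-negative, right-skewed, with left-censored missingness. Missing is a
first-class state distinct from 0 throughout: drug and tobacco compounds are
imputed as 0, and a 0 must survive every later stage, which constrains the
choice of transform (see below).

## Preprocessing

Stage order is fixed: osmolality normalization → imputation → median
centering → variance-stabilizing transform → detection filtering. The
detection mask is frozen before imputation, so the 80% rule always reflects
what the assay detected regardless of where filtering is applied; the
question of whether filtering happens before or after transformation is
thereby moot.

* Osmolality normalization divides each urine sample by its osmolality
  (mOsm/kg; any consistent unit works since it enters as a per-sample
  scale). Plasma is not osmolality-normalized.
* Imputation: per-metabolite minimum over all samples (not per cohort — the
  minimum is the natural proxy for a value below the detection limit);
  drug/tobacco compounds get 0 since absence, not censoring, is the usual
  cause. An all-missing non-drug metabolite has no minimum and is dropped.
* Median centering scales each metabolite to median 1. A median of 0 can
  occur for drug compounds; the fallback scales by the smallest positive
  value, and a metabolite with no positive value at all is dropped. Both are
  logged.
* The variance-stabilizing transform is the generalized log,
  glog10(x) = log10((x + √(x² + λ²))/2) with λ = (smallest positive value in
  the matrix)/10. It is strictly increasing, ≈ log10(x) for x ≫ λ, and
  finite at 0 (needed for the drug-compound zeros). A strict log10 is
  available via `RunConfig.transform = "log10"`; the prep chain is exactly
  invertible under it, which the exactness tests exploit, while glog agrees
  with log10 to ~1e-5 at centered scale.
* The modified 80% rule is non-strict (≥ 0.8) and pools both timepoints
  within a cohort: a metabolite is kept if detected in ≥ 80% of all control
  samples or ≥ 80% of all patient samples.
* Recovery ratios are per-subject log10 differences (post − baseline), for
  urine U3−U1 and plasma P4−P1, P3−P2, P3−P1; subjects missing either
  timepoint are omitted. Log2 fold changes use the change of base,
  log2fc = log10fc / log10(2).

## Per-metabolite mixed model

Each metabolite's transformed values follow

    value ~ cohort * timepoint + age + BMI + (1 | subject)

REML estimation profiles the single variance ratio θ = σ²_u/σ²_e. For fixed
θ, V₀ = I + θZZ′ yields closed-form GLS estimates and the profiled REML
criterion −½[log|V₀| + log|X′V₀⁻¹X| + (n−p) log σ̂²_e]. Because every
metabolite shares one design, ZZ′ is diagonalized once and each criterion
evaluation is a weighted least squares with diagonal weights. The optimum is
located on a 50-point log grid over θ ∈ [0, 10⁶] plus θ = 0 and refined by
golden section; boundary solutions (θ = 0 or θ_max) are flagged
`converged=False` but retained — at these sample sizes σ²_u = 0 fits are
expected and valid.

Covariates are centered at sample means so cell means are interpretable; all
five contrasts put zero weight on age and BMI and are invariant to the
centering. Contrast inference uses t statistics with Satterthwaite degrees
of freedom: df = 2f²/(g′Wg) where f = Var(c′β̂) as a function of
(σ²_u, σ²_e), g its numeric gradient (central differences, relative step
1e-5), and W the inverse of the numeric observed REML information. At the
σ²_u = 0 boundary the one-parameter case reduces analytically to the OLS
residual df (n − p), which is used directly; df is clamped to [1, n−p]. A
conservative residual fallback (`df_method="residual"`, df = n_subjects − p)
is exposed because the exact df convention of downstream consumers varies
and counts at q-thresholds can shift by a few metabolites between df
methods.

BH adjustment is applied separately within each contrast family across the
filtered-in metabolites. Fold changes serve two purposes and are computed on
two scales: enrichment input uses the fold change of mean normalized
(median-centered, pre-transform) concentrations per cell; volcano tables use
differences of cohort means of transformed values, and for the interaction
the ratio of mean per-subject recovery ratios (case minus control on log10
scale, converted to log2).

## Set enrichment

Sets are non-overlapping (Metabolon-style subpathways of known compounds, or
a precomputed chemical-similarity cluster column; overlap is a hard error).
Enrichment is the one-sample KS test of member p-values against
Uniform(0,1), one-sided toward "stochastically smaller" — the direction an
enriched set pulls its members — with the two-sided variant behind config
(`ks_alternative`). Sets with fewer than two measured members are skipped
and logged. The altered ratio is the fraction of members with p < 0.05; the
increased ratio is the fraction of altered members with positive fold
change, undefined (NaN) when nothing is altered. Reporting order is
superpathways alphabetical, sets in annotation (chemical-similarity) order
within superpathway.

## Pathway topology

Measured metabolites are matched to pathway-graph nodes by HMDB id; when
several metabolites share one id, only the first in annotation order is kept
(duplicates logged). Node importance is Brandes betweenness centrality
(unweighted shortest paths, fractional credit for ties, endpoints excluded)
rescaled so each pathway's maximum is 1; degenerate graphs (complete,
two-node, isolated) get all-zero importance. Pathway impact is the sum of
matched importances. The quantitative enrichment statistic is the global
test score Q = (y−ȳ)′XX′(y−ȳ)/m on the column-standardized matched matrix —
timepoint mode uses per-sample transformed values with sample cohorts as
labels, ratio mode per-subject recovery ratios with subject cohorts.
Inference is by label permutation with add-one smoothing (default 9999
permutations) rather than the asymptotic chi-square mixture: exact at these
sample sizes and directly verifiable against full enumeration. The package
ships no reference pathway databases (versioned, licensed); graphs are
user-supplied edge lists, and `simgen.simulate_pathway_graphs` builds
synthetic ones for testing.

## Urine–plasma correlations

All shared metabolites participate — the detection filter is deliberately
not applied here. Seven pairings: same-day timepoints (U1~P1, U1~P2, U3~P3,
U3~P4) and recovery ratios (U3/U1 against P4/P1, P3/P2, P3/P1). Pearson R is
computed within cohort across subjects on transformed values; p from
t = R√((n−2)/(1−R²)) on n−2 df, with |R| = 1 mapped to p = 0 and n < 3 or
zero-variance vectors skipped. BH families are per cohort × pairing
(matching the per-panel census presentation; a single global family is a
config switch). Outlier handling is compound-level: the modified z-score
0.6745(x−median)/MAD with threshold 6 is evaluated per metabolite on each
variable vector (cohorts pooled; urine and plasma separately); an outlier in
any timepoint variable removes the compound from all timepoint pairings
only, an outlier in any ratio variable from all ratio pairings only. A zero
MAD makes no outlier callable and is flagged. The differential screen
requires (1) |R| > 0.7, p < 0.05, q < 0.15 in one cohort and (2) |R| < 0.3
or an opposite-signed R in the other. Whether criterion (2)'s weakness bound
should be |R| < 0.3 or R < 0.3 is ambiguous for negative significant
correlations; |R| < 0.3 is the default reading, switchable via
`screen_weak_abs`.

## Clustering

Subject clustering uses Euclidean distances with Ward.D2 linkage (Lance–
Williams update on squared distances, heights on the distance scale), via
scipy's `linkage(..., "ward")`; merge heights are monotone and the result is
deterministic given input order. The post-exercise heatmap matrix takes the
metabolites significant in the case-vs-control post contrast at q < 0.1 with
median-centered concentrations as values.

## Synthetic-data generator

The generator is the package's validation instrument; its defaults encode
the study conditions the analysis assumes. Log10-scale latent for urine
(subject j, metabolite m, timepoint t):

    x = μ_m + u_j + s_jm + a_m·age_j + b_m·bmi_j + δ_m·case_j
        + (γ_m + η_m·case_j)·post_t + r_jm·post_t + ε

Raw urine = osmolality_s·10^x (osmolality multiplies the raw, not log,
scale, so normalization exactly inverts the distortion); values with
10^x < L_m are censored to missing (left-censoring, matching the implicit
assumption of minimum-imputation). Plasma shares u_j directly and couples to
the urine-specific deviates s_jm (stable) and r_jm (exercise response) with
per-metabolite correlation ρ_m; the post indicator for plasma covers P3/P4.
The two deviates are what make the timepoint-level and ratio-level
urine–plasma Pearson correlations tunable: a subject intercept alone is
shared across metabolites and cancels in ratios, so without them ρ would
have nothing to act on. Per-metabolite, u_j + s_jm together form the subject
random intercept the mixed model assumes, so s_jm does not perturb
calibration; r_jm adds post-timepoint variance (mild heteroscedasticity)
and is zeroed in calibration scenarios.

Defaults and why: 8 + 10 female subjects; 1403 metabolites in 84 subpathways
with a lognormal size profile (a few large, many small sets) and realistic
Metabolon-style names; ~63% known / ~5% partially characterized / rest
unknown; σ_u = 0.1, σ_s = 0.35, σ_e = 0.15, σ_r = 0.15 (log10 scale —
between-subject variation dominating residual noise, as in real urine
panels); γ = 0.3 (a 2× post-exercise increase) with η = −γ so patients show
no change, on 8 responder subpathways (~10% of the panel) drawn from the
amino-acid and lipid classes that respond to exertion; age ~ N(52, 5) both
cohorts, BMI ~ N(33, 4) controls vs. N(24, 4) patients (a deliberate
confound the covariate adjustment must absorb); osmolality lognormal around
600 mOsm/kg; detection: 18% of metabolites drawn with low detection targets
(0.2–0.75) and the rest near-complete, giving ~82% retention under the 80%
rule; ρ_m ~ U(0.4, 0.95), under which roughly 40% of shared metabolites
show |R| > 0.7 at timepoint pairings with n = 8/10. `SimScenario.noise_free()`
zeroes every random SD and disables censoring for exact-algebra checks;
`scenario.null()` zeroes δ, γ, η and r for calibration runs.

What the generator does not emulate — and what passing tests therefore do
not show about real data: batch and injection-order drift (the design
assumes a single batch), metabolite–metabolite correlation beyond the shared
subject deviates, heavy-tailed or non-lognormal abundance errors,
missingness not explained by a detection limit, diet-driven xenobiotic
structure, and real pathway-database topology (synthetic graphs are random
trees with shortcuts over the synthetic HMDB namespace).

## Numerical choices and degenerate inputs

θ search bounded at 10⁶ with flagged boundaries; Satterthwaite falls back to
residual df when the observed information is singular or the denominator is
non-positive; BH validates p ∈ [0, 1]; KS requires ≥ 2 members; the global
test requires ≥ 2 matched metabolites and both labels; correlations require
n ≥ 3 and nonzero variance; clustering rejects missing cells and k > n; ties
in agglomeration are resolved by scipy's deterministic chain order (random
real-valued inputs make exact ties measure-zero). Readers parse floats in
round-trip mode so write/read cycles are bit-exact. All stage logs carry
counts in/out and thresholds used, making filtering provenance auditable.

## Problem sizes in the validation suite

The suite validates on a 4+4-subject, 60-metabolite fixture for fast
end-to-end checks; 1000-metabolite all-null replicates at the full 8+10
design for calibration; the full 1403-metabolite panel for recovery and for
the acceptance script; 20 random small datasets for REML oracle equivalence;
and ≤ 10-sample toys where the permutation global test can be compared with
exhaustive enumeration. These sizes were chosen so each property is measured
at the scale where its guarantee is meaningful while the whole suite stays
interactive.

## Known limitations

Satterthwaite df uses numeric differentiation (adequate at these sizes;
Kenward–Roger is out of scope). The KS enrichment treats member p-values as
exchangeable and ignores within-set correlation, as the underlying method
does. The permutation global test's resolution is 1/(n_perm+1). Counts at
q-thresholds near the boundary can shift by a few metabolites between df
conventions; both conventions are exposed. The pipeline does not model
repeated-measures structure beyond a subject intercept (no random slopes)
and performs no cross-metabolite shrinkage.
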
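# Methods

This note documents the models behind `muenv`, the defaults and why they were
chosen, what the synthetic generators do and do not emulate, and the
numerical choices that matter for reproducing results.

## Preprocessing

Cell-line (bead-array-style) matrices carry per-cell detection p-values; the
pipeline keeps probes with detection p < 0.01 in at least one sample, then
quantile-normalizes. Quantile normalization is used as the normalization
step: it is deterministic, rank-preserving, and sufficient for a pipeline
whose downstream statistics (moderated t, Spearman scoring) use only
relative values; spline-based array normalizations are platform-specific and
add nothing here. Detection filtering runs **before** normalization.
Clinical cohort matrices have no detection layer and skip the filter.
Probe-to-gene collapse keeps, per gene, the probe with the highest detection
rate, ties broken by the larger interquartile range, residual ties by
lexicographically smallest probe id (reproducible; otherwise arbitrary).
All matrices are log2 by contract — no automatic log detection.

## Differential expression

Per subtype, the CAF-CM vs NAF-CM contrast is fit per gene by least squares
with cell line as a fixed blocking factor (`expression ~ condition +
cell_line`); serum-free controls are excluded from the signature contrast.
Blocking is the conservative choice for a within-subtype comparison of
treated lines; an unblocked (pooled) variant is available via
`blocked=False`.

Variance moderation follows the standard empirical-Bayes hierarchy: the
prior `s² ~ s₀²·d₀/χ²_{d₀}` gives the posterior variance
`s̃² = (d₀s₀² + d_g s²)/(d₀+d_g)` and `t = log2FC/(s̃·c)` on `d₀+d_g` df,
with `c` the contrast's standard-error multiplier from the design.
`(d₀, s₀²)` are estimated by matching the mean and variance of `log s²` to
their digamma/trigamma expressions; the trigamma equation is inverted by
Newton iteration. `d₀` is clipped to [0.1, 1e6] and values above 1e5 are
treated as effectively infinite. If the observed log-variances are *less*
dispersed than chi-square sampling alone allows, the prior is a point mass:
`d₀ = ∞` with `s₀²` the arithmetic mean of the gene variances — so when all
gene variances are equal, moderation is a strict no-op and the moderated t
equals the ordinary t. Zero-variance genes are floored at `s² = 1e-12` with
a logged warning.

DE calling is the dual threshold: two-tailed p < 1e-4 **and** natural-scale
fold change strictly outside [0.67, 1.5]. No multiplicity correction is
applied to DE calling (the raw-p threshold is the method); at 22,000 genes
the chance expectation at p = 1e-4 is 2.2 genes, which the null-calibration
test verifies.

## Enrichment

Preranked GSEA on the t-ranked list (ties in the statistic broken by gene
id). Hits increment the running sum by `|stat|^w / N_R`, misses decrement by
`1/(N − N_hits)`; ES is the extremum of the running sum. Default weight 1
and 1,000 permutations (the method's conventional defaults; neither is
dictated by the analysis itself, both are configurable). The null is
**gene-set permutation** — random same-size sets from the ranked universe —
which is the matching null for a preranked analysis; phenotype permutation
is out of scope. NES divides ES by the mean |null ES| of matching sign;
p-values are one-sided within sign with the +1 correction; FDR uses the
standard positive/negative pooled-NES scheme. Sets with no overlap are
skipped with a warning; sets covering the entire list are rejected (the
miss decrement is undefined).

## Signatures, gating, scoring

The cell-line collection is mean-centered across **all** of its arrays (all
subtypes and conditions); each clinical collection is mean-centered across
all of its samples. The signature centroid is the centered mean of the DE
genes over the subtype's CAF-treated samples. Scoring is the Spearman
correlation (average-tie ranks) between the centroid and a sample's
centered expression on the overlapping signature genes; ρ > 0 strictly is
μENV-positive, ρ = 0 or undefined is negative. A sample with constant
expression on the signature genes is reported negative with a warning
rather than dropped, keeping cohort partitions complete. The overlap floor
(`min_overlap`, default 10 genes) guards against cross-platform gene loss;
below ~10 genes a rank correlation is too unstable to dichotomize. The
basal signature itself holds only ~10 genes, so callers scoring their own
signature may cap the floor at the signature size.

Subtype gating thresholds come from a two-component Gaussian mixture (EM,
k = 2, 10 seeded restarts) on each reporter row (ESR1, ERBB2); the
threshold is the posterior-0.5 crossing between the component means. A fit
is rejected as degenerate when a component weight falls below 0.02, when a
single Gaussian explains the data at least as well by BIC, or when the
means are separated by less than one pooled SD — EM will happily split a
unimodal sample into two overlapping components, and the BIC comparison is
what reliably flags that case. Gating: ERBB2 above its cut ⇒ HER2+
regardless of ESR1; else ESR1 above its cut ⇒ ER+/HER2−; else ER−/HER2−.

## Survival

Kaplan–Meier with Greenwood variance; two-group log-rank with the
hypergeometric variance. Cox models use Efron tie handling and Wald
CIs/p-values (the conventions of the standard survival software this
mirrors); fitting is delegated to lifelines behind the module surface.
Covariate dichotomizations are strict: age > 50, size > 2 cm, GGI > 0.
"10-year" quantities apply administrative censoring at 120 months before
fitting. The GGI-by-time interaction is fitted by splitting each subject's
follow-up at the distinct event times and evaluating `x·g(t)` per risk
interval with `g(t) = log(t months)` — the same transform used by the
Schoenfeld diagnostic, so the diagnostic and the remediation are consistent.

Complete separation (monotone partial likelihood) is detected as any
|coefficient| > 10 and raised as an error in plain fits; in episode-split
fits the `(x, x·g(t))` pair is exempt, because with few events the pair is
only weakly identified jointly (log t varies little over the observed event
times) and can drift large while every other coefficient — including the
μENV effect under study — remains stable; a warning notes the weakly
identified pair. Firth-type penalization is out of scope.

## Synthetic data: what it emulates, what it does not

**Cell-line generator.** Nine lines (three per subtype) × three conditions
(CAF-CM, NAF-CM, serum-free control) × three replicates; 22,000 genes by
default so the p = 1e-4 chance expectation is 2.2 genes (configurable down
to ~1,000–2,000 for fast tests — tests and the acceptance script use 2,000
so the whole study runs in seconds). Gene variances are drawn from the
scaled-inverse-chi-square prior (defaults d₀ = 4, s₀² = 0.0625) so the
moderated-t model is exactly well specified and its type-I behaviour can be
tested. Planted DE genes (69/114/10 per subtype, disjoint, 80% upregulated)
shift CAF-treated samples of their subtype only, with |log2FC| drawn
uniformly on [1.0, 2.0] (mean 1.5): real treatment effects are
heterogeneous, and the magnitude spread is what gives the signature
centroid a meaningful within-set rank ordering. Per-(gene, line) offsets
(SD 0.25) create the blocking structure. Detection p-values mark ~95% of
genes (always including planted DE genes) as expressed.

**Cohort generator.** Subtype truth is drawn from configurable fractions
(defaults 0.55/0.20/0.25), the latent activation state per subtype from the
reported positive fractions (0.43/0.64/0.79). ESR1/ERBB2 reporter rows come
from two-component normal mixtures (means 6 and 11, SD 0.8 — > 4 SD
separation) conditioned on subtype; HER2+ tumors are ER+ with probability
0.5. Activated tumors **recapitulate their subtype's CAF-treated reference
profile**: each signature gene is shifted in proportion to its own centroid
value, normalized so the mean absolute shift equals `effect_size` (default
1.5 log2 units, the planted cell-line mean effect); per-gene noise SD is
0.5. This profile-shaped imprint is the faithful model of "stroma-activated
tumor" — a constant per-gene shift would carry no rank information within
the up-regulated set and makes small signatures artificially weak.

Survival times use an exponential baseline (closed-form sampling;
proportional hazards hold exactly except for the deliberate GGI-by-time
term) scaled by `exp(Σβx + β_gt·x_ggi·log max(t, 1))`. Default coefficients
plant the multivariable model: HR 2.098 (μENV), 1.334 (age > 50), 2.093
(size > 2 cm), 6.214 (GGI > 0) and 0.112 for GGI-by-time. The log-time
transform is floored at one month: with β_gt ≈ −2.19 a pure `log t` hazard
diverges as t → 0 (every GGI-positive subject would fail instantly); above
the floor the fitted pure-log-t model is effectively correctly specified
because events below one month essentially never occur at the calibrated
baseline. Censoring is independent exponential (rate 0.003/month) plus
administrative at 120 months. When a target event count is requested, the
baseline hazard is calibrated by bisection against the *expected* covariate
distribution (16 weighted binary patterns, numerically integrated expected
events), so the calibration is draw-independent; treated-cohort analogues
attenuate the μENV coefficient toward zero via a config factor. Clinical
covariates are drawn so each dichotomization has prevalence 0.5
(age ~ U(35, 65), size ~ U(0.5, 3.5), GGI ~ N(0, 1)).

**Not emulated:** probe-level bead data, batch effects, cross-platform
probe mapping, correlated gene–gene structure beyond the signature imprint,
immune/stromal deconvolution layers, and informative censoring. Passing
tests therefore demonstrate correctness of the estimation machinery under
the stated model, not robustness to those real-data complications.

## Measurement conventions

Hazard-ratio recovery studies report the **geometric mean** of the
estimated HR over simulation seeds (equivalently, exp of the mean log-HR):
Cox estimates are asymptotically normal on the log scale, and the
arithmetic mean of `exp(β̂)` is inflated by `exp(var(β̂)/2)` (~5% at ~53
events), i.e. it is not a consistent summary of the planted ratio.
Positive-rate recovery is measured on mixed cohorts through the full gating
path (reporter thresholds → subtype partition → collection-wide centering →
within-subtype scoring), averaged over five seeds of 2,000 patients:
collections are centered across all subtypes, and centering a
single-subtype cohort would absorb most of the signal of a
majority-activated group (79% in ER−/HER2−), which no real collection does.
Rare multivariable fits that fail to converge at ~53 events (< 5% of seeds)
are skipped and counted.

## Known limitations

* The moderated-t prior estimator ignores covariate-dependent variance
  trends (no mean–variance trend fitting).
* GSEA reports no leading-edge genes and supports only gene-set
  permutation.
* The Schoenfeld test is available for plain fits only; diagnosing a model
  that already includes the time interaction is out of scope.
* The μENV+ fraction recovery inherits a small upward bias for
  majority-activated subtypes (quiescent samples sit only ~0.2·shift below
  the collection mean), visible as ~+2 pp on the basal rate.
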
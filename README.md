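# muenv — subtype-specific tumor–stroma signature analysis

Breast tumors are shaped not only by their intrinsic molecular subtype but by
their stroma: fibroblasts near the tumor become "activated" (cancer-associated
fibroblasts, CAFs) and remodel tumor-cell expression through secreted factors.
`muenv` implements a complete, reproducible pipeline for deriving
**microenvironment (μENV) gene signatures** from an in-vitro model — breast
cancer cell lines of three subtypes (luminal/ER+, HER2+, basal-like) treated
with conditioned medium from cancer-associated vs normal fibroblasts — and for
testing whether those signatures carry prognostic information in clinical
cohorts.

It is written for computational biologists who want to reproduce, stress-test
or extend this class of analysis. Because the original clinical collections
are external microarray cohorts, the package ships first-class **synthetic
data generators** that emulate every layer of the study (treatment effects on
cell lines, bimodal ESR1/ERBB2 subtype reporters, a latent
microenvironment-activation state, survival with planted hazards), so every
stage is testable end to end with known ground truth.

## The method

1. **Differential expression (moderated t).** Within each subtype, per-gene
   linear models `expression ~ condition + cell_line` contrast CAF-CM vs
   NAF-CM treatment. Gene-wise variances are shrunk by the empirical-Bayes
   hierarchical model: with prior `s² ~ s₀²·d₀/χ²_{d₀}`,

       s̃²_g = (d₀·s₀² + d_g·s²_g) / (d₀ + d_g),   t_g = log2FC_g / (s̃_g·c)

   on `d₀ + d_g` degrees of freedom; `(d₀, s₀²)` are estimated by moment
   matching on `log s²` (digamma/trigamma equations, trigamma inverted
   numerically). A gene is DE when `p < 1e-4` **and** FC < 0.67 or FC > 1.5
   (both strict).
2. **Enrichment (preranked GSEA).** The weighted Kolmogorov–Smirnov running
   sum on the t-ranked list; gene-set permutation null, `NES = ES / mean|null
   ES|` of matching sign, positive/negative pooled FDR.
3. **Signature & scoring.** Each subtype's signature is its DE gene list plus
   a **centroid**: the mean expression of those genes in the subtype's
   CAF-treated lines, after mean-centering the whole cell-line collection.
   A tumor's μENV status is the sign of the Spearman correlation between its
   centered expression on the signature genes and the centroid
   (ρ > 0 ⇒ μENV-positive). Cohorts are first gated into ER+/HER2−, HER2+
   and ER−/HER2− using thresholds fit to the bimodal ESR1/ERBB2 reporter
   distributions (two-component Gaussian mixture, posterior-0.5 crossing).
4. **Survival.** Kaplan–Meier, log-rank, and Cox proportional-hazards models
   of distant-metastasis-free survival (Efron ties; 10-year administrative
   censoring at 120 months), univariable and multivariable with dichotomized
   age (>50), size (>2 cm) and GGI (>0); a GGI-by-time interaction
   `x·log t` is fitted via episode splitting at the event times, and
   proportional hazards are checked with the Grambsch–Therneau test on
   scaled Schoenfeld residuals (same log-time transform).

## Worked example

Run the whole synthetic study end to end (simulate → preprocess → DE → GSEA
→ signatures → cohort → gating → scoring → survival):

```
muenv run-all --seed 42 --out run42
```

With a 5,000-gene cell-line experiment and an 800-patient cohort this prints
(excerpt from the log and the survival summary):

```
subtype luminal: 67 DE genes
subtype her2: 111 DE genes
subtype basal: 11 DE genes
subtype luminal (ER+/HER2-): 45.6% muENV-positive of 419
subtype her2 (HER2+): 67.5% muENV-positive of 169
subtype basal (ER-/HER2-): 83.0% muENV-positive of 212
"luminal": {"logrank_p": 0.000183, "uni_hr": 2.62, "multi_hr": 3.00, "n": 419, "n_events": 63}
"her2":    {"logrank_p": 0.42,     "uni_hr": 1.51, "n": 169, "n_events": 20}
"basal":   {"logrank_p": 0.37,     "uni_hr": 1.60, "n": 212, "n_events": 35}
```

Reading this: the generators planted DE counts of 69/114/10 and latent
activation fractions of 43%/64%/79% — the recovered DE lists and the
classified positive rates track them. The μENV-positive luminal patients
show a clearly elevated distant-metastasis hazard (univariable HR 2.62,
log-rank p ≈ 2e-4) that persists in the multivariable model, while the
smaller HER2+/basal groups (20 and 35 events) do not reach significance —
the pattern the pipeline is designed to quantify. Every run writes per-stage
TSVs (contrasts, signatures, μENV calls, KM tables, Cox fits) plus a
manifest with the config hash and seed; the same config and seed reproduce
every table byte for byte.

Each stage is also exposed separately (`muenv simulate-celllines`, `de`,
`gsea`, `signature`, `subtype`, `score`, `survive`) and as library functions
(`muenv.fit_linear_contrast`, `muenv.classify_muenv`, `muenv.cox_fit`, ...).

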
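# Methods

This note documents the statistical procedures, conventions, and
synthetic-data models implemented in `lumishift`, and the design choices
made where more than one reasonable convention exists.

## Threshold registry

All decision rules read their constants from `ThresholdConfig`, so every
cutoff can be overridden per run (or from a YAML file via the CLI):

| parameter | default | units | rule |
|---|---|---|---|
| `pfs_responder_min` | 2 | months | responder iff PFS ≥ cutoff; NR iff progression event below it |
| `vaf_mutant_min` | 0.05 | fraction | mutant iff any panel variant VAF ≥ cutoff (inclusive) |
| `de_lfc_cut` / `de_fdr_cut` | 1 / 0.05 | log2 / fraction | significance gates for DE genes and differential peaks |
| `cnv_amp_min` / `cnv_loss_max` | +1 / −1 | log2 ratio | amplified (≥) / loss (≤), both inclusive |
| `peak_cap` | 60,000 | peaks | maximum peak-set size per motif analysis |
| `gene_window` | 3,000 | bp | TSS-to-peak distance for proximity |
| `min_sites_per_gene` | 2 | sites | ">1 site" read as ≥ 2; set to 1 for the inclusive reading |
| `min_depth` | 1 | reads | coverage floor below which a variant is not evaluated |
| `nes_display_cut`, `tf_top_k` | 2, 10 | — | display filters for GSEA and TF enrichment |

## Statistical primitives

**One-sided Fisher test.** P(X ≥ a) under the hypergeometric null with the
table's margins (enrichment direction). The odds ratio is the sample value
(a·d)/(b·c); a zero denominator with a positive numerator yields an
infinity sentinel. An optional Haldane correction (+0.5 per cell) applies
to the displayed odds ratio only, never to the p-value.

**FDR.** Benjamini–Hochberg step-up throughout. Note BH is not idempotent
(re-adjusting adjusted values inflates them); the tested invariants are
the direct step-up formula and rank-monotonicity.

**Rank tests.** The unpaired two-sided Mann–Whitney U test enumerates the
exact distribution when the combined sample size is ≤ 12 and tie-free,
otherwise it uses the normal approximation with tie correction (the mode
is reported). The paired test is the Wilcoxon signed-rank test: zero
differences are dropped (count reported; all-zero input returns p = 1
with a warning), and with ≤ 12 non-zero pairs the full 2^n sign-flip
distribution of the signed-rank sum is enumerated with average ranks —
this covers tied magnitudes, which off-the-shelf exact routines do not.
The figure-style "paired two-sided Mann–Whitney" comparison of condition
means is deliberately read as this paired signed-rank test, since a
Mann–Whitney test is unpaired by construction; the unpaired test remains
available separately.

**Chi-square.** Pearson's statistic without continuity correction;
zero-margin rows/columns are rejected.

## Signature scoring and luminal classification

Expression (log scale, genes × samples) is z-scored gene-wise against a
reference cohort: z = (x − mean_ref)/sd_ref with ddof = 1. Genes constant
in the reference are dropped with a warning; gene symbols are matched
case-insensitively after whitespace stripping, with no alias resolution.
A signature score is the unweighted mean z over the signature's available
genes (missing genes are reported, not imputed). ERα activity is the
21-gene estrogen-induced score; the 17-gene repressed panel is scored
separately and never subtracted. A sample is Lum-high iff it strictly
exceeds the median of the supplied sample set on *both* the ERα-activity
and luminal-TF scores; median ties fall to Lum-low. Medians are computed
over whatever baseline sample set is passed in — restricting to one
treatment arm is the caller's choice (the alternative, per-arm medians,
is equally defensible; the all-baseline default is documented here).

## Mutation inference and CNV

Per (sample, gene), status is the OR over panel variants: *mutant* if any
covered variant has VAF ≥ 5% (inclusive), *NMD* (no mutation detected) if
all covered variants fall below, *no-call* if no variant reaches the
1-read coverage floor. The no-call class is deliberate: zero coverage is
missingness, not evidence of absence. Off-panel variants are excluded
with a warning. CNV classes use inclusive log2 copy-ratio cutoffs (±1).
No cancer-gene list ships with the package; `filter_cancer_genes` takes a
user-supplied list.

## Survival

Kaplan–Meier estimation uses the product-limit estimator; the median is
the earliest time with S(t) ≤ 0.5 (infinity sentinel when never reached).
The log-rank test accumulates observed/expected events and hypergeometric
variance over distinct event times; the hazard ratio is the ratio of O/E
ratios rather than a Cox fit, matching the convention of attributing the
HR to the log-rank test itself. Patients censored before the responder
cutoff form an explicit *indeterminate* class, excluded from NR/Resp
contrasts — they cannot be shown to have progressed early.

## Expression association

Paired differential expression uses an ordinary per-gene paired t-test on
log2 values (log2FC = mean paired difference). This is a deliberate
deviation from moderated empirical-Bayes variance models: the validation
surface here is planted-effect recovery on synthetic data, not numerical
identity with any published package, and the ordinary t is exact under
the generator's Gaussian noise. Zero-variance genes get p = 1 (no shift)
or p = 0 (exact shift).

Preranked GSEA sorts genes by decreasing metric (ties broken by symbol
for determinism). Hits increment the running sum by |metric|^w (w = 1 by
default, w = 0 for unit weights) normalized by the total hit weight;
misses decrement by 1/(N − k). ES is the maximum deviation from zero. The
null is gene-label permutation at fixed set size; NES divides ES by the
mean |ES| of same-sign permutations; the two-sided p counts sign-matched
exceedances against all permutations with an add-one correction,
doubled and capped at 1 (approximately uniform under the null).

Per-gene response association fits logistic regression of response
(Resp = 1) on per-gene standardized expression plus dummy-encoded
covariates (arm, subtype), so coefficients are log-odds per SD, reported
divided by ln 2 as log2-odds. Complete separation or non-convergence
(|coef| > 15) yields a signed infinity sentinel with NaN p, excluded from
FDR. Enrichment calls (NR- vs Resp-enriched) gate on FDR < 0.05 with the
coefficient sign.

TF-target enrichment builds, per TF, the 2×2 of query × target membership
over the supplied universe and applies the one-sided Fisher test; the top
10 TFs by odds ratio among FDR < 0.05 are flagged.

## Chromatin

Peaks are BED-convention intervals (0-based, half-open). Differential
classes: *up*/*down* at |log2FC| ≥ 1 and FDR < 0.05; *unchanged* at
|log2FC| < 1 with FDR < 1 — an effectively unfiltered band, implemented
verbatim; *excluded* otherwise. Classes partition the input exhaustively.
Oversized peak sets are down-sampled to exactly `peak_cap` by seeded
uniform sampling without replacement, preserving input order.

Motif enrichment reports %TP − %FP (foreground minus background motif
percentage, in [−100, 100]) with a one-sided Fisher p per motif. The
background set is always supplied explicitly by the caller (unchanged
peaks, or opposite-direction motif-matched peaks) — there is no implicit
default. Co-occurrence partitions restrict to peaks carrying at least one
of the two motifs and report exclusive A-only/B-only/both fractions.

Peak-to-gene mapping anchors distance at the gene TSS (strand ignored):
distance 0 inside the peak, `start − tss` to the left, `tss − end + 1` to
the right (half-open end). The window is anchored at the TSS rather than
peak summits because the downstream claims concern promoter-proximal
regulation; genes qualify with ≥ 2 proximal sites by default.

## Synthetic-data models

**Cohort.** One latent binary state per patient — responder-like/
luminal-high versus non-responder-like/luminal-low — with P(low) =
`frac_nr` = 0.5 (the monotherapy biomarker subset of the motivating
setting is balanced, and 30–50% of patients progress by first scan).
Baseline expression is Gaussian around per-gene means (N(7, 1) log2
units) with noise SD 1; the high state carries +1 z-unit (`sig_effect`)
on estrogen-induced and luminal-TF genes, the low state +1 on MAPK-target
genes. On-treatment (C2D8) profiles of high-state patients lose the
estrogen-induced boost, emulating on-target drug effect; no separate
treatment-effect parameter exists. Survival is exponential per state
(median = ln 2/hazard gives closed-form calibration): median 6 months in
the low state and hazard ratio 6/22 for high vs low, reproducing a
22-vs-6-month median contrast. Censoring is independent uniform at rate
0.2. The reference cohort (138 samples) is effect-free draws from the
background distribution, standing in for a real reference population that
cannot be bundled. The clinical table exposes the latent state
(`true_group`) for truth-based evaluation. At the default exponential
shapes, few low-state patients progress before 2 months, so the *derived*
NR label is much rarer than the latent low state; truth-based analyses
should use `true_group`.

**Pileups / IHC.** Mutant reads are Binomial(depth, VAF) per planted
allele fraction. IHC intensity rows are Dirichlet × 100; zero
concentration entries pin buckets at exactly 0%.

**Chromatin.** One synthetic chromosome (60 Mb, 6,000 background peaks of
width 400 bp by default). Peak classes are multinomial with
`frac_up` = 0.25 and `frac_down` = 0.06 (gains several-fold more common
than losses, as seen after long-term ERα inhibition); per-peak log2FC/FDR
are drawn consistently with the class so that classification recovers the
planted truth exactly. Motif occurrences are Bernoulli with per-class
probabilities chosen so that, among peaks carrying ERα and/or FOXA1
motifs, ~70% of down peaks are ERα-only and ~70% of up peaks are
FOXA1-only. For each of 50 planted genes per co-occurrence pair
(FOXA1+MEF2B, FOXA1+TEAD1, FOXA1+STAT5B), two guaranteed up-class peaks
carrying both motifs are placed within the 3 kb window of the TSS, and
the gene's expression rises by `trend_effect` = 1 log2 unit per condition
step (parental → 2-month → resistant, noise SD 0.3).

**What the generators do not model.** Gene–gene correlation (expression
noise is independent), realistic library-size/count noise (values are
Gaussian on the log scale, not counts), batch effects, PAM50 subtype
structure beyond a covariate label, overlapping/clustered peaks, motif
hit correlation within peaks, and non-proportional hazards. Passing the
planted-recovery tests therefore demonstrates correctness of the
*computations* under the stated models, not robustness to the full noise
structure of real tumor data.

## Problem sizes and numerics

Validation suites run at desk scale: cohorts of 54–200 patients, ~560
genes (signature panels + 500 background), 2,000-gene null panels for
calibration checks, 2,000–6,300-peak chromatin landscapes, 199–1,000
permutations for GSEA. Exact enumeration paths (Fisher, rank tests ≤ 12,
sign-flip Wilcoxon) are compared to brute-force oracles at tolerance
1e-10 or better. All stochastic steps take explicit seeds; generators are
pure functions of (config, seed).

Known limitations: the logistic association sentinel threshold (|coef| >
15) is heuristic and may mislabel extremely strong genuine effects as
separation at small n; the O/E hazard ratio is biased away from 1
relative to a Cox estimate when groups are very unbalanced; and the
strict-median luminal rule guarantees ≤ 50% Lum-high, so latent-state
prevalences far from 50% attenuate group contrasts measured on derived
labels.
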
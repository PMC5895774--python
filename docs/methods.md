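# Methods

This note documents the models implemented in `steroidratio`, the
choices made where the procedure was genuinely open, and what the
synthetic data can and cannot demonstrate.

## Data model

A subject carries a class label (PCa / BPH / HC), age, total PSA
(ng/mL, possibly missing — "ND" cells are represented as missing, never
as zero) and a ten-steroid serum panel in ng/mL. The analyte order

aldosterone, corticosterone, cortisol, 11-deoxycortisol,
androstenedione, testosterone, DHEA, DHEAS, 17-OH-progesterone,
progesterone

is canonical: every positional index in the ratio formulas refers to
it. The embedded clinical table (71 subjects: 20 PCa, 20 BPH, 31 HC)
carries PSA, DHEAS, the reported 1–100 discriminating coefficient and
three reported classification columns, but not the full panels, which
were never published; everything that needs full panels runs on
synthetic cohorts.

## Feature encodings

**Ratio vector.** All pairwise ratios R(k, i) = C(k)/C(i) over the
canonical order with k < i — the numerator is always the
earlier-indexed analyte — giving n(n−1)/2 = 45 entries for n = 10.
The enumeration over unordered pairs is forced by the count formula
N(R) = Σ_{k=1}^{n−1}(n−k). Ratios are invariant under global rescaling
of a panel, which is the encoding's point: a dilution or calibration
shift common to all analytes cancels.

**Weight normalization.** Cortisol is divided by 10 and DHEAS by 100
before vector building (they circulate one to two orders of magnitude
above the other eight steroids and would otherwise dominate the
similarity). The operation is not idempotent; panels carry a
`normalized` flag so it is applied exactly once. It is on by default in
both matching modes.

**Percent vector (absolute match).** Cn_i = (C_i / Cv)·100 with
Cv = Σ C_i, entries keyed by the analyte's MRM parent m/z (shared parent
ions — DHEA and DHEAS both at m/z 271.2 — are disambiguated by analyte
name in panel order). A virtual m/z-1000 channel carries the raw total
Cv. The virtual channel is *excluded* from similarity by default
(`include_total` flag to include): it encodes overall abundance, which
would break the compositional intent of the encoding.

## Similarity and posterior

Similarity is (1 + cos θ)/2 ∈ [0, 1]; in ratio mode the cosine is taken
on the elementwise natural log of the ratio entries, making R and 1/R
symmetric contributors and the score exactly scale-invariant. The
log-transform lives in the classifier, not in the stored vector.

Per-class likelihood is the mean of the top-K neighbor similarities
within the class (K = 3 by default; with fewer than K members the class
mean is over what exists). The posterior is likelihood × prior ×
correction, normalized to sum to one. Priors are uniform by default so
the 31/20/20 class imbalance does not dominate; class-frequency and
explicit priors are available.

**Correction factor.** The per-class multiplicative correction C_A is
refined over sequential classification rounds: on a wrong round the
under-predicted true class is multiplied by (1 + rate) and the
over-predicted class divided by it; on a correct round every factor
decays toward 1 via the exponent (1 − rate). Rate 0.01, factors clipped
to [0.5, 2.0]. Only the *purpose* of this factor (progressively raising
classification accuracy over ≥ 10,000 sequential steps) is documented
for the original system, whose functional form is proprietary; the form
here is a declared substitute chosen to be deterministic, bounded, and
fixed-pointed at 1 on an all-correct stream. Corrections start at 1 and
are only changed by an explicit `refine`/`sequential_correction` call —
the leave-one-out results below therefore use unit corrections.

**Discriminating coefficient.** 1 + 99 × (winning posterior − runner-up
posterior), an affine map of the posterior margin onto [1, 100]. A
winning-posterior form (1 + 99·p_win) was rejected because with three
classes it cannot fall below ≈ 34 and so could never populate the low
(HC) band observed in the reported coefficients. The banding rule for
*reported* coefficients uses cutoffs (10, 30), placed inside the empty
gaps of the printed values (8.0 → 18.7 and 26.8 → 38.7): ≤ 10 → HC,
≥ 30 → PCa, else BPH.

**Ties** (exactly equal posteriors) go to the class of the single most
similar neighbor, then lexicographically. Classification is fully
deterministic; there is no hidden randomness.

**Leave-one-out protocol.** Each subject is classified against a
database of all other subjects (identity match excluded by id). This is
the evaluation used everywhere a classifier accuracy is quoted.

## Threshold baselines

Single-marker cutoffs are confidence limits of the geometric mean of
the PCa group's marker values, from a Student-t interval on natural
logs: gm = exp(mean ln x), CI = exp(mean ln x ∓ t·sd(ln x)/√n). PSA
uses the *lower* limit with high-side-positive (≥ 7.385 ng/mL → PCa,
n = 19 after excluding missing values — the printed cutoff is only
reproduced at n = 19); DHEAS uses the *upper* limit with
low-side-positive (< 888.7 ng/mL → PCa). Boundary values go to the high
side in both cases, consistent with every printed row.

## Evaluation

AUC is trapezoidal over the empirical ROC, identical to the
Mann-Whitney U statistic over score pairs with ties counting 0.5
(verified against a brute-force pair-counting oracle in the tests).
Missing scores are excluded and counted, never imputed. Sensitivity is
TP/(TP+FN) on the designated positive class; specificity TN/(TN+FP)
over all non-positive subjects, any non-positive prediction counting as
negative. Note the package's recomputed specificities from the printed
per-group counts (band rule: 41/51 = 80%; DHEAS rule: 35/51 = 69%) do
not equal the originally reported summary specificities (84% and 59%);
the recomputed values are reported as such and the discrepancy is
flagged rather than targeted.

## Enzyme attribution

The steroidogenesis graph ships as an editable edge list (substrate,
product, enzyme) covering cholesterol through the mineralocorticoid,
glucocorticoid and androgen branches, including non-panel intermediates
(pregnenolone, 17-OH-pregnenolone, 11-deoxycorticosterone, DHT). A
pair's **relational coefficient** is the Chebyshev (max-coordinate)
distance between class centroids of its log ratio — for a single pair,
the largest absolute centroid difference over class pairings — affinely
rescaled per cohort onto [1, 100] (least separating pair → 1, most →
100). Pairs above a threshold (default 40) are reported with the enzymes
on the shortest directed pathway segment between their steroids, in
either orientation; unconnected branches (e.g. aldosterone vs DHEAS)
yield an empty attribution. This is a heuristic ranking for hypothesis
generation, not an inference about enzyme activity.

## Synthetic cohort generator

Concentrations are log-normal per analyte with class-specific median
multipliers, optionally correlated on the log scale (a user-supplied
PSD correlation matrix; independent by default). Class sizes default to
20 PCa / 20 BPH / 31 HC. Anchors encoded in the defaults:

* **Scale:** HC medians (ng/mL) — aldosterone 0.10, corticosterone 4,
  cortisol 120, 11-deoxycortisol 0.3, androstenedione 1, testosterone
  4.5, DHEA 3, DHEAS 1200, 17-OH-progesterone 1.2, progesterone 0.15 —
  standard adult-male reference ranges, with DHEAS and cortisol one to
  two orders of magnitude above the rest. Between-subject log-sd 0.35
  (0.4–0.5 for the noisier aldosterone, cortisol, DHEAS channels).
* **PCa:** androgen-arm suppression — explicit multipliers (testosterone
  0.6, androstenedione/DHEA 0.7, DHEAS 0.6) compounded with a partial
  P450C17 deficit (factor 0.75) propagated along the pathway graph, so
  most steroids end lower in PCa while progesterone accumulates.
* **BPH:** a distinct mineralocorticoid-branch elevation (aldosterone/
  corticosterone ×1.8, 11-deoxycortisol ×1.6) plus mild androgen
  decrease, giving the class its own axis rather than placing it midway
  between HC and PCa. The branch shifts were calibrated once so that
  leave-one-out recovery on a default 71-subject cohort mirrors the
  reported per-group recovery pattern (roughly 90/80/81% for
  PCa/BPH/HC); they stay well inside physiological fold-ranges.
* **PSA:** log-normal with medians 1.0 (HC, matching the < 2.5 ng/mL
  control definition), 6.3 (BPH) and 10 (PCa, heavy-tailed, σ = 1.0),
  bracketing the clinical table's ranges.

**Enzyme perturbation** multiplies everything downstream of an enzyme's
edges by the factor and divides the enzyme's substrates — and their
descendants along branches that bypass the enzyme — by it. The upstream
propagation matters: a 21-hydroxylase deficit must raise not only
17-OH-progesterone and progesterone but the androgen branch fed by the
accumulated precursors, which a substrates-only rule would miss. This
is a mass-action caricature, not a kinetic model.

All draws flow from one mandatory seed through per-class spawned
substreams, so equal seeds give byte-identical cohort files.

**What passing tests show, and what they do not.** On these synthetic
cohorts the ratio-relationship mode recovers the classes at > 75%
leave-one-out accuracy and beats the absolute-percent mode by a wide
margin (≈ 86% vs ≈ 68% at seed 1) — demonstrating that the pipeline
recovers class structure *of the kind assumed* (fold-change signals on
low-abundance analytes, noisy dominant channels). Real serum panels
have unknown covariance among steroids, age and BMI effects, assay
floor effects near the LOD, and class differences that need not follow
the assumed enzyme axes; none of that is emulated, so synthetic
accuracies say nothing quantitative about clinical performance.

## Calibration QC

Calibration lines are least squares of response ratio vs nominal with
1/x weighting by default (MS responses are heteroscedastic over a
four-decade range); residual sd is the unweighted RMS residual with
n − 2 degrees of freedom. LOD = 3.3·sd/slope and LOQ = 10·sd/slope —
the slope rule, chosen because the reference assay documents only that
limits were derived from its 7-point calibration curves; its per-analyte
validation figures ship as annotation metadata
(`reference_assay_metrics`) and are never recomputed. Precision is the
replicate CV and accuracy error the relative bias against nominal.

## Numerical notes and limitations

* Cosine inputs are validated finite and non-zero-norm; the cosine is
  clipped to [−1, 1] before the affine map.
* Degenerate inputs raise typed errors naming the offending analyte
  (zero concentration in ratio mode, all-zero panel in percent mode).
* A panel-wide zero likelihood (impossible with the affine similarity
  map unless every similarity is exactly 0) falls back to a uniform
  posterior.
* Problem sizes: tests and the acceptance script run leave-one-out on
  71-subject cohorts (45-dimensional ratio features), sequential
  correction streams of 10⁴ steps, and an n = 1000 draw for marginal
  checks; the whole suite completes in a few seconds.
* The matching engine is instance-based; nothing is trained beyond the
  reference database and the bounded correction factors.
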
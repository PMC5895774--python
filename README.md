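# steroidratio

Serum steroid **ratio-relationship profiling** for prostate cancer
diagnostics.

Quantitative LC-MS/MS panels of ten serum steroids (aldosterone,
corticosterone, cortisol, 11-deoxycortisol, androstenedione,
testosterone, DHEA, DHEAS, 17-OH-progesterone, progesterone) carry
diagnostic information not only in the absolute concentrations but in
their *ratios*, which reflect the activities of the steroidogenesis
enzymes connecting them. This package implements a profile-matching
classifier over those ratios and the baselines it is compared against,
for researchers evaluating steroid panels as a triage tool alongside
PSA in men worked up for prostate cancer (PCa) versus benign prostate
hypertrophy (BPH) and low-PSA healthy controls (HC).

## The method

For a panel of concentrations C₁,…,Cₙ (n = 10), the **ratio vector**
collects every pairwise ratio

> R(k, i) = C(k) / C(i),  1 ≤ k < i ≤ n,  N(R) = n(n−1)/2 = 45 entries,

after a weight normalization that divides cortisol by 10 and DHEAS by
100 (those two circulate one to two orders of magnitude above the other
eight and would otherwise dominate any similarity score). A subject is
classified against a labeled reference database by angular similarity —
(1 + cos θ)/2 on the elementwise log of the ratio vectors, so a ratio
and its reciprocal contribute symmetrically and the score is invariant
to global rescaling of a panel — combined through a Bayes posterior

> P(A | B) ∝ P(B | A) · P(A) · C_A

where the likelihood P(B | A) is the mean similarity to the top-K
(default 3) neighbors in class A, P(A) is the class prior (uniform by
default) and C_A is a per-class multiplicative correction factor refined
over sequential classification rounds. Evaluation is leave-one-out: each
subject is scored against a database built from all the others, identity
match excluded. Each prediction carries a **discriminating coefficient**
on a normalized 1–100 scale; a banding rule maps reported coefficients
to classes (≤ 10 → HC, ≥ 30 → PCa, otherwise BPH).

Baselines: the **singular absolute concentration match** (the same
engine on percent-of-total concentration vectors, with a virtual
m/z-1000 channel carrying the raw total), and single-marker cutoffs set
at a 95% confidence limit of the geometric mean of the PCa group —
the *lower* limit for PSA (7.385 ng/mL on the embedded clinical table)
and the *upper* limit for DHEAS (888.7 ng/mL). ROC curves use the
trapezoidal / Mann-Whitney AUC. Class-separating ratio pairs are mapped
to steroidogenesis enzymes through an editable pathway graph
(`steroidratio enzymes`), e.g. the progesterone / 17-OH-progesterone
ratio implicates P450C17 (CYP17A1).

Because the study's full per-subject panels were never published, the
package includes a seeded synthetic cohort generator
(`steroidratio.simulate`) that emulates the study conditions
(20 PCa / 20 BPH / 31 HC, log-normal concentrations, class shifts and
enzyme-level perturbations propagated along the pathway graph); see
`docs/methods.md` for what it does and does not emulate.

## Worked example

```python
>>> import numpy as np
>>> from steroidratio import builtin_table1, geometric_mean_ci, roc_auc, band_classify
>>> t1 = builtin_table1()
>>> t1.class_counts()
{'PCa': 20, 'BPH': 20, 'HC': 31}
>>> psa = [s.psa for s in t1 if s.class_label == "PCa" and s.psa is not None]
>>> ci = geometric_mean_ci(psa)
>>> round(ci.lo, 3), ci.n
(7.385, 19)
>>> scores = [s.reported_coefficient for s in t1]
>>> labels = [s.class_label for s in t1]
>>> round(roc_auc(np.array(scores), np.array(labels), positive="PCa").auc, 4)
0.8353
>>> band_classify(44.5), band_classify(22.6), band_classify(5.3)
('PCa', 'BPH', 'HC')
```

The PSA threshold (7.385 ng/mL, the lower 95% GM limit over the 19
PCa subjects with a measured PSA) and the 0.8353 AUC of the 1–100
coefficient against PCa-vs-rest are the two headline numbers of the
embedded clinical table; the banding of the three example coefficients
shows one subject from each diagnostic band.

On a synthetic default cohort the full pipeline runs end to end:

```sh
$ steroidratio simulate --seed 1 --out cohort.csv
wrote 71 subjects to cohort.csv ({'PCa': 20, 'BPH': 20, 'HC': 31})
$ steroidratio classify cohort.csv --mode ratio
ratio-mode LOO accuracy: 85.9% (71 subjects)
PCa sensitivity 80%, specificity 100%
```

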
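# Methods

## The decision problem

A patient with a branch-duct or mixed-type IPMN (main pancreatic duct
dilatation at most 10 mm; wider ducts are main-duct disease and outside
scope) faces two competing risks: an unresected malignancy, and the
morbidity of a pancreatectomy performed on what turns out to be benign
disease. Both risks are quantifiable per patient — a malignancy
probability MP from a logistic nomogram over seven preoperative factors,
and a serious-complication probability SC from a surgical risk
calculator — and the package turns them into two decision rules.

**Balance rule (cohort-level).** On a cohort with known pathology
(malignant = high-grade dysplasia or invasive carcinoma), a cutoff *c*
on MP misses FN(*c*) malignancies and performs FP(*c*) unnecessary
operations. Weighting each unnecessary operation by the complication
rate *r* of the operation performed, the two harms balance where
FN = FP × *r*. On integer counts that equality is almost never exact,
so the selected cutoff minimizes |FN − FP·*r*| over the cutoff grid,
with ties broken toward the lower cutoff (favoring sensitivity). The
selection reports a boundary flag when the minimizer is the first or
last grid point, i.e. when the grid did not bracket a crossing. Because
FN rises and FP falls with *c*, the selected cutoff is weakly increasing
in *r* — a provable property of the rule, verified in tests — so more
morbid operations (PD vs DP) and more severe complication thresholds
yield higher cutoffs. Patients with MP exactly at the cutoff count as
operated (≥ convention); cutoffs are percents at every interface and
fractions internally, with the comparison done on the fraction scale.

**Direct rule (patient-level).** Operate when MP strictly exceeds the
patient's own SC; a tie goes to surveillance. The binary rule has a
single ROC operating point, so two AUC conventions are reported and
clearly labeled: the trapezoid AUC through that point,
(sensitivity + specificity)/2, and the AUC of the continuous difference
score MP − SC. Note that a common shift of both scores on the logit
scale leaves every operate/surveil decision unchanged (logit is strictly
monotone) but does reorder the difference score; only the binary rule is
shift-invariant, and a test documents both facts.

## Probability models

`LogisticModelSpec` holds an intercept, per-feature coefficients and
per-feature transforms (`identity`, `log1p`, `indicator`). The default
malignancy spec places its largest weights on duct diameter, mural
nodule and log1p(CA19-9) — the factors that dominate multivariable
analyses in this population — with smaller weights on age, sex, cyst
size and CEA; tumor markers enter via log1p to tame their skew. The
published nomogram's fitted coefficients live behind a web interface and
are not printed anywhere reusable, so this default is a **surrogate,
labeled as such — calibrate before any clinical use**. Missing features
raise an explicit error; incomplete records are excluded, never imputed,
mirroring how such cohorts are assembled.

The surgical-risk surrogate is logistic(baseline logit + centred
covariate terms + Gaussian logit noise). Baselines default to the
minimal serious-complication risks of the two operations (PD 12.2%,
DP 8.4%); the default covariate is a mild age effect (0.03 per year,
centred at 63) and the noise (default SD 0.30 on the logit scale) stands
in for comorbidity variation the surrogate does not model. At zero noise
and reference covariates every patient receives exactly the baseline.

## Synthetic cohort generator

No patient-level data accompany this analysis, so the generator is a
first-class module that emulates the study conditions rather than a test
fixture. Defaults: 464 PD + 293 DP patients; age truncated-normal
(63 ± 10, clipped to 18–95); MPD diameter and cyst size truncated
log-normal (medians 3.2 mm on (0.5, 10] and 28 mm on (5, 150]); CA19-9
and CEA log-normal (medians 15 U/mL, 1.5 ng/mL); sex male 55%; mural
nodule 35%. Malignant pathology is drawn Bernoulli at the logistic
latent probability of the default malignancy model (kept with the
cohort for oracle checks), yielding ≈20% malignancy prevalence as seen
in resected branch/mixed series; malignant cases split HGD/invasive
54/46 and benign LGD/IGD 54/46, the typical pathology mix. Complication
grades are sampled from the ordinal ladder whose exceedance
probabilities equal the configured rates exactly (PD: 43.3 / 18.1 /
6.7 / 2.4%; DP: 30.4 / 8.5 / 3.4 / 2.0% at ≥II / ≥IIIa / ≥IIIb / ≥IV);
grade V is pooled into the top (≥IV) band because rates are specified at
four thresholds, and the sub-II remainder splits evenly between "no
complication" and grade I. Features are mutually independent given the
latent predictor — real cohorts correlate duct size, cyst size and
markers, so generator-based results demonstrate the machinery, not
clinical performance. A single seed feeds named substreams (features,
pathology, complications), making generation bit-reproducible and
insensitive to added downstream stages.

## Evaluation statistics

Confusion metrics at a cutoff use the same ≥-operates convention as the
balance worksheet; any ratio with an empty denominator is reported as an
explicit NA sentinel, never silently zero. AUC is the Mann–Whitney
probability that a malignant patient outscores a benign one (ties count
half), with a DeLong variance from placement values and a normal 95%
interval clipped to [0, 1]; a brute-force all-pairs oracle and
scikit-learn cross-checks back it in tests. The Hosmer–Lemeshow
statistic sums (O − E)² / (E(1 − E/n)) over quantile bins of predicted
probability — 10 bins for the 10% quantile scale, 5 for the 20% scale.
Tied probabilities stay in one bin (duplicate quantile edges reduce the
effective bin count), and zero-variance bins are merged into a neighbor
and logged. The reference distribution defaults to chi-square with
(bins − 2) degrees of freedom, the standard choice when the
probabilities come from a model fitted to the same data; for
probabilities fixed in advance (external validation) that reference is
known to be anti-conservative, so `df=n_bins` is exposed and the
calibration simulation in the acceptance tests refits a correctly
specified logistic model per replicate, the setting the default df
targets. With fewer than three effective bins the test is vacuous and
says so.

## Bundled reference worksheets

`ipmn_balance.datasets` ships the two published balance worksheets —
fourteen (cutoff, FP, FN) rows each for the PD (n = 464, 116 malignant)
and DP (n = 293, 54 malignant) groups with their complication rates.
They are inputs (published aggregate counts), not package outputs, and
they let the selection rule be exercised against its published answers:
13/21/32/41% (PD) and 14/16/21/27% (DP) across the four severities. One
printed cell of the PD worksheet (the ≥IV product in the FP = 117 row)
is inconsistent with its own row — it equals 114 × 0.024 while the
row's other three products use 117 — and the tests freeze the
arithmetically consistent value. An alternative "first crossing"
selection rule was rejected because it fails to reproduce the published
PD ≥IIIa cutoff (it yields 33, not 32); nearest-to-equality reproduces
all eight.

## Problem sizes and numerical choices

Property tests run 100 random cohorts of up to 200 patients against
exhaustive oracles; marginal-recovery checks use 50,000 patients per
surgery group (3 binomial SE tolerance); the calibration type-I check
runs 500 replicates of 2,000 patients. The default cutoff grid is the
integer percents 1–99; published worksheets supply their own grids.
Weighted-FP columns print at three decimals and proportions at four,
matching the worksheet conventions. All randomness descends from one
integer seed through named substreams.

## Limitations

The default models are surrogates: nothing here reproduces the fitted
nomogram or the proprietary risk calculator, and cohort-dependent
published statistics (cohort AUCs near 0.80/0.63, the 31.7% surgery
reduction of the direct rule) are not reproducible without the original
patient-level data — the package reproduces the published worksheet
arithmetic and cutoffs exactly, and validates everything cohort-dependent
by simulation against oracles instead. The generator's independence
assumption understates real feature correlation; the balance rule
weighs harms by complication *rate* only, not severity-specific utility
(no QALY or cost extension); and max-across-modalities imaging rules are
out of scope since the synthetic cohort carries one value per feature.
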
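# ipmn-balance

Risk–benefit decision analysis for surgery in branch-duct and mixed-type
intraductal papillary mucinous neoplasm (IPMN) of the pancreas.

IPMNs are premalignant pancreatic cysts with a broad spectrum of
malignancy risk. Clinical nomograms can turn a patient's preoperative
profile — age, sex, main pancreatic duct (MPD) diameter, cyst size, mural
nodule, CA19-9, CEA — into a malignancy probability (MP), but they do not
say *where to cut*: above which probability should a surgeon operate,
given that pancreatectomy itself carries substantial morbidity? This
package, aimed at surgical and biostatistical researchers, implements a
cutoff-selection framework that weighs both sides of that trade-off.

## The balance rule

For a candidate cutoff *c* on the malignancy probability (operate when
MP ≥ *c*), define on a surgical cohort with known pathology:

- **FN(c)** — malignant patients with MP < *c*: malignancies the cutoff
  would have missed;
- **FP(c)** — benign patients with MP ≥ *c*: operations the cutoff would
  have performed unnecessarily.

Each unnecessary operation only harms with the probability *r* of a
postoperative complication, so the two risks balance at the cutoff where

```
FN(c) = FP(c) × r
```

FN is weakly increasing and FP weakly decreasing in *c*, so a balance
point exists and the selected cutoff is the grid value minimizing
|FN − FP·r| (ties go to the lower cutoff, favoring sensitivity). Because
complication rates differ by operation and by how severe a complication
one is willing to weigh, the rule is applied per surgery group
(pancreaticoduodenectomy, PD; distal pancreatectomy, DP) and per
Clavien–Dindo severity threshold (≥II, ≥IIIa, ≥IIIb, ≥IV) — a riskier
operation earns a higher bar for surgery.

The package also implements the fully individualized variant: operate
when the patient's malignancy probability strictly exceeds their own
predicted serious-complication risk (MP > SC), plus the evaluation
machinery for either rule — confusion metrics at a cutoff, ROC/AUC with
DeLong confidence intervals, and Hosmer–Lemeshow calibration in the 10%
and 20% quantile scales — and a synthetic-cohort generator so the whole
analysis runs without patient-level data.

## Worked example

The package bundles the published balance worksheets — per-cutoff
(FP, FN) counts for a PD group (n = 464) and a DP group (n = 293), with
their complication exceedance rates. `examples/02_balance_cutoff.py`
runs the selection rule over them:

```
PD group (grid of 14 published rows):
  complications >= grade IV   (rate  2.4%): cutoff 13%  |FN - FP x rate| = 0.912
  complications >= grade IIIb (rate  6.7%): cutoff 21%  |FN - FP x rate| = 0.399
  complications >= grade IIIa (rate 18.1%): cutoff 32%  |FN - FP x rate| = 0.711
  complications >= grade II   (rate 43.3%): cutoff 41%  |FN - FP x rate| = 0.238

DP group (grid of 14 published rows):
  complications >= grade IV   (rate  2.0%): cutoff 14%  |FN - FP x rate| = 0.240
  complications >= grade IIIb (rate  3.4%): cutoff 16%  |FN - FP x rate| = 0.012
  complications >= grade IIIa (rate  8.5%): cutoff 21%  |FN - FP x rate| = 0.030
  complications >= grade II   (rate 30.4%): cutoff 27%  |FN - FP x rate| = 0.416
```

Reading the PD ≥IIIa line: at a 32% cutoff the group's 23 missed
malignancies almost exactly equal the 131 unnecessary operations
weighted by the 18.1% major-complication rate (23.711) — so 32% is the
balance cutoff for major complications after PD. The cutoffs rise with
the complication rate within each group, and the riskier PD operation
gets a higher cutoff than DP at every severity.

The other examples generate a synthetic cohort
(`01_simulate_cohort.py`), evaluate discrimination and calibration at a
selected cutoff (`03_diagnostics.py`), apply the per-patient MP > SC
rule (`04_direct_comparison.py`), and drive the full pipeline end to end
(`05_full_pipeline.py`). A thin CLI wraps the same library calls:

```sh
ipmn-balance simulate --seed 1 --out cohort.csv
ipmn-balance score --cohort cohort.csv --out scored.csv
ipmn-balance balance --scored scored.csv --group PD --severity IIIa
ipmn-balance run --out results/
```

## Scope

The package does not re-derive the published nomogram's coefficients
(its default malignancy model is an explicitly labeled surrogate), does
not reimplement the proprietary ACS NSQIP risk calculator (a baseline +
covariates + noise surrogate stands in), and stops short of cost-utility
extensions (QALYs, monetary costs). See `docs/methods.md` for the model
details, defaults, and limitations.
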
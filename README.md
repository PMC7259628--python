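# tumorkinetics

Tools for asking a question RECIST alone cannot answer: **did the tumor's
growth rate change when treatment started?**

RECIST 1.1 judges response from post-baseline changes in the sum of longest
diameters (SLD) of target lesions, implicitly treating pre-treatment growth as
zero. But untreated solid tumors grow roughly exponentially, so a patient
labelled "stable disease" may either have indolent disease the drug never
touched, or an aggressive tumor whose growth the drug arrested — a
*therapeutically induced stable disease* (TISD). Telling these apart requires
at least one **pre-baseline scan** and a model of the kinetics on both sides
of treatment onset.

This package implements that analysis for longitudinal SLD series, for
trial statisticians and methodologists working with early-phase oncology
data (and, here, with synthetic cohorts that emulate such a trial):

* **Segmented log-linear growth model.** For patient *i* with SLD `y_ij` at
  time `t_ij` (months relative to first dose),

  ```
  ln y_ij = ln y_0i + r_gi · t_ij · I(t_ij ≤ 0) + r_si · t_ij · I(t_ij > 0) + ε_ij
  ```

  fit per patient by closed-form OLS with the breakpoint fixed at treatment
  onset (`t = 0`). `r_g` is the pre-treatment exponential rate, `r_s` the
  on-treatment rate (month⁻¹), `y_0` the model SLD at onset, and residual SD
  is pooled across patients. Rates convert to doubling / halving times via
  `T_double = ln 2 / r` and `T_half = ln ½ / r`.
* **Change-in-slope classification.** `d = r_s − r_g`; `|d| ≤ 0.05` month⁻¹
  is negligible ("stable"), `d < −0.05` improving, `d > +0.05` worsening.
  TISD = improving **and** `r_g > 0.05` month⁻¹.
* **RECIST 1.1 engine.** Per-visit CR/PR/SD/PD from baseline and nadir
  (−30 % for PR; +20 % from nadir and ≥ 5 mm, or any new lesion, for PD) and
  best overall response (BOR), cross-tabulated against the slope classes.
* **Two-point comparator.** The shortcut that estimates rates from just the
  pre-baseline→baseline and baseline→first-on-treatment intervals, to
  quantify what is lost by ignoring later scans and by conflating the
  baseline visit with treatment onset.
* **Synthetic cohorts.** A generator that draws trajectories from the model
  itself under named scenarios (`trial_like`, `tisd`, `null`) with a
  six-weekly visit schedule, progression-linked dropout and lognormal
  measurement noise — every downstream stage is testable without clinical
  data.

## Worked example

The `analysis/` scripts run the whole study on a simulated 68-patient
cohort; each writes its tables under `results/`:

```
$ python analysis/01_simulate_cohort.py
simulated 68 patients (seed 2026); 68 evaluable, 0 excluded
scans per patient: 3-14; post-baseline scans: 1-12

$ python analysis/02_fit_growth_rates.py
fit 68 patients (0 excluded); 0 fit failures
median r_g = +0.044 month^-1, median r_s = +0.072 month^-1, median d = -0.005 month^-1
pooled residual SD (log scale): 0.0862
39 patients with non-negative r_g; median doubling time among growing tumors: 6.5 months

$ python analysis/04_classify_responses.py
BOR x slope-class cross-tab:
       worsening  stable  improving  Total
bor
CR             0       0          0      0
PR             2       2         17     21
SD             3       8          4     15
PD            22       5          5     32
Total         27      15         26     68
RECIST response rate: 30.9% (21/68)
growth-declination response rate: 38.2% (26/68)
TISD (r_g > 0.05, d < -0.05): 9 patients, 3 of them RECIST-SD
```

Reading this: a median pre-treatment rate of +0.044 month⁻¹ means the
typical tumor was growing before therapy; `d` near zero says the typical
patient's kinetics barely changed, yet 26/68 individual patients improved
(`d < −0.05`), more than the 21/68 that RECIST calls responders — and three
RECIST-"stable" patients were actually growing tumors arrested by treatment.
`05_estimator_comparison.py` shows the two-point shortcut inflating the
on-treatment rate by +0.11 to +0.24 month⁻¹ (the earlier the baseline scan,
the worse) on noise-free data where the segmented fit is exact.

The same pipeline runs on real scan tables
(`patient_id,t,sld,new_lesion` CSV, or date pairs) through the CLI:

```
tumorkinetics run --in cohort.csv --out results/run
tumorkinetics simulate --scenario tisd --n 100 --seed 7 --out results/sim
```

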
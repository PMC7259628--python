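# Methods

## The model

Tumor burden is summarized by the RECIST sum of longest diameters (SLD, mm).
Untreated solid tumors are assumed to grow (or shrink) exponentially, and a
treatment that works changes the exponent at onset. For patient *i*, scan
*j* at time `t_ij` (months relative to first dose; negative = before
treatment):

    y_ij = y_0i · exp( r_gi · t_ij · I(t_ij ≤ 0) + r_si · t_ij · I(t_ij > 0) ) · exp(ε_ij)

or equivalently, on the log scale, a linear model in the design
`{1, t·I(t ≤ 0), t·I(t > 0)}`. The breakpoint sits at `t = 0` — treatment
start — by construction and is never estimated; a scan at exactly `t = 0`
belongs to the pre-treatment segment. `ε_ij ~ N(0, σ_res)` on the log scale
(multiplicative lognormal noise on SLD), with `σ_res` pooled across patients
as `sqrt(Σ RSS_i / Σ dof_i)` over patients with residual degrees of freedom.

Each patient is fit independently by closed-form OLS (normal equations).
This mirrors per-subject `lmList`-style fitting; shrinkage or mixed-effects
estimation is deliberately out of scope. With the minimum eligible design —
two pre-treatment scans and one on-treatment scan — the model is saturated
(3 observations, 3 parameters): it interpolates exactly, the residual SD is
0 and the standard errors are reported as undefined (NaN), not zero.

Derived quantities: `d = r_s − r_g` (month⁻¹) is the treatment-effect
statistic; `T_double = ln 2 / r` (defined for `r > 0`) and
`T_half = ln ½ / r` (defined for `r < 0`, reported positive) convert rates
to characteristic times. At `r = 0` both are undefined and returned as NaN
rather than raised, since a zero rate is a legitimate estimate.

## Eligibility and data model

A patient enters the rate analysis with at least two scans at `t ≤ 0` (a
pre-baseline and a baseline scan) and at least one at `t > 0`. The filter
partitions a cohort into evaluable patients and excluded ones with
machine-readable reasons (`too_few_pre`, `no_post`); eligibility is monotone
in scans. Duplicate `(patient, t)` rows are a hard error — they indicate an
upstream merge bug, and silently averaging them would hide it. Calendar
conversion is fixed at 1 month = 365.25/12 days. A missing `new_lesion`
column is tolerated (all-false, with a warning): the growth model does not
use it, only RECIST progression does.

## Zero SLD

Complete disappearance of target lesions gives SLD = 0, which cannot be
log-transformed. The default rule substitutes 2.5 mm — half the 5-mm RECIST
measurability floor, i.e. the largest SLD still indistinguishable from
absence — before fitting; a strict mode raises instead. The RECIST engine
sees the raw 0 (it means CR there). The choice only matters for the handful
of complete responders and biases their fitted `r_s` toward less extreme
shrinkage than a smaller substitute would.

## RECIST 1.1 engine

Per visit: PD for any new lesion, or SLD up ≥ 20 % from the nadir (smallest
SLD seen so far, baseline included, not counting the current visit) with an
absolute increase ≥ 5 mm; otherwise CR for SLD = 0, PR for ≥ 30 % below
baseline, else SD. PD takes precedence over CR/PR. The 5-mm clause is part
of RECIST 1.1 and on by default; it can be disabled, which also makes the
categories exactly scale-invariant (used in tests). BOR is the best category
over on-treatment visits (CR > PR > SD > PD); by default evaluation stops at
the first PD, matching trials that scan until progression — a full-trail
mode is available and agrees on BOR for patients who never progress. No
confirmation scans are required for CR/PR, and SD has no minimum duration by
default (a threshold in months is available). A patient with no evaluable
on-treatment assessment is UE. Non-target lesions are outside the data
model, so CR means target-lesion SLD = 0.

## Classification and summaries

With cutoff `c = 0.05` month⁻¹ (configurable): improving `d < −c`, worsening
`d > +c`, stable otherwise — the boundaries `d = ±c` are classified stable,
reading "between −0.05 and +0.05 is negligible" as a closed interval. TISD =
improving with `r_g > c`: a tumor that was genuinely growing and whose
growth the drug arrested. The flag is computed for all patients; an option
restricts it to RECIST-SD patients, the subgroup where it is usually
reported. Group summaries (all / RECIST responders / non-responders) give
mean with a t-distribution 95 % CI (n−1 dof; normal approximation available;
NaN for groups of one), median and range for each of `r_g`, `r_s`, `d`. The
cross-tab has BOR rows CR/PR/SD/PD, slope-class columns, and totals; UE
patients are footnoted, not tabulated. Response rates report both numerator
and denominator: RECIST rate = % with BOR CR/PR, model rate = % with
`d < −c`.

## Two-point comparator

The comparator uses exactly three anchors: the last two scans at `t ≤ 0` and
the first at `t > 0`. `r_g` is the log-slope of the first interval, `r_s` of
the second. No time-shifting is applied to model "baseline treated as
onset": two-point slopes are shift-invariant, and the consequence of the
conflation appears exactly where it belongs — when the baseline scan
precedes onset by `b` months and the first on-treatment scan is at `t₁`, the
on-treatment interval straddles the breakpoint and (noise-free)

    rs_2pt = (r_s·t₁ + r_g·b) / (t₁ + b),

a convex combination of the two true rates, with bias `b·(r_g − r_s)/(t₁+b)`
growing in `b`. The tests verify this closed form against simulation. A
ratio variant `r_s / r_g` is reported, undefined at `r_g = 0`.

## Synthetic cohorts

The generator draws from the model's own data-generating process, so it is
the right instrument for testing estimator correctness, and nothing more:
parameter recovery, classification operating characteristics and pipeline
plumbing. What it emulates: one pre-baseline scan (uniform in (−12, −0.86)
months), one baseline scan (uniform in (−0.80, 0)), six-weekly on-treatment
visits (42 days = 1.3799 months under the fixed calendar), per-phenotype
truncated-normal rate distributions, lognormal residual noise, per-visit
Bernoulli new lesions for progressor phenotypes, and progression-linked
dropout (no scans after the first RECIST-PD visit), which reproduces the
empirical pattern that progressing patients contribute the fewest
on-treatment scans. Truth and observations are written to separate files so
ground truth cannot leak into fitting code.

What it does not emulate — and what passing tests therefore do not show
about real data: real scan-time distributions are right-skewed (uniform
windows are not), readers disagree with themselves (no inter-occasion
measurement-reader model), real tumors need not be exactly exponential on
either side of onset, baseline SLD and growth rate may be correlated, and
new lesions here are exogenous coin flips rather than a function of disease
burden. Model misspecification on real data is not tested here.

Preset scenarios (defaults chosen once as study conditions):

* `trial_like` — 24 % responders (`r_g ~ TN(−0.040, 0.13)` on (−0.427,
  0.133); `r_s ~ TN(−0.454, 0.21)` on (−0.911, −0.143); 1–3 scheduled
  on-treatment scans), 24 % stable (`r_s = r_g` + small jitter), 52 %
  progressors (`r_g ~ TN(0.057, 0.15)`, `r_s ~ TN(0.12, 0.20)`, 15 %
  per-visit new-lesion hazard, up to 12 scans, PD-stopped). Truncation
  bounds are the observed ranges such cohorts report; baseline SLD is
  lognormal (median 60 mm, log-SD 0.5); `σ_res = 0.1` (≈ 10 % measurement
  error, typical for SLD re-reads).
* `tisd` — every patient a growing tumor arrested on treatment
  (`r_g ~ TN(0.20, 0.05)` on (0.08, 0.40), `r_s ~ TN(0, 0.01)`), no new
  lesions, `σ_res = 0.05`, 4–8 post scans: the phenotype the pre-baseline
  scan exists to detect.
* `null` — `r_s = r_g` exactly, so any classified improvement/worsening is
  a false signal; the observed false-signal rate matches the rate the
  per-patient OLS sampling distribution predicts (tested).

## Numerical choices

* Closed-form normal-equations OLS; rank deficiency is declared when the
  condition number of `XᵀX` exceeds 1e10 or the design rank is < 3, and the
  error names the unidentifiable segment. This separates true
  non-identifiability (e.g. both pre-treatment scans at `t ≈ 0`) from
  numerical noise.
* Result CSVs are written with 12 significant digits, so write→read
  round-trips are lossless to well below 1e-9 relative error.
* All simulation randomness flows from one `numpy` Generator seeded
  explicitly; identical seeds give byte-identical cohorts, and the pipeline
  manifest (config hash + SHA-256 of each output, no timestamps) makes
  reruns verifiable.
* Fits that fail for individual patients are collected and reported by the
  cohort fitter rather than aborting the run.

## Problem sizes

The test suite and the reproduction script use cohorts of 20–400 patients
and 100–1000 random refits per property; these sizes make Monte-Carlo
checks stable (standard errors an order of magnitude below the asserted
margins) while a full run stays in the seconds-to-a-minute range.

## Known limitations

* Per-patient OLS with 3–14 points is noisy; standard errors on `r_s` with
  one post-baseline scan are undefined (saturated), and with two they are
  wide. No shrinkage is applied by design.
* The 0.05 month⁻¹ cutoff is a convention, treated strictly as a rate
  threshold; the package does not attempt to justify it.
* A documented arithmetic tension in this literature: a median growth rate
  of 0.022 month⁻¹ corresponds under `T = ln 2 / r` to ≈ 31.5 months, not
  the ≈ 4 months sometimes quoted alongside it; this package always reports
  `ln 2 / r`. (For `r = 0.05134` month⁻¹ the formula gives 13.5 months,
  which is the cross-check used in the tests.)
* UE best overall response arises here only from having no evaluable
  post-baseline assessment; other clinical routes to UE (e.g. off-protocol
  scans) are not modelled.
* The RECIST implementation covers target-lesion SLD and new lesions only —
  no non-target-lesion assessment, nodal short-axis rules, or confirmation
  timing.
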
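# Methods

## Model structure

The package implements a two-stage state-transition (Markov) cohort
model of colorectal-cancer screening outcomes after a positive FIT, with
1-year cycles from age 50 to 100. The clinical core states are: healthy;
undetected adenoma (small <5 mm, medium 6–9 mm, large ≥10 mm);
undetected CRC by stage (I–IV); surgically treated CRC by stage
(recurrence-free); recurrent CRC (early-stage I/II vs advanced III/IV);
and two absorbing death states (CRC vs other causes).

Surveillance scheduling is encoded by crossing the watchful core states
with a *tunnel* clock — an integer count of years until the next
scheduled test, together with the test type (FIT or colonoscopy). This
keeps the whole model a finite Markov chain (184 states): the one-cycle
operator is an explicit row-stochastic matrix, testable by matrix
algebra, and the exact same operator drives both the deterministic
cohort run and the patient-level microsimulation used as its oracle.

One cycle is the composition of four stages in a fixed order:

1. **Scheduled tests** (clock = 0). A colonoscopy detects each lesion
   class with probability one minus the arm's miss rate; detected
   adenomas are resected (polypectomy) and the patient returns to the
   healthy state with the findings-appropriate surveillance clock
   (5 years for small/medium, 3 years for large findings); detected
   cancers move to the treated states (surgery for I–III, plus adjuvant
   chemotherapy for III; systemic chemotherapy for IV). A follow-up FIT
   costs the FIT fee and, when a lesion is present, triggers a
   diagnostic colonoscopy with probability `fit_sensitivity` (default
   0.75; no source states a value). A negative FIT returns the patient
   to routine biennial programme FIT.
2. **Death**: the background life-table probability `qx` applies to
   every alive state; CRC mortality applies on top of it to undetected
   CRC and treated stage IV (stage-group "no recurrence" rates) and to
   the recurrence states ("post recurrence" rates), by half-open age
   band [50,65), [65,75), [75,∞).
3. **Progression** among survivors: adenoma onset (age-interpolated),
   size growth, CRC stage progression, clinical presentation of
   undetected CRC, and post-surgical recurrence. Entry to stage IV by
   progression is costed with one systemic-chemotherapy course.
4. **Clock decrement.**

Death before progression is a documented convention; at 1-year cycles
any fixed order is defensible.

### Index event and missed lesions

Every cohort member receives a colonoscopy at cycle 0 — that event
defines the FIT-positive cohort — and the positive index FIT is costed
once at entry. A missed *adenoma* is scheduled for the 5-year
surveillance colonoscopy: in a FIT-positive cohort a missed polyp
typically coexists with detected lesions, so the patient is under
surveillance and the missed polyp surfaces at a follow-up examination
(the package models one worst lesion per patient, so multiplicity enters
only through this routing). A missed *cancer* leaves the examination
formally negative (FIT in 10 years), but can present clinically in any
cycle (below).

### Clinical presentation of undetected CRC

Undetected cancer does not wait for the next scheduled test: each cycle
it presents symptomatically with a stage-dependent annual probability —
0.20 (I), 0.40 (II), 0.70 (III), 0.90 (IV) — and is then diagnosed
(diagnostic colonoscopy, device fee in the CADe arm) and treated. No
source prints these probabilities; they are documented model constants,
rising with stage in line with the short pre-clinical sojourn of
advanced disease. Without this pathway missed cancers linger up to ten
years, which roughly doubles the between-arm differences and materially
overstates the detection benefit.

## Detection parameters

Conventional colonoscopy misses small/medium/large adenomas at
31%/19%/9% (95% CIs 25–38 / 12–28 / 4–16). The CRC I/II miss rate is the
large-adenoma rate reduced by a configurable factor (default 50%, giving
4.50%); stages III/IV are assumed always seen at colonoscopy.

The CADe arm defaults to the tabulated AI-aided miss rates —
17.26%/8.28%/7.60% (`DIRECT_TABLE`) — with the CRC I/II miss obtained by
dividing the conventional 4.5% by the per-patient CRC detection-rate
ratio 3.36. The published narrative derivation ("miss rate times the
incidence-rate ratio") does not reproduce those tabulated values
exactly, so an alternative `IRR_DERIVED` mode (conventional miss ÷ IRR)
is exposed; the tabulated, self-consistent numbers are the default.

In the sensitivity analyses the CADe effect must respond to the IRR:
perturbing an IRR scales the direct miss rate by (baseline IRR /
perturbed IRR), clamped to [0, 1]. At the baseline IRR this reproduces
the tabulated rates exactly, so a zero-variance PSA collapses onto the
base case; IRR = 1 is the null effect (CADe miss = direct rate ×
baseline IRR ≤ conventional miss).

## Economics

Costs (2022 CAD) enter through two channels:

- **Event costs** at occurrence: FIT $31.11, colonoscopy $688.00,
  polypectomy $413.00, CRC surgery $12,082.00 (stages I–III), adjuvant
  chemotherapy $9,637.00 (stage III), first systemic-chemotherapy course
  $11,442.00 (stage IV entry).
- **Annual disease-management costs** by state occupancy: post-surgical
  follow-up while recurrence-free ($306.00/year for stage I,
  $1,427.85/year for stages II–III); systemic chemotherapy each year in
  treated stage IV and advanced recurrence; the intensive follow-up
  bundle in early-stage recurrence (salvage rather than continuous
  palliative therapy).

The split between one-off and ongoing costs is not stated by the source
tables (both follow-up rows are described as one-year bundles); the
attachment above is the clinically standard reading and reproduces the
published per-case cost levels, whereas a strictly one-off reading
underestimates both arms by roughly $700 and reverses the sign of the
cost increment.

The CADe device is a $2,250 monthly subscription; amortised over 1,000
colonoscopies/year this is $27 per procedure, applied to *every*
colonoscopy in the CADe arm (index, surveillance and diagnostic). The
3-year contract corresponds to an $81,000 acquisition cost. Costs and
outcomes are discounted at 3.5%/year, cycle 0 undiscounted.

## Accrual conventions

Life years and QALYs accrue per cycle from state occupancy with a
half-cycle correction by default (the average of start- and end-of-cycle
occupancy; without the correction, end-of-cycle occupancy is used, so a
cohort wiped out in its first year accrues 0.5 vs 0 LY). Utility
weights: healthy 0.90, any adenoma 0.91, CRC I/II 0.67 (undetected,
treated or recurrent early-stage), CRC III 0.59, CRC IV and both
recurrence states 0.25. Event costs are not half-cycle corrected.

## Calibrated constants

Two inputs are not printed anywhere and are calibrated once, openly:

- **Background life table.** A Gompertz–Makeham hazard
  h(x) = 1.2×10⁻³ + 6.048×10⁻⁶·exp(0.11·x), tabulated as
  qx = 1 − exp(−h(x)) for ages 50–110. The scale was bisected so the
  conventional arm's discounted life expectancy from age 50 equals the
  published 19.125 years; the slope 0.11/year gives realistic old-age
  mortality (qx(100) ≈ 0.31) so the cohort is effectively extinct by the
  age-100 horizon (extending to 110 changes results by <0.1%). Any
  national life table can be substituted as a two-column CSV.
- **Healthy-state utility 0.90**, consistent with general-population
  utility norms at ages 50+; the published QALY/LY ratio (≈0.895)
  implies the source did not use 1.0.

## Sensitivity analyses

**Deterministic (tornado).** Each parameter with a published range is
set to its low and high bound, all else at base: effect-measure and
transition CIs; utilities' CIs; costs from −15% (computed) to the
printed +15% bound; the device fee at ±15%; the onset curve shifted
knot-wise to its CI bounds. The outcome is incremental NMB at
$50,000/QALY (ICER spreads are undefined across dominance quadrants);
rows are sorted by spread. Ranges violating a type invariant are skipped
with a logged warning.

**Probabilistic.** 1,000 independent parameter draws (one uniform per
parameter in fixed order, so runs pair draw-by-draw across scenarios at
the same seed):

- probabilities and utilities: Beta, moment-matched to the printed mean
  and 95% CI ((hi − lo)/3.92 as the SD);
- costs: Gamma with the ±15% range read as a 95% interval;
- rate ratios: Lognormal with median at the point estimate and log-width
  from the CI (the fitted 2.5%/97.5% quantiles reproduce the printed
  bounds within 2%).

Parameters are drawn independently (no correlation information exists).
The detection-improving scenario truncates the IRR distributions at 1
via inverse-CDF restriction on the same uniforms, so it removes only
unfavourable draws and its acceptability is never below the full-CI
scenario's at the same seed. Acceptability at threshold w is the
fraction of draws with w·ΔQALY − ΔCost > 0; the CEAC is evaluated on a
$0–$100,000 grid in $5,000 steps.

## Validation oracles

- A 3-state reduced configuration (healthy / undetected small adenoma /
  death) matches a hand-written closed-form recursion to 10⁻¹².
- A vectorised microsimulation samples patient trajectories from the
  exact cohort operators; cohort and microsimulation means agree within
  3 standard errors at n = 50,000 for LY, QALYs and cost.
- Discounting matches the geometric-series closed form; transition rows
  sum to 1 within 10⁻¹²; cohort mass is conserved within 10⁻⁹ over the
  lifetime; a zero-variance PSA reproduces the deterministic comparison.

## What the synthetic data does and does not emulate

The synthetic life table and the trajectory sampler emulate the model's
own stochastic structure — they make every stage testable without any
external download, and parameter-recovery tests confirm the sampler
reproduces the configured transition probabilities. They do not add
real-world features the model itself omits: no per-endoscopist
detection heterogeneity, no polyp multiplicity beyond the high-/low-risk
routing, no colonoscopy complications, no sex-stratified mortality
(the cohort's 54.5% male fraction is carried but unused unless a
sex-specific life table is supplied), and no FIT false positives.
Passing tests therefore demonstrate internal consistency and faithful
reproduction of the published analysis, not predictive validity for any
real screening programme.

## Problem sizes

The default analysis runs a 184-state cohort for 50 cycles per arm
(milliseconds); the PSA reruns both arms 1,000 times per scenario
(~20 s per scenario on one CPU); microsimulation oracles use
n = 50,000 patients. These sizes are the study's own: nothing is scaled
down from the published design.

## Known limitations

- The model tracks one (worst) lesion per patient; multiplicity enters
  only through surveillance routing.
- Treated early-stage CRC carries its stage utility for life; models
  that return long-term survivors to population utility would show a
  larger QALY gain per averted cancer.
- The clinical-presentation probabilities and the two calibrated
  constants above are model choices, not published data; all are
  exposed in the configuration and can be overridden.
- The printed P-values accompanying the published LY/QALY results have
  no reproducible derivation and are out of scope, as is any
  budget-impact or multi-strategy frontier analysis.
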
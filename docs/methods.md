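# Methods

## Estimation model

The pipeline estimates penetrance of endometrial (EC) and ovarian (OC) cancer
in female mismatch-repair-variant heterozygotes from prospective follow-up
records, one row per woman: gene, inclusion age (25–74 y), last-observation
age (≥1 y after inclusion), optional ages of hysterectomy, bilateral
salpingo-oophorectomy (BSO), EC/OC diagnosis, and death.

**Person-years and annual incidence rates.** For each gene × endpoint, a
woman's at-risk interval runs from `max(inclusion, 25)` to the earliest of
last observation, removal of the organ at risk (hysterectomy for EC, BSO for
OC), diagnosis, or age 75. A cancer diagnosed at or before inclusion is a
*previous* cancer: the record contributes no time and no event for that
endpoint (it still contributes to the other endpoint). The exact fractional
overlap of the interval with each half-open 5-year bin [s, s+5), s = 25…70,
is accumulated at 0.01-year resolution; the event is counted once, in the bin
containing the diagnosis age. A diagnosis at the same age as surgery counts
as an event followed by censoring, the registry convention for occult cancers
found at risk-reducing surgery. The annual incidence rate (AIR) of a bin is
events / person-years; bins under 10 person-years (configurable) are flagged
unreliable, and a bin with no person-years has an undefined AIR that
downstream stages treat as zero with an explicit warning in the curve
metadata. Exact Poisson (Garwood) intervals from chi-square quantiles are
provided as plumbing; they are not a registry-calibrated uncertainty model.

**Combined endpoint.** For EC-and/or-OC, a woman stays in the risk set while
at least one organ is intact (`combined_censoring="both-organs"`, default);
hysterectomy alone reduces her to ovarian risk but does not censor her. The
alternative `"any-surgery"` mode censors at the first organ removal; both are
exposed because registry practice is ambiguous on this point.

**Cumulative incidence.** Incidence is assumed zero before 25. With AIR
constant within each 5-year bin, cumulative incidence follows the annual
recursion `Q(age) = Q(age−1) + [1 − Q(age−1)]·AIR(age)`, `Q(25)=0`, on the
integer grid 25…75. The recursion is algebraically `1 − ∏(1 − AIR)` and the
two forms must agree to 1e−12 (property-tested). No smoothing or
interpolation between bins. The conditional interval risk for a woman
cancer-free with the organ intact at age a is
`(Q(b) − Q(a)) / (1 − Q(a))`; consecutive interval risks compose as
`1 − (1−p_ab)(1−p_bc)`, exactly on unrounded values.

**Survival.** Crude survival after diagnosis is the Kaplan–Meier
product-limit estimate from diagnosis to death or last observation, with
*all-cause* death as the event (that is what "crude" means here); a flag
restricts events to deaths attributed to the followed cancer for sensitivity
analysis. Survival is pooled across genes and diagnosis ages — per-gene and
per-age case counts in registries of this size are too small for stratified
curves — and evaluated at 10 years as a right-continuous step function
(carry-forward with a warning beyond the last observed time). Deaths tied
with censorings are processed first, the standard convention. The estimator
is `lifelines.KaplanMeierFitter`; tests verify it against a hand-computed
product-limit example and against empirical survival on censoring-free
inputs.

**Combined survival interpolation.** EC survival exceeds OC survival by a
fixed difference (89 % vs 84 % at 10 years in the calibration, difference
5 points, taken as age-constant). For an age interval, the endometrial share
of combined risk is `EC_fraction = EC_risk / (EC_risk + OC_risk)` on
unrounded risks, and the combined survival is
`S_OC + (S_EC − S_OC) · EC_fraction`, which is necessarily between the two
endpoint survivals (asserted).

**Tables and surgery benefit.** The standard table layout has nine age
intervals (25–40/50/60/70; 40–70, 50–70, 60–70; 40–50, 50–60). Each cell's
death risk is `risk × (1 − survival₁₀)` computed on unrounded values;
whole-percent rounding (half away from zero) is applied only at render time —
required for the combined table's survival cells to round consistently. When
EC and OC risks are both zero in an interval, the survival cell is empty (no
risk to survive) and the death risk is zero. The benefit of risk-reducing
surgery at age a over horizon b is counterfactual: cancers prevented equal
the interval risk the woman would otherwise face, deaths prevented are that
times `(1 − survival₁₀)`; no surgical-complication or hormone-replacement
disutility is modelled. When no combined-endpoint curve is available the
combined risk falls back to the independence form `1 − (1−EC)(1−OC)`, and the
table records which rows used the fallback.

## Synthetic cohort generator

The raw registry data are not public, so the generator emulates the record
structure with a known generating process, making every estimator testable by
parameter recovery.

**Event process.** Discrete annual Bernoulli draws from piecewise-constant
hazards — deliberately the exact inverse of the annual recursion, so the
closed-form oracle `analytic_interval_risk = 1 − ∏(1 − h(t))` is exact rather
than a continuous-time approximation. Partial-year exposure f uses
`1 − (1−h)^f`. Events are placed at the end of the exposed year (minus the
0.01-y resolution step) so that estimated AIRs are unbiased for the
generating hazards. EC and OC are independent given the gene (no joint model
is published); the first gynecological cancer is treated surgically, which
removes both organs from subsequent risk — the generator records the
therapeutic surgery ages so downstream censoring sees it. Prophylactic
surgery is drawn per-year from bin-specific uptake and removes uterus and
ovaries together by default (`hysterectomy_only` flag available, since
oophorectomy type is typically not in the data call).

**Hazard calibration.** Default hazards anchor the published cumulative
risks Q(40), Q(50), Q(60), Q(70) per gene × endpoint exactly: within each
segment [25,40), [40,50), [50,60), [60,70) the constant annual hazard solves
`(1−h)^k = (1−Q_b)/(1−Q_a)`. The [70,75) bin reuses the [60,70) hazard (the
published tables stop at 70; annual incidence remains high at older ages).
Because the published values are rounded whole percents, the implied
conditional rows reproduce within rounding except two cells that the source's
own rounding makes internally inconsistent (MLH1 EC 50–60: 14 % vs printed
15 %; MSH2 OC 40–70: 15 % vs printed 16 %). PMS2 has zero hazard below 50
for both endpoints (no demonstrable premenopausal risk). The published PMS2
ovarian death-risk cells are not reproducible from `risk × (1 − survival)`
(apparent typesetting inconsistency in the source table); the implementation
follows the formula and does not special-case them.

**Post-diagnosis survival.** A cure mixture: with probability c the woman
never dies of the cancer within follow-up; otherwise the death time is
exponential with scale 3 y (deaths concentrate early, then the curve
flattens, as observed for these cancers). c is solved so the model's 10-year
survival equals the target: `c + (1−c)e^(−10/scale) = S₁₀`, default S₁₀ =
0.89 (EC) and 0.84 (OC). A death simulated inside the first follow-up year
is moved to inclusion + 1 y (rare) so every emitted record satisfies the
≥1-year-follow-up inclusion rule. Background (non-cancer) mortality is off
by default — crude survival in the real registry includes it, so a
`background_mortality` annual rate is available for sensitivity runs.

**Cohort composition.** Inclusion ages are drawn from a categorical
distribution over 5-year bins weighted toward younger women (0.14 at 25–29
declining to 0.05 at 70–74), uniform within bin, capped at 74. Total
follow-up is 1 y plus an exponential with mean 6 y truncated at 24 y (mean
≈ 7 y, maximum 25 y). Default cohort sizes divide the registry's published
female observation years (7838 / 5487 / 1614 / 862 for
MLH1 / MSH2 / MSH6 / PMS2) by the 7-year mean follow-up: 1120 / 784 / 231 /
123 women. Annual prophylactic-surgery uptake defaults to 0.005 below 40 and
0.02 from 40, reflecting uptake concentrated after the recommended age
window.

**What the generator does not emulate.** Family-based ascertainment,
genotype misclassification, time trends in surgery uptake, inter-centre
heterogeneity, competing mortality (by default) and any EC–OC dependence
beyond first-event treatment. Passing recovery tests therefore shows the
estimators invert this generating process at scale — not that the published
point estimates are unbiased for the real registry.

## Numerical and design choices

- Ages at 0.01-y resolution; bins half-open [s, s+5); an event at exactly
  75 is out of range; an event at the last-observation age is valid (event,
  then immediate censoring).
- All table arithmetic on unrounded floats; rounding half away from zero at
  render only.
- Validation is total: every CSV row is accepted or rejected with a
  machine-readable reason code; strict mode turns any rejection fatal. A
  cancer age at or before inclusion is a *flag*, not a rejection.
- The pipeline (`lynchrrs run`) is deterministic for a fixed config and
  seed: the manifest hashes are reproducible end to end. Table survival
  columns use the pooled Kaplan–Meier estimate when at least 20 cases are
  available, otherwise the configured targets (logged either way).
- Test and demo problem sizes (cohorts of 2 000–100 000 women, ≥2 000
  simulated cases for survival recovery) are chosen so binomial sampling
  error is well below the tolerances being checked while the full suite runs
  in seconds.

## Limitations

Confidence intervals on cumulative incidence and on the tables are not
produced (the registry's published CI method for these quantities is not
reproducible from the available description; the Poisson rate CI is
plumbing, a bootstrap is future work). Competing-risk (Aalen–Johansen)
estimation is deliberately out of scope — simple censoring matches the
source methodology. Survival pooling across genes is an assumption known to
be weakly supported for MSH6/PMS2, where case counts are very small.
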
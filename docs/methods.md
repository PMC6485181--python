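# Methods

`cfrecruit` implements the statistical design of a multicenter
observational study of sputum inflammatory biomarkers in cystic fibrosis
(CF): who gets approached for enrollment and how that stays random, what
counts as the primary clinical event, how many patients are needed, whether
the enrolled cohort represents its reference population, and how specimens
are processed and shipped without losing material. Everything runs on
synthetic data, so every claim below is mechanically checkable.

## Randomized letter selection

Each potentially eligible patient is pre-assigned an i.i.d. uniform letter
of the alphabet within their recruitment block (one adult and one pediatric
block per center). A patient may be approached at a clinic visit only if
their letter is *strictly earlier* than the block's threshold letter.
Because the letter is assigned before any clinic contact and carries no
information about the patient, inclusion is concealment-preserving: staff
cannot select patients by their characteristics.

We parameterize the threshold as `k`, the number of flagged letters
(`k = 0` none, `k = 26` all); a letter with index `ell` (0 = 'A') is
flagged iff `ell < k`. The threshold letter itself is never flagged —
"earlier than" is strict. Letters are drawn with replacement; collisions
are harmless because the flag rule depends only on each patient's own
letter.

**Planning arithmetic.** The initial threshold is the smallest `k` with

```
(k / 26) · N · c · s ≥ T
```

where `N` is the block pool, `c` the planning consent rate (default 0.53),
`s` the planning show rate (default 0.90, i.e. a 10% no-show rate), and `T`
the block's enrollment target. If even `k = 26` falls short, the result
carries an insufficient-pool flag rather than raising.

**Adaptive speed control.** Thresholds are reviewed at the end of study
month 1 and quarterly from month 3. At each review the controller
re-estimates consent and show rates from the observed trace, shrunk toward
the planning values with a weight of 10 pseudo-observations (small-count
stabilization; the source design names no formula, so this is our choice),
and recomputes the smallest adequate `k` from the remaining pool and
remaining target. Three numerical choices matter:

- *Opportunity-weighted pro-rata benchmark.* With periodic clinic visits,
  most patients are first seen within one visit interval, so the expected
  enrollment trajectory is concave in calendar time. Enrollment speed is
  therefore judged against the expected fraction of recruitment
  opportunities elapsed (offset-averaged probability of having shown at
  least once), not against calendar time, which would misread the natural
  early surge as excessive speed.
- *Hold band.* Within ±5% of the pro-rata target the threshold is held.
- *Asymmetric steps.* When ahead, the threshold moves exactly one letter
  earlier per review: enrollment already granted cannot be revoked, so
  braking gently is sufficient and avoids oscillation. When behind, the
  threshold jumps to the recomputed `k` but by at most two letters per
  review, because each newly flagged letter releases a backlog of patients
  at once.

A threshold change never alters a past decision; enrolled patients stay
enrolled, and patients not yet approached are re-evaluated against the new
`k` at their next visit. Under simulation (pool 1000, target 150, true
consent 0.40 against a planned 0.53), final enrollment lands within ±15%
of target in well over 90% of studies.

**Integrity checking.** Two diagnostics: (a) *replay* — every flag
decision in the trace is recomputed from the letter table and the threshold
history; any mismatch means inclusion depended on something else; (b)
*exchangeability* — a permutation test per covariate that flagged and
unflagged patients differ no more than chance. Under a correct
randomization the permutation p-values are uniform; the check fails only
below α = 0.001 to keep the false-alarm rate negligible across covariates.

## Pulmonary exacerbation rule engine

The primary clinical event is defined by co-occurrence: at least one
symptom from a fixed nine-item list (increased sputum, cough, dyspnea,
chest pain or tightness, hemoptysis, fever, chills, arthralgias, fatigue)
together with at least one objective sign; respiratory failure requiring
mechanical ventilation qualifies regardless; the site PI may override
borderline cases. The sign criteria and boundary conventions:

| criterion | rule | boundary |
|---|---|---|
| lung function | FEV₁ or FVC drop ≥10% of baseline | ≥ (exactly 10% counts) |
| fever | temperature > 38.4 °C | strict (38.4 does not count) |
| hemoptysis | witnessed > 100 ml/episode | strict |
| hypoxemia | SaO₂ < 90% or PaO₂ < 60 mmHg despite usual oxygen | strict |
| adolescent desaturation | SaO₂ drop ≥5 points from baseline, age 12–<18 | ≥ |
| oxygen need | increased supplemental-oxygen requirement | boolean input |
| weight | unplanned loss ≥5% of baseline over ≤3 months (93 days) | ≥ |

The 10% lung-function drop is interpreted *relative to baseline* (the
convention in CF exacerbation criteria), with an absolute-percentage-point
switch exposed for sensitivity analyses. "Mild exacerbation" — a state
the design names but does not define — is operationalized as symptoms
without signs or signs without symptoms: deterministic, and monotone (adding
a criterion never demotes a verdict). A PI `force_not` override is final
(PI discretion outranks the automatic rule) and downgrades to mild when any
criterion is present. Criteria with missing inputs are reported as
unevaluated rather than silently treated as absent. Clinical stability is
the absence of an exacerbation; by default a mild call also blocks
enrollment and is flagged for PI adjudication (configurable). The
classifier is verified against an independently coded truth table over the
exhaustive presence/absence sweep.

Sample-collection scheduling: enrollment sample at day 0; within 48 h of
the first exacerbation onset (end-exclusive at +48:00); a convalescent
sample 4–12 weeks (28–84 days) after onset; additional windows for later
events; a final end-of-study sample.

## Bootstrap power and sample size

For a biomarker endpoint, power at sample size `n` is estimated by drawing
`n` patients with replacement from a pilot dataset, refitting the model
(proportional hazards for time-to-event, least squares for continuous
outcomes), and recording significance of the biomarker coefficient by a
two-sided Wald test at level α (the design states α levels without a test
type; two-sided Wald is standard and matches the closed forms). Power is
the significant fraction of B replicates, with Monte-Carlo SE
`sqrt(p(1−p)/B)`; degenerate resamples (no events, constant biomarker,
non-convergence) are redrawn with a 10·B attempt cap. The grid search
reports the smallest `n` reaching the target, confirmed at the next grid
point before stopping early.

The independent oracle is the Schoenfeld requirement for a
proportional-hazards covariate,

```
events = ceil( (z₁₋α/2 + z_power)² / (β² σₓ²) )
```

(60 events at β = 0.5/SD, α = 0.01, power 0.90; 32 at α = 0.05, power
0.80), and its linear-regression analogue with `σ²_resid/(slope² σₓ²)` and
a +2 degrees-of-freedom allowance. With uncensored exponential pilots the
patient count equals the event count, so the bootstrap minimal-`n` can be
compared to the closed form directly; agreement within one grid step is
the standing check. Pilot datasets of 2,000 subjects keep the pilot's own
estimation error (SE(β̂) ≈ 0.022) small relative to a grid step. Model
fits use `lifelines` (Cox) and `scipy.stats.linregress` (OLS); the
bootstrap machinery, search and oracles are this package's own.

## Cohort representativeness and seasonal effects

Characteristic-by-characteristic comparison of the enrolled cohort against
a reference population: Pearson χ² on the 2×2 table (df = 1, no continuity
correction — documented, matching the textbook closed form) for binary
characteristics, Welch two-sample t for continuous ones, and quasi-Poisson
regression (Poisson GLM with Pearson-χ²-estimated dispersion) on a cohort
indicator for counts. An adjusted mode replaces each two-sample test with
a pooled regression of the characteristic on the cohort indicator plus age
and sex, since registry-style comparisons are usually reported adjusted;
with individual-level reference data unavailable outside simulation, the
unadjusted tests are the defaults. Null calibration is checked by drawing
cohorts of 114 from a synthetic reference of 14,394 and comparing each
cohort against its complement (comparing against a superset containing the
cohort itself would break independence under the null).

Seasonal effects: season from the enrollment date (meteorological:
Dec–Feb Winter, Mar–May Spring, Jun–Aug Summer, Sep–Nov Fall), one
regression per characteristic with Summer as the reference season, model
family matched to the characteristic type, and Bonferroni correction at
α/m across the m characteristics tested. A constant characteristic yields
exact zero contrasts without fitting (the GLM deviance is degenerate
there). On a noiseless +8.7-year Fall age shift the Fall coefficient is
recovered exactly.

Shipping controls: ordinary least squares of the shipped measurement on
the paired immediate measurement, plus per-pair elevation factors
(shipped/immediate, undefined and excluded with a warning for non-positive
immediate values). The mean factor carries a normal-approximation 95%
interval built from the factor SD (a population-style interval, matching
the reporting convention of the motivating analyses) and clipped below at
zero; the maximum factor is reported alongside.

## Biospecimen workflow

Timing: collection ≤20 min; ≤1 h from collection start to processing
initiation; ≤3 h initiation-to-completion (the protocol's "1–3 h" lower
bound is descriptive, not enforced). Fractionation after centrifugation
(20 min, 2800 g, 4 °C): lipid layer L, aqueous halves SA (1:1 buffer) and
SB (1:1 protease inhibitor), pellet P; default aliquot plan 1 L + 2 SA +
2 SB + 1 P (the protocol says "aliquots" without counts). Labels render as
`<ID>_<YYYYMMDD>_<FRACTION>_<sample#>_<aliquot#>` — the protocol lists the
components, the format is ours — and parse back exactly.

Split-batch shipping fills the currently smallest shipments first, cycling
within each sample's aliquots, so every sample with ≥2 aliquots spans ≥2
shipments: no single shipping failure can destroy all material from any
sample. Single-aliquot samples are flagged with a warning (the invariant
is unsatisfiable, not an error). Cytology QC: oral contamination at ≥5
squamous epithelial cells per low-power field; counting adequacy "low"
below 200 cells; the differential must sum to 1 within 1e-9.

## Synthetic populations

The generator emulates the marginals of a sputum-producing CF cohort: age
~ N(27, 12) truncated at 12 years, split into pediatric [12, 18) and adult
[18, ∞) blocks; FEV₁ percent predicted ~ N(80, 23) truncated to (0, 150];
male fraction 0.46; prior-year exacerbation counts negative binomial with
mean 1.0 and SD 1.2 (the reported moments are overdispersed relative to
Poisson); airway-infection prevalences at the published cohort fractions;
nine centers with pools of 77 adults and 17 children each (≈696 + 154
eligibles). Truncated sampling is by rejection — exact, and cheap at
these scales. Two published summaries of home elevation disagree
(328 ± 112 m vs 1305 ± 442 m); both are exposed as presets
(`ELEVATION_VALLEY`, the default, and `ELEVATION_MOUNTAIN`) and the
package takes no position on which is correct.

Visit streams are quarterly (91-day interval) with ±7-day jitter and
independent 10% no-shows; exacerbation processes are homogeneous Poisson;
pilot time-to-event data are exponential with hazard `exp(β·x)` for a
standard-normal biomarker, with administrative censoring at a horizon
solved numerically to hit the requested expected censored fraction; paired
shipping measurements are `shipped = slope·immediate + intercept + noise`
with positive truncated-normal immediate values. Every generator takes one
seed and is byte-reproducible.

What the generator does *not* emulate: disease progression, correlation
between covariates, center-level heterogeneity, seasonal case mix,
informative no-shows, or geography. Passing tests therefore demonstrate
that the *machinery* is correct under the stated study conditions, not
that any real cohort is representative.

## Problem sizes and reproducibility

Default check sizes: 10,000 patients for marginal-fidelity and
flagged-fraction laws; 1,000 null studies (200 patients, 499 permutations)
for exchangeability; 200 simulated studies of 1,000-patient pools for the
controller; B = 500 bootstrap replicates on 2,000-subject pilots for the
power engine; 1,000 null cohort draws (114 from 14,394) for type-I
calibration. These sizes give Monte-Carlo standard errors comfortably
inside every tolerance asserted. All randomness flows through
`numpy.random.default_rng` seeds passed explicitly; no global state.

## Known limitations

- The controller's remaining-pool arithmetic treats the letters of
  not-yet-approached patients as uniform, which understates early-letter
  depletion late in a study; the bounded step sizes compensate in
  practice.
- Quasi-Poisson inference uses Wald z statistics; for very small cohorts a
  likelihood-ratio test would be preferable.
- The exacerbation engine evaluates single encounters; it does not merge
  consecutive encounters into episodes.
- Bootstrap power inherits the pilot's sampling error; requirements from
  small pilots should be read as estimates with that extra variance.
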
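# cfrecruit

A toolkit and simulator for the statistical design of multicenter
observational biomarker studies in cystic fibrosis (CF). It is written for
biostatisticians and study designers who want the machinery of a
randomized-recruitment observational study — not just a description of it —
in testable, replayable form:

- **Concealment-preserving random-letter selection.** Every potentially
  eligible patient is pre-assigned a uniform random letter within their
  center's adult or pediatric block; only patients whose letter falls
  strictly earlier in the alphabet than the block's threshold letter may be
  approached at clinic. Inclusion depends on nothing but the pre-assigned
  letter, so clinic staff cannot select patients by their characteristics.
  The initial threshold index `k` (number of flagged letters) is the
  smallest `k` with `(k/26)·N·c·s ≥ target` for pool `N`, consent rate `c`
  (default 0.53) and show rate `s` (default 0.90).
- **Adaptive enrollment-speed control.** At scheduled reviews (end of
  month 1, then quarterly) the threshold moves earlier in the alphabet when
  enrollment runs ahead of its pro-rata target and later when it lags,
  without ever revoking a past decision — the scheme stays a randomization,
  and an integrity checker replays every decision to prove it.
- **A rule-based pulmonary-exacerbation definition** (≥1 symptom plus ≥1
  objective sign; mechanical ventilation qualifies regardless; PI override
  for borderline cases), with a "mild" category for instability short of
  the full definition, plus protocol sample-collection windows (48 h
  exacerbation, 4–12 week convalescent).
- **Bootstrap power / sample-size estimation** for proportional-hazards and
  linear-regression biomarker endpoints, checked against the Schoenfeld
  closed form `events = ceil((z₁₋α/2 + z_power)²/(β²σₓ²))`.
- **Cohort representativeness and seasonal-bias statistics** (χ², Welch t,
  quasi-Poisson; seasonal regressions against a Summer reference with
  Bonferroni correction) and the paired immediate-vs-shipped biomarker
  analysis.
- **Biospecimen workflow QC**: processing-timing rules, L/SA/SB/P fraction
  labeling, split-batch shipping (no single shipment may hold every aliquot
  of a sample), and cytology QC thresholds.
- **A synthetic-population module** generating CF-like multicenter cohorts
  (age ~ N(27, 12) truncated at 12+, FEV₁% ~ N(80, 23), 46% male,
  overdispersed exacerbation counts, published infection prevalences),
  visit streams with 10% no-shows, pilot biomarker datasets and shipping
  pairs, so everything above runs without access to any registry.

See `docs/methods.md` for the models, assumptions, numerical choices and
limitations.

## Worked example

```python
from datetime import date
from cfrecruit import synth_population as sp, randomization as rz

# a 9-center eligible pool at realistic scale (~696 adults, ~154 children)
pats = sp.generate_population(sp.PopulationConfig(seed=1))
letters = rz.assign_letters(pats, seed=3)
visits = sp.generate_visits(pats, horizon_days=365, no_show_rate=0.10,
                            seed=2, start_date=date(2015, 1, 1))

# initial thresholds from the planning arithmetic
dec = rz.required_threshold(pool_size=100, target_enrollment=20,
                            consent_rate=0.53, show_rate=0.90)
print(dec.k, dec.threshold_letter)
```

```
11 L
```

Eleven flagged letters (A–K): a pool of 100 with a 53% consent rate and a
10% no-show rate is expected to yield `(11/26)·100·0.53·0.90 ≈ 20.2`
enrollments, so the threshold letter is L and patients lettered A–K may be
approached. Running the full enrollment simulation and integrity check
(one `ThresholdState` per block from the same planning arithmetic, total
target 114 split across blocks by pool size):

```python
states = {}
for bk, pool in letters.groupby("block_key").size().items():
    t = 114 * pool / len(pats)
    d = rz.required_threshold(int(pool), t, 0.53, 0.90)
    states[bk] = rz.ThresholdState(
        block_key=bk, k=d.k, effective_from=date(2015, 1, 1),
        pool_size=int(pool), target_total=int(round(t)),
        target_remaining=int(round(t)),
        study_start=date(2015, 1, 1), study_end=date(2016, 1, 1))

trace, history = rz.simulate_enrollment(pats, letters, visits, states,
                                        consent_rate_true=0.53, seed=4)
report = rz.check_randomization_integrity(trace, letters, history, pats)
print(trace["enrolled"].sum(), report.n_mismatches, report.passed)
```

```
133 0 True
```

133 patients enrolled against a target of 114; zero replay mismatches means
every approach decision is reproducible from the letter table and the
threshold history alone, and the balance p-values confirm flagged and
unflagged patients are exchangeable on age, lung function and exacerbation
history.

The same workflow is available from a shell:

```bash
cfrecruit synth --seed 1 --out-dir data/
cfrecruit recruit --patients data/patients.csv --visits data/visits.csv \
    --target 114 --seed 2 --out trace.csv
cfrecruit power --pilot data/pilot.csv --model coxph --alpha 0.01 \
    --power 0.9 --grid 20:100:20 --reps 500 --seed 3
cfrecruit shipqc --pairs data/pairs.csv
```

The last command prints, for a simulated set of seven shipping-control
pairs (generated noiselessly from slope 1.15 and intercept 5.19, so the
regression recovers both and the per-pair elevation factors
`shipped/immediate` vary only with the immediate level):

```
n=7: coefficient = 1.15, intercept = 5.19, p = 1.92e-50; mean elevation factor 1.59 (95% CI 0.7-2.5), max 2.6
```

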
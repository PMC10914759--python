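# Methods

This note documents the models, estimators and numerical choices behind the
package, in the spirit of a statistical software appendix. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## The assay and what is simulated

The system under study is an 18-sensor panel of activity-based protease
biosensors (BM01–BM15, BM17–BM19): graphene particles carrying
peptide–TCPP conjugates whose fluorescence is quenched until an active
serum protease cleaves the tether. A serum sample incubated with the panel
on a 384-well plate yields, per sensor and per 10-minute read from 10 to
60 minutes, a fluorescence value that a BM19 peptide–TCPP standard curve
converts to released reporter concentration (ng/ml). One assay therefore
produces 18 × 6 = 108 `sensor_time` features (e.g. `BM01_40`).

The synthetic generator (`leap.synthetic`) emulates the study design on
which the analysis pipeline is meant to operate:

- **Cohort.** 450 donors, 132 with pathologically confirmed lung cancer,
  with site (KUMC 84 / Marmara 235 / Vejle 131), sex (282/168), age-band,
  smoking, stage and histology margins quota-sampled exactly (largest-
  remainder apportionment followed by a seeded shuffle). Quota sampling —
  rather than independent multinomial draws — makes the configured integer
  counts exact, so design-count tests are deterministic. Attributes are
  assigned independently of one another, so joint structure beyond the
  margins (e.g. site × smoking correlation) is not emulated.
- **Replication.** A 150-donor subset, apportioned over the site ×
  diagnosis cells proportionally to their size, is assayed in triplicate:
  750 assays in total.
- **Signal.** True released concentration follows saturating kinetics
  `A_s · t/(t + K_s)`, scaled by `(1 − δ_s)` for cancer donors and by a
  donor-level lognormal effect `exp(u_i)`, `u_i ~ N(0, 0.2²)`, shared
  across all sensors of a donor. The shared effect is what induces
  inter-sensor correlation and is the dominant nuisance term.
- **Planted effects.** Effects are parameterised as target *percent
  differences* `d_s` (the study's statistic, see below), with
  `δ_s = d_s/(1+d_s)`. Seven designated sensors (BM01, BM10, BM13, BM14,
  BM17, BM18, BM19) carry d between 7.7% and 12.3% with mean 9.5%; the
  remaining eleven share the balance so the panel mean is exactly 5.4%.
- **Measurement.** Fluorescence = `intercept + slope·C·(1+ε) + η` with
  replicate noise `ε ~ N(0, 0.06²)`, read noise `η ~ N(0, 1 RFU²)`,
  floored at 0 RFU; slope 12.5 RFU/(ng/ml), intercept 50 RFU. Each plate
  holds 21 assays (18 wells each) plus a six-point two-fold BM19 dilution
  series, 800 → 25 ng/ml. Amplitudes `A_s` span 120–600 ng/ml (free
  parameters of the generator; the one deliberately weak sensor, BM15 at
  20 ng/ml, keeps the below-LLOQ censoring path exercised in-distribution).

Not emulated: temperature dependence, plate-position effects, serum
autofluorescence background, lyophilisation stability, serum-vs-plasma
differences, and any joint demographic structure. Passing tests therefore
show that the pipeline recovers the statistical structure it assumes; they
say nothing about performance on real sera.

## Quantitation

Per plate, ordinary least squares of fluorescence on nominal standard
concentration gives the calibration line; `r²` is the squared Pearson
correlation, and curves with `r² < 0.999` are flagged (warning, not error —
the observed regime is `r² > 0.9999`). Plates lacking standards fall back
to the pooled study-wide curve with a warning. Concentration estimates are
floored at zero; duplicate wells of one sensor × time are averaged **on the
concentration scale before censoring** (censor-then-average would bias
near-LLOQ means downward asymmetrically); values strictly below the LLOQ
(2.98 ng/ml) are then set to exactly zero, with the boundary value kept.

Intra-assay CV is the per-donor, per-feature sample SD/mean over replicate
assays (positive-mean features only), averaged over features then donors.
With triplicates the sample SD carries the usual c₄(3) ≈ 0.886 downward
bias, so a 6% generative CV yields estimates near 5.3–5.4%; the test band
(±20% relative) accommodates this deliberately — the estimator matches
standard practice and is not bias-corrected.

## Cohort statistics

- **Percent difference** of a feature:
  `100·(mean_control − mean_case)/mean_case` — positive values mean lower
  activity in cancer, and the cancer mean is the denominator. Because the
  planted suppression uses `δ = d/(1+d)`, this estimator is unbiased for
  the planted `d`.
- **Per-feature t-tests**: pooled-variance Student's t, two-sided, no
  multiple-testing correction (a Benjamini–Hochberg helper is provided but
  off by default); a Welch flag exists. Zero-variance identical groups
  return t = 0, p = 1.
- **Hotelling's T²**: two-sample with pooled covariance,
  `T² = (n₁n₂/(n₁+n₂)) d′S⁻¹d`, converted to an F statistic on
  `(p, n₁+n₂−p−1)` degrees of freedom. Singular pooled covariance raises
  an error advising feature reduction rather than silently
  pseudo-inverting.
- **Clopper–Pearson intervals** from Beta quantiles, with the exact
  endpoint conventions (lower 0 at x = 0, upper 1 at x = n).
- **Triplicate precision**: percent of triplicate donors whose three class
  calls agree; a per-call majority-agreement variant is also provided.
  Full-triplicate concordance is the default because it is the stricter
  reading.

## The evolutionary classifier

Linear genetic programs — ordered instruction lists over a small register
file, the 108 features and a per-program constant pool — are the unit of
evolution. Register 0 after the last instruction is the score; `score > 0`
calls cancer. All 48 palette functions are protected (guarded division,
magnitudes under roots/logs, clamped exponentials, 0/1-valued comparisons
and booleans, ternary conditional), and every instruction result is
clamped to ±10⁶ with NaN/Inf replaced, so execution is total.

**Input representation.** Programs see z-scored `log1p` concentrations,
standardised with Training-set statistics stored in the model. The noise
model is multiplicative (shared donor effect, replicate CV), so log
features make the nuisance variation additive and removable by simple
feature differences; constants (drawn N(0, 2)) then live on the same scale
as the inputs.

**Search.** S = 8 islands of n_i = 250; each generation pairs the island
randomly, keeps the fitter of each pair (ties: larger margin, then shorter
program, then a seeded coin), and refills with offspring by copy-mutation
or one-point tail crossover (parents retained). After a 50-generation
warm-up, every 10 generations the top 5% of each island emigrate to the
next island on a unidirectional toroid. Fitness is balanced accuracy
(raw accuracy selectable).

Several choices here were forced by the step-function nature of an
accuracy fitness at desk scale, and differ from the most naive setup:

- a smooth *margin* score (class-weighted mean of `tanh(score)` signed by
  the label) breaks exact fitness ties, so variants that improve the
  decision margin without yet flipping a call are visible to selection;
- instruction proposals weight arithmetic heavily (all 48 functions remain
  reachable) and read their own destination register half the time,
  seeding accumulator chains that extend well under insertion and tail
  crossover;
- point mutations concentrate on effective code (backward-liveness
  introns are fitness-neutral edits), and fitness evaluation skips
  introns — an exact optimisation;
- the register file is small (3–4): with many registers and uniform
  destination choice most random programs never write the output register;
- islands are *heterogeneous*, cycling mutation rate, crossover
  probability and register count across a fixed table, because
  homogeneous runs fail together on a bad early draw of building blocks;
- programs may grow to 48 instructions (initialised at 2–24): useful
  classifiers on this data are long additive combinations, and tight
  length caps cap attainable accuracy;
- training runs two independent evolutions from derived seeds (the run
  length stays at the w + g·S = 130 schedule) and pools the survivors
  before model selection: single desk-scale runs have high outcome
  variance, and a stalled search must then happen twice to hurt.

**Selection and the ensemble.** Survivors (exact duplicates collapsed) are
re-scored on the Selection third: `score = accuracy × reliability` with
`reliability = 1 − |accuracy_train − accuracy_selection|`. The top-ranked
program is "the" selected algorithm; the ensemble takes ranked programs
whose Selection-set call vectors are pairwise distinct, up to 51 — without
the distinctness filter the top of the ranking is behavioural clones of
rank 1 and the vote degenerates, and a larger distinct committee reduces
the variance of the vote fraction around its thresholds. Class calls threshold the positive-vote
fraction at five operating points: 0.7 / 0.6 / 0.5 / 0.4 / 0.3 for
Spec Max / Spec Bias / Ensemble / Sens Bias / Sens Max, so sensitivity is
non-decreasing and specificity non-increasing across the ladder by
construction.

**Splitting.** Donors (never assays) are dealt into thirds stratified
jointly on disease status, stage, site, sex, age band, smoking and
histology: cells are shuffled and dealt round-robin with a pointer carried
across cells, giving subset sizes and per-cell counts within one of equal,
with sub-3-donor cells dealt the same way under a warning. Replicates of
one donor can never straddle subsets; leakage is asserted on every
training run.

**Relative impact.** For sensor i, `f_i` is the fraction of ensemble
members referencing any of its features and `a_i` the drop in ensemble
balanced accuracy on the Selection set when its features are replaced by
the training mean (zero in standardised space), floored at 0. The impact
is `100 · (f_i/mean(f) + a_i/mean(a))/2`, so the panel mean is exactly
100%; sensors are binned at >200%, 100–200% and <100%. If every ablation
drop is zero the usage term alone is used, with a warning.

## Screening triage model

A deterministic expected-value calculation on a population of 100,000
at-risk individuals with 0.91% prevalence. LDCT alone screens at its
observed 3.9% compliance with the Lung-RADS operating point (sensitivity
84.9%, specificity 87.2%). The triaged pathway screens at 75% blood-test
compliance (sensitivity 90%, specificity 82%) and refers positives to
LDCT; a detection requires both tests positive, a false positive requires
both tests falsely positive. Reporting rules: LDCT-only detections round
to the nearest integer, triaged detections to the nearest ten, fold
change on unrounded counts rounded half-up — matching the precision such
projections are quoted at. PPV confidence intervals apply the exact
binomial interval to the rounded TP/FP counts. The triaged PPV computed
from these parameters is ≈23.3–23.4%; published figures quoting ≈23.7%
rest on a parameterisation not fully recoverable from headline values,
and this model reports its own computed value.

## Determinism and problem sizes

All randomness flows from one root seed through named child streams
(cohort, reads, training; `leap.pipeline.child_seeds`), so identical
configuration and seed give byte-identical artifacts including the final
JSON report. The test suite and acceptance script run the full 450-donor,
750-assay design; classifier evaluations use the default search scale
(8 islands × 250 programs × 130 generations × 2 restarts, ~10⁵ program
evaluations per restart). The planted-signal check is stochastic by nature
and is asserted as a pass rate over a fixed battery of ten derived seeds.

## Known limitations

- The generator's independence assumptions (demographics independent of
  each other and of the signal; noise independent across wells) are
  simplifications; real panel data will have structure the classifier can
  exploit or be confounded by that is absent here.
- Percent-difference estimates inherit the donor-effect sampling noise
  (≈2.3 percentage points SD per 450-donor cohort); single-cohort
  estimates of the 5.4% panel mean are correspondingly noisy, which is why
  the acceptance script averages replicate cohorts.
- The evolutionary search is a desk-scale instrument (~10⁵–10⁶ program
  evaluations); it demonstrates recoverability of a planted multivariate
  signal, not the performance ceiling of evolutionary classification.
- Below-LLOQ censoring is rare under default amplitudes (BM15 aside);
  heavy-censoring regimes are exercised in unit tests, not in the default
  cohort.
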
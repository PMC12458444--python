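# Methods

`invbehave` quantifies how the *Drosophila melanogaster* chromosomal
inversion In(2L)t shapes sleep, startle response and foraging position
across sexes and temperatures, from single-fly tube-tracking data.  Because
the kind of raw tracking data it consumes is rarely redistributable, the
package pairs the analysis chain with a synthetic trajectory generator
whose ground truth is known exactly; every downstream stage is validated
against that truth.

## Data model

A fly is tracked in one dimension along a food-capped tube (position 0 mm =
food end, `L` = 65 mm by default) at a uniform sampling interval `dt`
(default 1 s; real tracking rigs vary, so both are configuration).  Speed
is `|Δx|/dt`, aligned to the later sample of each pair, with the first
sample's speed defined as 0.  Each fly carries metadata: In(2L)t genotype
(`INV` inverted homozygote / `HET` heterozygote / `STD` standard
homozygote), sex, assay temperature (20/25/30 °C), replicate experiment
block, and cross identity.

## Behavioral traits

Six traits are scored per fly:

| trait | definition | units |
|---|---|---|
| sleep | time in sleep bouts (≥ 5 consecutive inactive minutes) per scored hour, over the pre-stimulus period | min/h |
| base speed | mean speed in the hour before the first stimulus | mm/s |
| startle duration | time from a stimulus until the 10-s rolling mean speed first returns to (≤) baseline, averaged over stimuli | s |
| startle magnitude | mean speed in the post-stimulus minute minus baseline, averaged over stimuli | mm/s |
| near-food occupancy | share of baseline-hour samples in the food-adjacent eighth of the tube | proportion |
| far-food occupancy | share of baseline-hour samples in the food-distal eighth | proportion |

Conventions that the trait definitions leave open, and the choices made:

* **Inactivity** is operationalized as per-minute displacement ≤ ε
  (default ε = 1 mm), on minute bins — the standard activity-monitor
  convention.  A step belongs to the minute containing its later sample;
  a partial trailing minute is dropped, and sleep is normalized by the
  number of scored minutes.
* **The ≥ 5 min bout threshold is inclusive**: exactly five inactive
  minutes form a bout.
* **Return to baseline** uses a trailing 10-s rolling mean computed from
  post-stimulus samples only, so a fly asleep at the stimulus cannot leak
  low pre-stimulus speeds into the first windows.  If the first
  post-stimulus smoothed value is already ≤ baseline the duration is 0.
* **Censoring**: a duration that has not returned by the next stimulus (or
  recording end) is recorded at that cap and flagged; censored values are
  kept in the per-fly mean rather than dropped, which would bias durations
  downward.
* **Zones** are eight half-open bins `[iL/8, (i+1)L/8)`; `x = L` falls in
  the last bin.  Occupancy is scored over the pre-stimulus baseline hour by
  default because post-stimulus position is confounded by startle
  locomotion (configurable to the full recording).
* Baseline speed is reported in mm/s throughout, for consistency with the
  speed traces.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes, not
fly biomechanics:

* **Sleep/wake** is an alternating renewal process with exponential sojourn
  times (means `mu_wake_s`, `mu_sleep_s`).  The initial state is drawn from
  the stationary distribution (flies acclimate overnight before assays), so
  the asleep fraction is `mu_S/(mu_S+mu_W)` from the first sample.  Asleep
  flies are frozen in place.
* **Movement while awake**: an Ornstein–Uhlenbeck proposal
  `kappa*(p* − x)dt + sigma_x*sqrt(dt)*N(0,1)` supplies each step's
  *direction* toward a preferred position `p*`; the step *magnitude* is a
  per-step log-normal wake-speed draw times `dt`.  Steps that would leave
  the tube are flipped back inside, preserving the magnitude, so the
  derived speed trace reproduces the configured speed distribution exactly.
  A zero proposal (κ = 0 and σ_x = 0) means no movement.
* **Startle**: each stimulus truncates the current bout and starts a fresh
  exponential wake bout (mechanical arousal restarts wake maintenance), and
  adds a speed excursion `A·exp(−(t−t_stim)/τ)` until it decays below one
  step-noise unit (σ_x).  Each step receives the exact integral of the
  decay over its interval, giving the closed form
  `A·τ·(1−e^(−60/τ))/60` for the mean post-stimulus-minute speed excess.
* **Design effects** shift the generating parameters; each block adds
  Gaussian random-intercept shifts (sleep-bout mean, log wake speed,
  startle amplitude, preferred position).

Default parameters — the emulated study conditions, chosen once:

* Cohort: 3 genotypes × 2 sexes × 3 temperatures × 3 blocks × 34 flies/cell
  (≈ 1.8k flies, the scale of the emulated assay's three blocks).
* Baseline (STD female, 25 °C): `mu_wake` 1200 s, `mu_sleep` 1800 s
  (36 min/h sleep), median wake speed 1.2 mm/s (log-SD 0.15), κ = 0.02 /s,
  σ_x = 1 mm, A = 3 mm/s, τ = 15 s.
* Genotype: inverted homozygotes have *longer bouts of both kinds*
  (`mu_sleep` +300 s, `mu_wake` +900 s; heterozygotes half-way), so their
  sleep *fraction* is lower (30 vs 36 min/h) while their longer wake bouts
  keep them moving after a startle — reproducing both the lower sleep and
  the longer startle durations of inverted flies.  Preferred positions are
  STD 15 / HET 30 / INV 45 mm: inverted flies haunt the food-distal end.
  Genotype (and sex) offsets on log wake speed cancel the wake-fraction
  differences so that mean baseline speed is genotype- and sex-null, as
  observed.
* Sex: males sleep more (`mu_sleep` +300 s) and startle harder (A +0.5).
* Temperature (slopes per °C from 25): sleep falls (`mu_sleep` −60,
  `mu_wake` +60), speed rises (log-speed +0.03), startle sharpens
  (A +0.06, τ −0.4).
* Block random-intercept SDs: 120 s on `mu_sleep`, 0.05 on log speed,
  0.1 on A, 1 mm on `p*`.
* Stimulus schedule: first stimulus at 3600 s (a baseline hour must exist),
  then every 1800 s, four stimuli — a placeholder schedule, configurable.

A **trait-table shortcut** (`simulate_phenotype_table`) draws the six
traits directly from the linear mixed model the inference assumes
(intercept + genotype contrasts + covariate + interaction + block intercept
+ Gaussian noise, proportions clamped to [0, 1]).  It is used where a
criterion concerns the inference machinery itself rather than the
trajectory model.

**Randomness**: numpy PCG64; a master seed is split with
`SeedSequence(entropy=(seed, stream, index))` where `index` is a counter
over design cells and within-cell replicates, so enlarging a cohort never
reshuffles existing flies.  The position update has a numba-compiled fast
path and a pure-Python twin; their outputs are bit-identical (tested), so
results do not depend on whether numba is importable.

What the generator deliberately omits: circadian structure (the emulated
assay runs in constant darkness), social interaction, arousal-threshold
dynamics, non-exponential bout-length distributions, and measurement noise
in position.  Tests passing on synthetic cohorts therefore validate the
*pipeline*, not any claim about real flies.

## Inference

For each trait, four nested linear mixed models are fitted by **maximum
likelihood** (models in the ladder differ in fixed effects, so REML
likelihoods would not be comparable):

    null:         trait ~ 1                        + (1 | block)
    inversion:    trait ~ genotype                 + (1 | block)
    covariate:    trait ~ genotype + covariate     + (1 | block)
    interaction:  trait ~ genotype * covariate     + (1 | block)

Genotype is treatment-coded with STD as reference (coding affects reported
contrasts, not the LRTs).  The covariate is sex (2-level factor) in the
25 °C between-sex analysis, or temperature in °C as a *numeric* regressor
(one parameter) in the females-across-temperatures analysis; both ladders
therefore have structural parameter counts (3, 5, 6, 8) — fixed effects
plus block variance plus residual variance — and LRT df (2, 1, 2).
Proportion traits are arcsin-square-root transformed before modeling (and
before the post-hoc tests).  AIC is `2·npar − 2·logLik` with the
structural npar.

Numerical choices:

* Fitting uses statsmodels `MixedLM` (ML).  The variance MLE may sit on
  the σ_B = 0 boundary, where the mixed log-likelihood equals the OLS
  log-likelihood of the same fixed effects; both candidates are evaluated
  and the valid maximum kept (this also covers optimizer failures and the
  degenerate constant-trait case).  Several optimizers are tried before
  accepting a boundary fit.
* LRT statistics in (−1e−6, 0) are clamped to 0 (convergence jitter);
  anything more negative aborts the comparison as a convergence failure.
* A factor term with a single observed level contributes no parameters;
  its LRT is 0 with p = 1 and npar keeps its structural count.

If the genotype LRT or the genotype-bearing interaction LRT is significant
at α = 0.05 (the conventional gate), **Welch two-sample t-tests** compare
all genotype pairs within each covariate stratum, with unadjusted p-values
by default (a pooled-variance option exists, as does optional
multiple-testing correction upstream of reporting; published analyses of
this design report both fractional and integer post-hoc dfs, so both
variants are exposed).  Strata with fewer than two flies in a genotype are
skipped.

## Pipeline and reproducibility

`run_end_to_end` chains simulate (or ingest) → phenotype → both analyses →
report.  Every run writes a manifest with the config snapshot, seed,
package versions, per-stage row counts, warnings (censored startles,
non-convergences, skipped pairs) and SHA-256 digests of all artifacts;
re-running the same config reproduces the stochastic stages bit-identically.
Summary plots show genotype means with mean ± 1.96·SE error bars per trait
and stratum (captions of the kind "95% standard errors" are rendered as a
95% normal CI — a documented convention, since the phrase is ambiguous).

## Validation problem sizes

Statistical checks are run at desk scale, chosen for Monte-Carlo precision
rather than biological fidelity:

* type-I calibration: 500 null cohorts at 10 flies/cell (test) and 400 in
  the acceptance script;
* effect recovery: 200 replicates at 20 flies/cell per trait (sign rate
  and bias vs. the mean model SE);
* closed forms: 120–150 flies per config, with bout means (2 h) long
  enough that the 5-min threshold and minute binning are negligible
  against Monte-Carlo error, and step noise small enough that the startle
  excursion outlives the scored minute;
* direction-of-effect: one 540-fly trajectory cohort at 25 °C with a 2-h
  baseline window.

## Known limitations

* Startle duration is defined relative to each fly's own baseline, so in
  any two-state movement model it is partly a function of sleep structure;
  the generator's wake-maintenance mechanism makes the genotype ordering
  explicit rather than removing the coupling.
* With only three blocks the random-intercept variance is weakly
  identified; ML point estimates of σ_B are noisy (the fixed-effect LRTs
  remain calibrated, which the type-I check verifies).
* The χ² reference for the LRT is asymptotic; at very small cohorts the
  gate is approximate.
* Proportion traits are modeled as Gaussian after the arcsin-sqrt
  transform; zero-inflated occupancy (flies that never visit a zone) is
  not explicitly modeled.
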
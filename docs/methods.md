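# Methods

This note documents the models and procedures implemented in `flocknet`,
the choices made where the design was genuinely open, and what the
synthetic studies do and do not establish about real field data.

## Flocking-event detection

Birds foraging in fission–fusion flocks produce, at each feeding
station, a temporal stream of RFID reads consisting of bursts (flock
visits) separated by quiet gaps. Detection proceeds per site-day (no
event spans a night, since the birds do not forage after dusk) and pools
the reads of co-located feeders (the paired trial feeders stand within a
metre of each other; feeder identity is retained on each record for the
dietary response, but a flock visit covers both).

The day's detection times are fitted with one-dimensional Gaussian
mixtures for K = 1…K_max components, K_max = min(`max_components`,
⌈n/3⌉), and K is chosen by BIC. Implementation details that matter:

- **Initialization.** EM is started deterministically by cutting the
  sorted times at the K−1 largest inter-detection gaps and seeding each
  component with its segment's mean, variance and mass. For bursty data
  this start is near the global optimum, so EM converges in a few
  iterations and the BIC-versus-K curve is clean; random multi-starts
  (`n_init > 1`) are available but rarely change the result. Naive
  random initialization was both slower and prone to local optima that
  biased BIC toward over-segmentation.
- **Search over K.** BIC against K is U-shaped in practice, so the scan
  uses a coarse grid (about a tenth of K_max) followed by refinement
  around the coarse minimum, with early stopping after eight
  non-improving values. This is a runtime optimization only; it targets
  the same BIC minimum as an exhaustive sweep.
- **Variance floor.** Component variances are floored at 1 s². A flock
  visit spans at least seconds, and sub-second repeat reads of a perched
  bird are collapsed upstream; without the floor, EM places point-mass
  components on coincidental pairs of nearly simultaneous reads and BIC
  rewards them, splitting true events.
- **Pruning and combining.** Components with mixture weight below
  `0.5/n` are pruned (their detections reassigned to the nearest
  surviving component mean). Mixture components are density components,
  not clusters: occasionally BIC describes one burst with two heavily
  overlapping Gaussians, so adjacent components whose means are closer
  than `merge_overlap_factor` (default 2) times the sum of their SDs are
  combined into one event. Genuinely separate bursts sit far outside
  this threshold — at the generator's defaults the centre-to-centre gap
  (≥ 300 s) is five times the merge threshold (2 × 2 × 30 s).
- An event's members are the distinct tags assigned to the component;
  start/end are the min/max assigned times; singleton events are
  retained (they contribute to group-size statistics but no dyads).

On simulated streams at default settings the detected assignment matches
the generating events with adjusted Rand index ≈ 1.0, and the per-day
event count is exact on ≥ 95% of site-days whenever gaps exceed ~20
within-burst SDs.

## Social networks

The Simple Ratio Index for a dyad is the proportion of flocking events
involving either bird in which both were seen:
`SRI(A,B) = F_AB / (F_A + F_B − F_AB)` ∈ [0, 1]. Networks are built per
site and per period (baseline, trial 1, trial 2); sites are treated as
separate populations, so cross-site weights are structurally zero. No
edge thresholding is applied.

Node metrics: strength (sum of incident weights); average edge weight
(strength / number of non-zero edges — reported as *missing* for
isolated nodes, because 0 would conflate "no bonds" with "weak bonds";
such birds are dropped from models using that metric, with a logged
count); eigenvector centrality (leading eigenvector of the weight
matrix, computed on the largest connected component, sign-fixed
non-negative, scaled to max 1, other nodes 0 — the normalization only
affects the coefficient scale); mean flock size (mean size of the
focal's events, counting the focal); and number of unique flock-mates.

## Dietary-decision models

The usage response for bird *i* is the pair (novel_i, familiar_i) of
detection counts at the two trial feeders, fitted as a binomial-logit
GLM so that both the direction and the weight of evidence of each bird's
preference enter the likelihood. Feeder-count data are overdispersed
relative to binomial sampling, so inference is quasi-binomial: the
coefficients are exactly the binomial-IRLS estimates; the dispersion
φ = Pearson χ² / (n − p) multiplies the squared standard errors; Wald
statistics are referred to a t distribution on n − p degrees of freedom.
Fits go through `statsmodels` GLM (IRLS); an independent hand-written
IRLS oracle in the test suite confirms agreement to 10⁻⁶ and the
dispersion arithmetic.

Centrality is always taken from the period immediately before the
modelled trial (baseline → trial 1, trial 1 → trial 2), together with
site, sex, age class, immigrant status, and the raw count of feeder
detections in that prior period. Birds detected in a trial but absent
from the prior network have undefined centrality and are excluded
(logged); `include_absent_with_zero` re-admits them with zero strength
for sensitivity analysis. Predictors are unstandardized by default
(coefficients in raw logit units); a z-score flag exists for
cross-metric comparison, and `log_prior` applies log1p to the
prior-usage covariate.

Neophobia responses: the binary first-arrival choice (quasi-binomial);
latency to first novel-feeder use measured two ways — clock time
(seconds since midnight of the first-use day) and elapsed foraging time
(within-day spans only; nights excluded) — both Gaussian-family, as is
conventional for latencies on this scale. Birds never recorded at the
novel feeder have missing latencies and are dropped from latency models
(their post-first counts are zero). Post-first-use preference re-counts
novel/familiar detections strictly after each bird's first novel-feeder
record.

## Permutation inference

Network metrics violate independence assumptions, so every model term
also receives a permutation p-value. The response variable (the
successes/fails pair moves as a unit) is reassigned uniformly at random
among birds of the same site and period; the model is refitted with the
predictor matrix untouched, preserving the exact distributions of and
covariances between predictors; and after B permutations
`p_rand = (1 + #{|β*| ≥ |β̂|}) / (B + 1)` per term. The two-tailed
absolute-value rule is used (the alternative "twice one tail" differs
only for skewed nulls), and the add-one correction keeps p_rand
strictly positive.

Two implementation decisions worth recording:

- **Speed.** Permutation refits share one design matrix, so the
  binomial-logit refits run through a batched Newton/IRLS solver
  (`flocknet.irls`) that solves all permutations' weighted least-squares
  steps at once; Gaussian refits are a single least-squares solve. The
  batched solver is validated against `statsmodels` to ~10⁻⁷ in the
  tests. 10,000 permutations of a 150-bird model take about a second.
- **Separated refits are kept.** Permuted binary responses
  quasi-separate a few percent of the time; their coefficient estimates
  are finite but very large. Discarding and redrawing such fits trims
  the null's tail and measurably inflates the type-I error, so they are
  retained as legitimate far-tail draws. Only numerically failed
  (non-finite) refits are redrawn, capped at 1% of the requested draws,
  beyond which the test aborts rather than report a biased null.

Calibration measured over 1,000 replicate null studies (200 permutations
each, scaled down from the 10,000 a single real analysis would use):
rejection at 0.05 falls within [0.03, 0.07].

## The synthetic-data generator

The generator emulates the study design end to end: two sites of
`n_individuals_per_site` tagged birds; a 12-day baseline with one
familiar-food feeder per site; two 4-day trials, each pairing a
novel-food feeder (red at site 1 / green at site 2 in trial 1, swapped
in trial 2) with the familiar feeder; feeder positions swap every other
day (recorded as a column; no behavioural effect is simulated, matching
its role as a nuisance control).

Mechanics, per site-day: event count ~ Poisson(`events_per_site_day`);
event centres uniform over a 28,800 s (8 h) foraging day with a minimum
centre spacing `between_event_gap_min`; each local bird joins each event
independently with probability logistic(`join_intercept` +
`join_slope`·g_i), where g_i ~ Normal(0, `gregariousness_sd`) is the
bird's latent sociality; members emit Poisson(`detections_per_member` ×
r_i) + 1 reads at Normal(centre, `within_event_sd`), where r_i is a
lognormal per-bird read-rate multiplier (`detection_rate_sd`). During
trials each read is assigned to the novel feeder with probability
logistic(`diet_intercept` + `diet_slope_sociality`·g_i + colour and
trait effects); the *first* read of each bird in a trial instead uses
the first-arrival (neophobia) logit, whose sociality slope is a separate
parameter defaulting to 0 — so by default usage is sociality-linked
while first-arrival choice is not, the dissociation the analysis is
built to detect.

Default parameter choices and why:

| parameter | default | rationale |
|---|---|---|
| `n_individuals_per_site` | 40 | between the two field sites' 52 and 33 birds |
| `baseline_days` / `trial_days` | 12 / 4 | the study design |
| `events_per_site_day` | 30 | tens of flock visits per feeder-day; keeps a simulated study cheap enough for replicate testing |
| `within_event_sd` / `between_event_gap_min` | 30 s / 300 s | bursts of a couple of minutes separated by clear gaps; the 10× ratio keeps segmentation well-posed by construction |
| `detections_per_member` | 3 | a handful of reads per bird per flock visit after duplicate collapsing |
| `detection_rate_sd` | 0.6 | birds differ ~2-fold (fold-SD) in per-visit feeder use, independent of sociality; without this, prior feeder usage would be a deterministic proxy of sociality and collinear with strength |
| `join_intercept` / `join_slope` | −1.8 / 0.5 | mean join probability ≈ 0.15, giving a typical group size ≈ 6.6, close to the observed 6.8 |
| `diet_intercept` | −0.5 | novel food used somewhat less than familiar overall |
| `diet_slope_sociality` | 0.5 | the true effect, on the scale of the reported usage coefficients (~0.5 logits per sociality SD) |
| `site_colour_effect` | −1.5 | a strong colour (green) aversion, mirroring the observed site × colour preference |
| `covariate_effects` | all 0 | age/sex/immigrant effects were null findings; configurable for power studies |

Timestamps are seconds since each day's 06:00 dawn, serialized as
ISO-8601 datetimes from a nominal winter start date. Solitary events are
allowed (no minimum flock size is imposed). A bird can appear at only
one site; no movement, weather or detection-failure model is included.

**What the synthetic studies do not establish.** The generator's flocks
are memoryless (no repeated subgroup structure, no temporal
autocorrelation of membership beyond the shared gregariousness), reads
within a burst are exchangeable, and every bird is tagged. Consequently
the simulated SRI networks are denser (≈ 85–99% of dyads realized) than
the observed winter networks (63–70%), and passing recovery tests shows
the *pipeline* is correct and calibrated under the stated generative
model — not that the field data satisfy that model. Degenerate inputs
are handled explicitly: empty streams yield empty event lists; a single
detection is a singleton event; density and typical group size raise on
empty inputs rather than return silently.

## Problem sizes used in tests

Replicate-based checks run the full simulate → network → model → permute
chain with the prior-period network built from the generator's true
events (event detection is validated separately against ground truth, to
adjusted Rand ≈ 1, so re-running the mixture fits inside every replicate
would only re-measure that). Sizes: event recovery over 500 site-days;
type-I calibration over 1,000 null studies × 200 permutations; power
over 100 studies × 1,000 permutations at 150 birds; the neophobia
dissociation over 200 studies. The pipeline itself defaults to 1,000
permutations per model; `analysis/05_permutation_tests.py` uses 10,000,
matching what a single real analysis would run.
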
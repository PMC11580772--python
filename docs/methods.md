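# Methods

This note documents the statistical procedures implemented in `bondtrace`,
their assumptions, the defaults of the synthetic-data generators, and the
numerical choices that were genuinely open.

## Study designs the package models

Two introduction designs recur in captive studies of social-bond formation:

1. **Small-cage introductions.** A newcomer is placed with 1–3 unfamiliar
   residents in each of ~18 small cages (2 or 4 adult females per cage).
   The first 6 h of behavior are scored as timed, directed events in two
   classes: affiliative (sniffing/licking, merged because they are hard to
   delimit on video) and aggressive. Long-term cooperation is then observed
   for months as aggregated binomial data: seconds of allogrooming or food
   sharing out of the seconds each directed pair was observable.
2. **Flight-cage introduction.** ~20 bats from 3 capture sites are released
   together wearing proximity sensors; pings (timestamp + RSSI) accumulate
   whenever two tags are in range. Long-term allogrooming is observed for
   months, including a randomized "forced proximity" week in which trios
   (one bat per site) are co-housed, giving a causal reference effect.

## Aggregated binomial GLM and the cage-constrained null

The Study-1 statistic is the slope β of
`logit Pr(behavior) = α + β·z(x)`, where x is a directed dyad's
first-interaction seconds for one behavior class and the response is
`behavior_s` out of `possible_s`. Predictors are z-scored so slopes are
comparable across the four predictor × response models.

Dyads here violate every convenient assumption: only cagemates could
interact, some actors had one possible receiver and others three, and actor
and receiver effects are not estimable (not all pairs co-occur). Inference
is therefore permutation-based. The exchangeable unit is the *event
receiver*: under the null that introduced bats direct behaviors at random
within their cage, each event's receiver is redrawn uniformly among the
actor's cagemates while keeping actor, class, onset and duration. This
conserves per-actor totals exactly, never crosses a cage, and reduces to the
identity in 2-bat cages. An alternative null that shuffles observed dyad
totals among each cage's directed stranger pairs is available
(`unit="dyad_totals"`) for sensitivity analysis; the event-level unit is the
default because it operationalizes "behaviors directed at random" without
assuming totals are exchangeable across dyads with different exposure.

Numerics: the GLM is fit by a 2-parameter Newton/IRLS solver with
step-halving (the permutation engine refits it ~10⁵ times in calibration
studies; per-fit overhead matters). Its estimates agree with
`statsmodels` GLM to ~1e-7 and with a brute-force likelihood grid to <1e-3
(both checked in tests). The predictor is re-standardized within every
permuted dataset, since permutation changes its distribution. Permuted fits
with zero predictor variance or flagged non-convergence (|slope| > 30 on
the z scale, or failed Newton convergence) are dropped and the Monte-Carlo
denominator reduced; the count is reported. p-values use the add-one
convention `(1 + b)/(m + 1)`, which is standard for Monte-Carlo tests and
guarantees p > 0. One-tailed directions default to upper for affiliative
predictors and lower for aggressive ones (the directional predictions of
the design). No multiplicity adjustment is applied across the four models.

Incidence proportions use the exact Clopper–Pearson interval
(beta-quantile form, via `scipy.stats.binomtest`); percentages are reported
to two significant figures (whole percents at ≥10%, one decimal below).
Mean event durations use a seeded percentile bootstrap of the mean.

## Sensor pipeline

*Encounters* are maximal runs of a pair's pings with inter-ping gaps
≤ `max_gap_s` (default 60 s; ping interval 2 s — hardware-dependent and
configurable). A single-ping encounter is assigned one ping interval of
duration. *Contacts* are encounters whose maximum RSSI reaches the
(1 − q) empirical quantile of **encounter-level maxima over the whole
dataset** (default top 5%; top 1% defines "close contacts"). Ties at the
threshold are kept (≥). The quantile uses the `higher` order statistic so
that 100 distinct encounters at 5% yield exactly 5 contacts. A ping-level
thresholding variant (quantile over raw ping RSSI) is available behind a
flag, since sensor systems differ in whether the reference distribution is
per-ping or per-encounter.

First-contact durations accumulate the intersection of each contact's
interval with half-open windows [0, W h); an encounter straddling a window
boundary contributes only its intersection, making per-pair minutes monotone
in W and exactly decomposable into per-interval increments.

Network density is the fraction of unordered pairs with positive contact
minutes. Site assortativity is the categorical assortativity coefficient
`r = (Σᵢeᵢᵢ − Σᵢaᵢbᵢ)/(1 − Σᵢaᵢbᵢ)` computed on a mixing matrix that uses
edge weights (contact minutes) as multiplicities, so long contacts count
proportionally. Familiar/unfamiliar contrasts are percentile bootstraps with
the pair as the resampling unit.

## Negative-binomial multi-membership model

Dyadic allogrooming minutes over the observation period are overdispersed
counts owned by both members of the pair:

    y_d ~ NB(μ_d, φ),  Var = μ + μ²/φ
    log μ_d = log(possible_d) + α + x_d'β + u_i(d) + u_j(d)
    u_b ~ Normal(0, σ_bat²)

The log-exposure offset converts coefficients to effects on hourly *rates*.
Fixed effects in the full model: standardized first-contact minutes for a
chosen window, forced-proximity (pair was in a treated trio), post-treatment
period, and their interaction — the interaction being the causal reference
effect of one week of forced proximity. Pre- and post-treatment grooming
enter as two rows per dyad, which is what makes the interaction estimable.
The contact covariate is standardized over unfamiliar pairs only (the
population the model is fit to). The pre-treatment-weeks variant drops the
treatment terms (the treatment has not happened yet) via
`study2_model_frame(include_treatment=False)`.

Priors are weakly informative and config-exposed: Normal(0, 2.5) on
standardized fixed effects, Normal(0, 5) on the intercept, half-Student-t(3)
on σ_bat and on 1/√φ. Sampling uses `emcee`'s affine-invariant ensemble
sampler with differential-evolution moves (which mix far better than stretch
moves in this ~25-dimensional hierarchical posterior) on a non-centered
parameterization (u = σ·z, with log σ and log φ as sampling coordinates,
Jacobians included). Defaults: 64 walkers, 3000 steps, first half discarded,
thinned by 3. Walkers are treated as chains for split-R̂ and bulk/tail ESS
(arviz) on the interpretable scalars (intercept, slopes, log σ, log φ); the
fit raises an error when any R̂ exceeds `rhat_max` (default 1.3 — an
ensemble-sampler mixing guard, deliberately looser than the ~1.01 expected
of gradient-based samplers with long independent chains).

Derived quantities. Percent change per 1 SD of a standardized predictor is
`100·(e^β − 1)` per draw. Bayesian R² follows the draw-wise definition on
the expected-value scale: for draw s, `R²ₛ = Var_d(μ_{sd}) /
(Var_d(μ_{sd}) + mean_d(μ_{sd} + μ_{sd}²/φₛ))`, with sample variance
(ddof 1) over observations and the NB mean–variance relation supplying the
residual term; μ includes the offset. Constant fitted values give R² = 0 by
convention. The variance share of a term is the per-draw difference between
the full model's R² and the R² of the model refit without that term (draws
paired by index); negative shares are reported as-is rather than clipped,
as honest propagation of posterior uncertainty.

The familiarity model applies the same machinery with contact minutes
(rounded to integer counts) as the response, unfamiliarity as the sole fixed
effect, and no offset (all pairs share the observation span of a window).

## Synthetic-data generators

The generators define the study conditions under which the pipeline is
tested; they are first-class, tested code with ground-truth ledgers.

**Small cages** (`Study1Config`): 18 cages — 9 of size 2 and 9 of size 4 —
each with one newcomer from a second site (one newcomer meeting 1 or 3
residents; 36 introduced stranger pairs, the closest this layout comes to
the 35 pairs of the emulated design). Events per directed cagemate pair are
Poisson (0.35/h affiliative, 0.03/h aggressive over the 6-h horizon);
affiliative durations are log-normal with arithmetic mean 252 s (σ = 1),
aggressive durations uniform on [1, 25] s — reproducing the order-of-
magnitude scale separation between the classes. Long-term responses are
binomial draws per directed stranger dyad with
`logit p = baseline + effect·z(affiliative seconds) + N(0, 0.5)`; exposure
seconds are uniform over the observed ranges (540–1860 min grooming,
240–960 min sharing, scaled by `obs_days/303`). The dyad-level logit noise
(SD 0.5) is a modeling convention — the emulated design reports no noise
model. Default `effect_affiliative = 0`, the empirical finding for this
system; recovery and power tests plant nonzero slopes explicitly.

**Flight cage** (`Study2Config`): 20 bats over 3 sites (7/7/6 → 190 pairs,
57 familiar, 133 unfamiliar). Encounters per pair are Poisson over 24 h
(1.0/h familiar, 0.5/h unfamiliar by default — contact driven by encounter
*frequency*); durations exponential (mean 120 s, clipped to [2 s, 30 min]);
pings every 2 s within an encounter. Encounter max RSSI is drawn from a
familiarity-independent distribution (base N(−55, 6) per encounter, per-ping
noise SD 2), keeping RSSI thresholding a pure measurement filter rather than
a second familiarity channel. Candidate intervals that collide within the
60-s gap are merged before pings are emitted, so the ledger's encounters are
exactly what the ping stream supports. Grooming counts are gamma-Poisson
(NB) draws per dyad-period with intercept −5.5 (≈0.004 grooming minutes per
possible minute), planted contact slope ln(1.32), forced-proximity
interaction ln(3.38) (a 238% rate increase), dispersion φ = 2 and σ_bat =
0.5; six forced trios (one bat per site). Timestamps are seconds since
introduction (t = 0 when strangers first share the space).

What the generators do *not* emulate: pup presence, deaths mid-study, the
multi-day gap between sensor deployment and the start of long-term
observation, circadian structure in encounter rates, and RSSI-distance
physics. Passing tests therefore demonstrate the correctness and calibration
of the *procedures* under a faithful but idealized data-generating process,
not conclusions about real colonies.

## Problem sizes and tolerances used in verification

- Permutation calibration: 200 null datasets × 500 permutations; the
  rejection rate at α = 0.05 must lie in the binomial 95% interval around
  0.05. Power: 60 datasets with planted slope 1.0 must reject more often.
- Slope recovery: the planted slope 1.0 is recovered within ±0.15 (mean of
  replicate GLM fits); the NB contact slope ln(1.32) is covered by the 95%
  CrI in ≥85% of 40 full-size (190-dyad) replicates.
- Exact checks: dyad totals and window minutes against the generator
  ledgers (atol 1e-9); Clopper–Pearson against beta quantiles on all
  (k, n ≤ 10); Bayesian R² against a hand-computed 3-draw × 4-observation
  toy posterior; assortativity against a hand-evaluated mixing matrix.
- Null-quantile stability across seeds allows 10% of the null SD at 5000
  permutations, the scale of the Monte-Carlo error of an empirical 2.5%
  quantile at that sample size.

## Known limitations

- The ensemble sampler yields fewer effective samples per minute than a
  gradient-based sampler would on this posterior; diagnostics thresholds
  are set accordingly, and very short chains (as in some orchestration
  tests) require relaxing the R̂ guard explicitly.
- The event-level permutation unit is one reading of "interactions that
  could have been observed"; the dyad-total variant is provided because the
  exchangeable unit is not uniquely determined by the design.
- Replicating the published field coefficients exactly requires the
  deposited dataset and the original default priors of the original fitting
  software; with weakly informative priors the replication is expected to
  be close but not bit-identical.
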
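# bondtrace

Do first meetings between strangers predict their long-term social bonds?
`bondtrace` is an analysis toolkit for dyadic behavioral data from
introduction experiments in group-living animals, built around the design of
captive vampire-bat studies: strangers are introduced (in small cages under
video, or in a flight cage wearing proximity sensors), their first
interactions are measured, and their cooperative relationships (allogrooming,
food sharing) are followed for months afterwards.

It is aimed at behavioral ecologists and biostatisticians who need inference
that respects the awkward structure of such data: dyads are not independent
(each belongs to two individuals), not every pair can interact (cage
constraints), and observation effort differs wildly across pairs.

## What it computes

**Small-cage introductions (event logs).** Timed, directed affiliative /
aggressive events are aggregated into dyad totals over a 6-h scoring horizon
(`interactions`). Incidence proportions get exact Clopper–Pearson intervals;
mean event durations get percentile-bootstrap intervals. The inference engine
(`permutation`) fits an aggregated binomial GLM

  logit Pr(behavior second) = α + β·z(first-interaction seconds)

to long-term behavior seconds out of possible seconds, then tests β against a
*cage-constrained permutation null*: each event keeps its actor, class, onset
and duration, but its receiver is redrawn uniformly among the actor's
cagemates (behaviors directed at random within the cage). One-tailed
Monte-Carlo p-values use the add-one convention p = (1 + #{β\* ≥ β̂}) / (m+1).

**Flight-cage introductions (proximity sensors).** Ping streams are segmented
into encounters at a maximum inter-ping gap; an encounter is a *contact* when
its maximum RSSI falls in the dataset-wide top 5% (top 1% for "close
contacts"). Cumulative first-contact minutes are accumulated over half-open
windows [0, W h) for W ∈ {4, 8, 12, 16, 20, 24}, and contact networks are
summarized by density and weighted site assortativity (`contacts`).

**Dyadic count regression (`dyadic`).** Long-term allogrooming minutes are
modeled with a Bayesian negative-binomial multi-membership regression

  y_d ~ NB(μ_d, φ),  log μ_d = log(exposure_d) + α + x_d'β + u_i(d) + u_j(d),
  u_b ~ Normal(0, σ_bat²),

with weakly informative priors, sampled by an affine-invariant ensemble
sampler (differential-evolution moves) on a non-centered parameterization,
with split-R̂ / ESS diagnostics. Slopes on standardized predictors are
reported as percent changes 100·(e^β − 1); variance explained is the per-draw
Bayesian R² = Var(fit) / (Var(fit) + Var(res)), and the share attributable to
first contacts is the R² difference between the full model and the model
without that term.

**Synthetic data (`synthetic`).** Generators emulate both study designs with
planted parameters and a ground-truth ledger (per-dyad event seconds, contact
minutes per window, per-bat random effects), so every stage is testable by
exact ledger checks and parameter recovery.

## Worked example

```python
import numpy as np
from bondtrace import gen_study1, Study1Config, permutation_test
from bondtrace.interactions import incidence_summary

# exact binomial CI for an observed incidence (30 of 35 pairs affiliative)
s = incidence_summary(30, 35)
print(s["percent"], s["percent_lower"], s["percent_upper"])
# 86.0 70.0 95.0   -> "86% (95% CI [70%, 95%])"

# synthetic introduction experiment with a planted slope of 1.0
events, cages, longterm, truth = gen_study1(
    Study1Config(seed=42, effect_affiliative=1.0)
)
res = permutation_test(events, cages, longterm, predictor="affiliative",
                       response="grooming", n_perm=5000, random_state=0)
print(f"observed slope = {res.observed_coef:.3f}")
print(f"null 95% quantiles = [{res.q025:.3f}, {res.q975:.3f}]")
print(f"one-tailed p = {res.p_one_tailed:.4f}")
```

Output:

```
86.0 70.0 95.0
observed slope = 1.105
null 95% quantiles = [-0.222, 1.118]
one-tailed p = 0.0310
```

The observed logit-scale slope (1.105) sits at the upper edge of what the
cage-constrained null produces by chance, so the planted affiliative effect
is detected (p ≈ 0.03); with the default `effect_affiliative=0` the same
pipeline returns p ≈ 0.5–0.9.

A command-line interface wraps the same stages:

```sh
bondtrace generate --study 2 --out runs/s2 --seed 7
bondtrace study2-contacts --pings runs/s2/pings.csv --bats runs/s2/bats.csv
bondtrace report --out runs/full --seed 7     # full synthetic pipeline
```

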
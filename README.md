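# herdtrack

Annual-migration analysis for GPS-collared ungulates: tactic classification
from displacement curves, per-movement migration characteristics, stopover
detection from Brownian-bridge utilization distributions, satellite
phenology (green-up / dry-down), and the variance-comparison /
model-selection inference layer — all exercisable end to end on a bundled
synthetic cohort generator with known ground truth.

It is written for movement ecologists who study partial migration in
northern large herbivores (red deer and similar species) from 2-hourly GPS
collar data, and for anyone who wants a tested, reproducible implementation
of this analysis chain.

## The models at the core

**Tactic classification (net squared displacement).** The displacement
`nd(t)` of each fix from the winter origin is fitted with five candidate
movement models — resident `nd = c`, nomad `nd = β√t`, disperser
`δ/(1+exp((θ−t)/φ))`, migrant `δ/(1+exp((θs−t)/φs)) − δ/(1+exp((θa−t)/φa))`,
and a mixed migrant with a separate return asymptote — ranked by AICc.

**Migration characteristics.** Each seasonal migratory movement is refitted
with its own logistic `nd(t) = δ/(1+exp((θ−t)/φ))`: `δ` is the distance
between seasonal ranges (km), `θ` the mid-date of migration (Julian day),
`φ` the temporal scale (days). Departure = `θ − 2φ`, arrival = `θ + 2φ`,
duration = `4φ`; distance roamed is the sum of Euclidean step lengths within
that window and mean speed the mean per-step speed.

**Stopovers.** The Brownian-bridge movement model turns a migratory segment
into a utilization distribution (motion variance σ²ₘ estimated by odd/even
leave-one-out likelihood); stopovers are the top-25%-of-mass cell clusters
that survive range-overlap and stationarity filters.

**Phenology.** Per-pixel annual NDVI is summarized by the double logistic
`base + a·[1/(1+e^{−mS(t−S)}) + 1/(1+e^{mA(t−A)}) − 1]`; the instantaneous
rate of green-up (IRG) is its spring derivative, peaking at `S` with value
`a·mS/4`; onset-to-peak duration is `ln(2+√3)/mS`.

**Inference.** Brown–Forsythe (Levene) variance tests and Fisher variance
ratios with F-based CIs for season × sex contrasts; log / z-score /
median-centering transforms; an `|r| ≤ 0.3` collinearity screen; exhaustive
candidate sets fitted as mixed models with crossed random intercepts for
animal and year (ML); AICc with the parsimony rule (simplest model within
2 AICc); Nakagawa marginal/conditional R².

## Worked example

```python
import pandas as pd
from herdtrack import synthetic as syn, nsd

truth = syn.TrackTruth(
    animal_id="deer1", sex="F", tactic="migrant",
    winter_center=(10, 10), summer_center=(25, 20),
    spring_theta=124, autumn_theta=260, spring_phi=3, autumn_phi=2,
)
track = syn.simulate_track(
    truth, None,
    pd.Timestamp("2010-01-01", tz="UTC"), pd.Timestamp("2010-12-31", tz="UTC"),
    seed=3,
)
res = nsd.analyze_track(track)
print(res["classification"].tactic)
fit = res["spring_fit"]
print(f"delta={fit.delta:.1f} km, theta={fit.theta:.1f}, phi={fit.phi:.2f} d")
ev = nsd.extract_migration_event(fit, track)
print(f"departure day {ev.departure:.1f}, duration {ev.duration:.1f} d, "
      f"roamed {ev.distance_roamed:.1f} km at {ev.mean_speed:.2f} km/h")
```

prints

```
mixed_migrant
delta=17.9 km, theta=124.0, phi=2.92 d
departure day 118.2, duration 11.7 d, roamed 88.2 km at 0.32 km/h
```

The animal lands in the migratory class (`mixed_migrant` nests the shared
double logistic and often edges it by AICc on noisy tracks;
`nsd.binary_tactic` collapses both onto "migrant"). The recovered distance
between ranges (17.9 km vs the true 18.0), mid-date (124.0 vs 124) and
temporal scale (2.92 d vs 3) match the generating parameters, and the
derived event obeys the definitional identities (duration = 4φ). The 88 km
roamed against an 18 km range separation reflects the tortuosity of the
simulated fix-to-fix path.

The full chain — simulate → clean → migrate → stopovers → phenology →
covariates → report — runs as numbered scripts under `analysis/`, via the
library (`herdtrack.pipeline.run_pipeline`), or from the shell:

```bash
herdtrack run --out results/run --seed 1
```

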
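# pollenforage

Analysis of pollen foraging by social bees from corbicular pollen loads.

Agricultural landscapes offer bees a narrow floral menu, and designing
effective agri-environment schemes (flower strips, field margins) requires
knowing which plants specific pollinators actually use — not just visit.
`pollenforage` implements a complete analysis pipeline for studies that
sample pollen pellets from returning honeybee and bumble bee foragers and
survey the surrounding floral resources:

* **Pellet composition** — per-pellet morphotype grain counts (≈500
  counted grains), the 3% rare-morphotype exclusion, and family-level
  pooling.
* **Foraging metrics** — daily flower constancy (share of trips where one
  morphotype holds ≥ 97% of a pellet), pollen richness *S*, and Simpson
  diversity SDI = 1 − Σ pᵢ² per colony-day.
* **Resource availability** — estimated floral counts (efc): quadrat
  floral totals for wildflowers and crops (alfalfa racemes, corn stalks
  halved from 2 m² quadrats, soybean racemes extrapolated from stem
  subsamples), weighted by each stratum's share of the landscape area, and
  folded into per-survey morphotype availability proportions.
* **Preference inference** — proportion-preserving χ² tables (counts out
  of 500, categories shared with counts > 5 retained at their original
  proportions, the rest pooled into an "other" row) and an
  availability-proportional resampling null model: each pellet's grain
  total is redrawn from a multinomial over availability, and morphotypes
  collected above / below the null's 95% percentile interval are
  classified preference / avoidance.
* **Synthetic studies** — a generator with known constancy, preference
  multipliers and availability weights, emulating the full field design
  (2 species × 3 sites × 5 periods, 150 survey quadrats), so every stage
  is testable without field data.

## Worked example

```python
import numpy as np
from pollenforage import (
    AvailabilityProfile, PreferenceModel, summarize_dataset,
)
from pollenforage.simulate import SpeciesParams, simulate_pellets

avail = AvailabilityProfile("June", {
    "Fabaceae_Tricolporate": 0.45, "Lotus_corniculatus": 0.10,
    "Apiaceae": 0.20, "Asteraceae_Spines": 0.25,
})
# bees that over-collect Lotus 5-fold, otherwise availability-proportional
params = SpeciesParams(constancy_prob=0.3,
                       preference_multipliers={"Lotus_corniculatus": 5.0})
pellets, _ = simulate_pellets(avail, params, n=120, rng=np.random.default_rng(0))

res = PreferenceModel(pellets, avail).fit(n_iter=1000, seed=42)
print(res.summary())
```

```
Availability-proportional null model
  species: honeybee   survey: June
  pellets: 120   grains: 60000
  iterations: 1000   interval: 95% percentile
           morphotype  availability  observed_prop  null_mean  ci_low  ci_high classification
             Apiaceae        0.2000         0.1313     0.2000  0.1968   0.2031      avoidance
    Asteraceae_Spines        0.2500         0.1654     0.2501  0.2465   0.2536      avoidance
Fabaceae_Tricolporate        0.4500         0.3266     0.4499  0.4460   0.4540      avoidance
   Lotus_corniculatus        0.1000         0.3767     0.1001  0.0977   0.1024     preference
```

The bees collected 38% Lotus against 10% availability — far above the
null interval, a clear preference — and correspondingly less of everything
else. `res.plot()` draws the observed-dot / null-interval figure, and
`summarize_dataset` produces the tidy per-colony-day
constancy/richness/diversity table that downstream mixed models consume.

The same operations are available from a thin CLI
(`pollenforage validate | metrics | availability | prefs | simulate`);
`pollenforage simulate --out dir --scale tiny` writes a complete,
mutually consistent input-file suite to play with.

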
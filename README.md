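# coraldemog

Stage-structured demographic modelling of open coral populations on
atolls: how do reef-coral communities recover after mass mortality, how
much external larval supply does that recovery require, and what happens
to coral cover when chronic human pressure and recurrent disturbance are
added on top?

The package is aimed at population ecologists and reef scientists who
want a tested, scriptable implementation of the classic size-based
matrix-projection workflow for corals — from life-table resampling all
the way to 50-year impact-scenario forecasts — without depending on any
particular field dataset: a synthetic-data module generates every input
the pipeline needs from documented assumptions.

## The model

Corals are grouped into three growth-form guilds (arborescent,
branching/encrusting, massive) and five radius-defined size classes
(spat < 1 cm, recruits < 5 cm, juveniles < 10 cm, medium 10–20 cm, large
> 20 cm, open-ended).  Each guild follows the affine recurrence

```
n(t+1) = A n(t) + ν
```

where `n` is the vector of class counts, `A` a 5×5 Lefkovitch matrix
with loops `P_i` on the diagonal, growth rates `G_i` on the
sub-diagonal, optional fertilities at `A[1,4]` and `A[1,5]`, and `ν` a
vector of zeros carrying the year's externally supplied spat in its
first entry — the open-population (larval-connectivity) term.

Under fixed stage durations `T_i`, the probability that a surviving
colony advances out of stage *i* is

```
γ_i = (σ_i^T_i − σ_i^(T_i−1)) / (σ_i^T_i − 1),   G_i = σ_i γ_i,   P_i = σ_i (1 − γ_i)
```

with `σ_i` the annual within-stage survival.  Because literature life
tables disagree, each guild's matrix is the arithmetic mean over 10,000
Monte-Carlo trials that resample every stage's `(σ, T)` pair
independently from a pool of life-table samples.  Without fertility the
matrices are column-substochastic, so the asymptotic growth rate λ
(dominant eigenvalue) is always below one: these populations persist
only through immigration, and with constant supply they converge to the
stationary distribution `n* = (I − A)⁻¹ ν`.

On top of the core projection the package provides

* **elasticities** of λ to every matrix entry, averaged over a
  logarithmic fertility grid, plus a global sensitivity ranking of
  recruitment level vs. timing vs. fertility;
* **hindcast calibration**: an exhaustive (or seeded-subsampled) grid
  search over per-year spat supply, fertility, and post-disturbance
  survival fractions, accepting parameterizations that reproduce an
  observed size distribution to better than 10% in every class, and
  summarizing accepted supply histories as per-year max/min/mode;
* **impact scenarios**: cumulative annual recruitment reduction
  (1 %/yr ⇒ exactly 50% lost by year 50), episodic mass mortality of
  the non-recruit classes every 8 years, their synergy grid, and a
  lagoon/ocean homogenization contrast — all reported through a
  disc-area cover proxy (median class radii 1, 3, 5, 10 cm).

## Worked example

```python
import numpy as np
from coraldemog import (chagos_like_world, generate_recovery_fixture,
                        ImpactScenario, run_scenario)

world = chagos_like_world(rng_seed=1)          # synthetic atoll preset
A = world.matrices["massive"]
print(round(A.lambda_, 3))                     # 0.975  — subcritical

fixture = generate_recovery_fixture(world)     # "observed" post-event data
key = ("lagoon", "massive")
res = run_scenario(A, fixture.observed[key], world.nu_true[key],
                   ImpactScenario(recruitment_loss_rate=1.0,
                                  episodic_mortality=0.5))
print(round(res.retention, 1))                 # 38.2  (% of initial cover)
print(round(res.relative_final_cover, 1))      # 20.2  (% of undisturbed run)
```

The first number says large massive corals die at only ~2.5% per year,
yet the guild cannot maintain itself without larval import (λ < 1).  The
scenario numbers say that fifty years of 50% mortality pulses every
eight years plus a 1 %/yr cumulative recruitment decline leave the
lagoonal massive population at 38% of its starting cover and at about
one fifth of where the undisturbed trajectory would have been.

The same pipeline is scriptable from the shell:

```
coraldemog simulate --seed 1 --out fixture/
coraldemog build-matrices --life-tables fixture/life_tables.csv --trials 10000 --seed 1 --out mats/
coraldemog hindcast --matrix mats/matrix_massive.json --observed obs.csv \
    --pre-disturbance pre.csv --nu-grid 0,100,1000,10000 --out hc/
coraldemog forecast --matrix mats/matrix_massive.json --init obs.csv \
    --nu 1000 --scenario scenario.yaml --out fc/
```

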
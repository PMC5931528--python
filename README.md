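# penguinforage

Quantitative movement and trophic ecology of a central-place foraging
seabird: how intra-specific competition between breeding stages shifts
time budgets, dive depths, foraging density and diet.

The package reimplements, as tested Python, the analysis chain used to
study dietary divergence in gentoo penguins (*Pygoscelis papua*) at a
South Georgia colony across incubation and chick-rearing:

1. **Dive extraction** — 1 Hz time-depth-recorder (TDR) records are
   zero-offset corrected with a running low-quantile surface filter,
   dives detected with a 2 m threshold, foraging trips segmented from
   the wet/dry (temperature) channel, and per-bird time budgets
   (proportion of time at sea *P*, dives per hour) derived.
2. **Stage-comparison models** — linear mixed models in the `nlme`
   tradition: trip durations (√-transform, individual random
   intercept), proportion of time at sea (arcsin √ transform,
   stage-stratified variance), and maximum dive depths (trip nested in
   individual, first-order autoregressive residuals within trips,
   stage-stratified residual variance), all fitted by maximum
   likelihood with backward stepwise deletion via likelihood-ratio
   tests; dive rates via a Poisson model with a log trip-hours offset.
3. **Movement** — a continuous-time correlated random walk (velocity =
   Ornstein–Uhlenbeck process) fitted to irregular GPS fixes by Kalman
   filtering; dive locations imputed with 100 forward-filter
   backward-sampled draws each; densities gridded at 0.005° as

   dives cell⁻¹ day⁻¹ = cell proportion × (pairs × 2) × (P × 24) × dive rate.

4. **Diet** — δ¹⁵N diet classes from a finite Gaussian mixture with BIC
   model selection, and the proportion of crustaceans *p* in the diet
   from a two-source Bayesian mixing model (krill vs pooled fish, with
   a trophic enrichment factor Δ = 2.7‰):

   δᵢ ~ Normal(p(μ_c + Δ) + (1 − p)(μ_f + Δ), p²σ_c² + (1 − p)²σ_f² + σ_res²).

5. **Energetics** — an affine activity budget DEE(P) = (1 − P)·e_land +
   P·e_sea calibrated through the two stage-level (P, DEE) pairs, and
   colony-scale seasonal prey consumption.

Because the original deployment data were not public, the package ships
a first-class synthetic-data generator (`penguinforage.synthetic`) whose
defaults encode the study's reported parameters (dive depths 36.4 m
± stage contrast +17.7 m, within-trip depth autocorrelation 0.47, trip
durations 291/316 min, time at sea 0.162/0.360, dive rates 15.39/13.62
h⁻¹, diet classes 9.54 ± 0.49 and 11.31 ± 0.49 ‰, prey sources from the
reported table). Every analysis is exercised end-to-end on that
generator, with parameter-recovery tests against the generating truth.

## Worked example

```python
import numpy as np
from penguinforage import energetics, isotopes

# activity-budget energetics calibrated through the stage (P, DEE) pairs
rates = energetics.derive_activity_rates(0.162, 405.0, 0.360, 483.0)
print(round(rates.e_land, 1), round(rates.e_sea, 1))
# 341.2 735.1        (kJ kg⁻¹ day⁻¹ ashore / at sea)

cons = energetics.colony_consumption(
    energetics.ColonyParams(pairs=1933, chicks=1604), round_to=10)
print(cons)
# 680.0              (metric tonnes of prey over the 137-day season)

# two-source δ¹⁵N mixing model for the fish-leaning diet class
krill = isotopes.PreySource("krill", 6.55, 0.625, 20)
fish = isotopes.pool_fish_sources(
    isotopes.PreySource("icefish", 11.03, 1.16, 9),
    isotopes.PreySource("notie", 11.06, 1.05, 5))
consumers = np.random.default_rng(1).normal(11.31, 0.49, 6)
res = isotopes.fit_mixing_model(consumers, krill, fish, tef=2.7, seed=1)
print(round(res.posterior_mean, 2), tuple(round(c, 2) for c in res.ci95))
# 0.52 (0.38, 0.64)  (posterior crustacean proportion, 95% CrI)
```

The interpretation: birds in the high-δ¹⁵N mixture class obtain roughly
half their diet from crustaceans, versus >0.9 for the krill class — the
dietary divergence the analysis is designed to detect.

## Analysis walkthrough

`analysis/` holds numbered drivers that run the full chain on a seeded
synthetic study and write their tables under `results/`:

```sh
python analysis/01_simulate_study.py          # generate TDR/GPS/isotope data
python analysis/02_dive_processing.py         # ZOC, dives, trips, budgets
python analysis/03_behaviour_models.py        # stage mixed models + selection
python analysis/04_movement_density.py        # CTCRW, imputation, density maps
python analysis/05_diet_isotopes.py           # mixture classes + mixing model
python analysis/06_energetics_consumption.py  # DEE and colony consumption
```

A config-driven single entry point (`penguinforage all --seed 7 --out
out/`) and per-stage subcommands (`simulate`, `dives`, `trips`,
`budget`, `diet`, `energetics`) are also installed.

## Layout

- `src/penguinforage/` — `synthetic`, `tdr`, `movement`, `models`,
  `isotopes`, `energetics`, `pipeline`, `cli`
- `analysis/` — narrative drivers (above)
- `tests/` — unit, property and acceptance suites
- `docs/methods.md` — model assumptions, parameter choices, numerical
  details and limitations
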
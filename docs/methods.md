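# Methods

This note documents the models implemented in `penguinforage`, the
assumptions behind them, the defaults of the synthetic-data generator,
and the numerical choices that a maintainer or reviewer would want
stated explicitly.

## Dive extraction (`tdr`)

**Zero-offset correction.** Pressure sensors drift, so the recorded
"surface" wanders by up to a metre or two. The correction is a two-pass
running low-quantile filter: the 5th percentile of depth in consecutive
5-minute windows tracks the surface (at the surface most samples sit at
the offset, and even at a dive rate of ~15 h⁻¹ the majority of samples
in any window are surface samples), and a running median over five
windows rejects windows dominated by dive activity. The window-level
baseline is linearly interpolated to sample resolution and subtracted.
Both window length and quantile are exposed. The contract is that the
median of surface-phase depths after correction is within ±0.2 m of
zero; near offset change points the baseline can lag by up to half a
window.

**Dive detection.** A dive is a maximal contiguous run of samples at or
below the threshold depth (default 2 m, matching the standard practice
for this logger resolution). Intervals are sample-closed with an
exclusive end, so a 3-sample run at 1 Hz is a 3 s dive. Dives touching
the record boundary are kept and flagged. No minimum dive duration is
imposed by default (none is biologically warranted at a 2 m threshold);
it would be trivial to filter on `duration_s` downstream.

**Trip segmentation.** Trips are identified automatically from the
temperature channel used as a wet/dry proxy (cold = immersed), with a
dry-gap rule: wet bouts separated by less than 10 min of dry record are
merged, and bouts shorter than 30 min are discarded. Manual inspection
— how such records are traditionally segmented — is not reproducible;
the thresholds here are config-exposed and the defaults recover the
generator's true trips essentially exactly.

**Time budgets.** P = Σ trip durations / deployment span; dive rate =
Σ dives / Σ trip hours. Deployments of 4–11 days yield 5–25 trips per
bird, so per-bird P carries appreciable sampling noise (SD ≈ 0.07);
cohort means are the quantity of interest.

## Movement (`movement`)

The continuous-time correlated random walk models velocity as an
Ornstein–Uhlenbeck process with decay β (s⁻¹) and driving scale σ, and
position as its integral. Filtering runs per axis in a local
equirectangular tangent plane centred on the colony — at the ≤ 40 km
scale of inshore foraging the projection error is negligible. The exact
discrete transition of the (position, velocity) state over irregular
steps is Kalman-filtered against fixes with Gaussian measurement error
(default SD 25 m, estimable); maximum likelihood uses Nelder–Mead on
log-parameters with three starts. The prior on the initial state is
proper (position SD 10 km centred on the first fix, velocity at its
stationary distribution), so the filter likelihood is exactly the joint
Gaussian density of the fixes — the test suite verifies this against a
brute-force dense-covariance oracle at 1e-6.

**Imputation.** Dive locations are drawn by forward-filter
backward-sampling, giving joint trajectory draws rather than
independent marginals: neighbouring dives within one imputation respect
path continuity, which matters when densities are accumulated over
adjacent cells. Dive times outside the GPS span are flagged as
extrapolations.

**Density surfaces.** Imputation draws are binned into half-open 0.005°
cells anchored at the colony. Each cell's dives-per-day value is the
product of the cell's share of draws, birds (pairs × 2), hours at sea
per day (P × 24) and the hourly dive rate; the sum over cells therefore
equals the colony total exactly (asserted in tests). The estimator is
linear in pairs and in P.

**Distance regressions.** √distance (km) is regressed on trip duration
(min) by OLS. The square root is on the *response*: plugging the stage
mean durations into √D = a + b·t reproduces the stage mean distances,
whereas reading the transform on duration does not — the implementation
follows the reading that is internally consistent.

## Stage-comparison models (`models`)

The mixed models use exactly the covariance families the analyses need:
random intercepts for individual or trip-nested-in-individual, AR(1)
residual correlation within trips (successive dives reach similar
depths), and residual variances stratified by breeding stage. Fits are
maximum likelihood — not REML — so likelihood-ratio tests of fixed
effects are valid, and backward stepwise deletion drops the least
significant term while p > α (default 0.05).

Implementation: within each trip the data are whitened against the
AR(1) correlation (O(n)); random intercepts enter through the Woodbury
identity on a (1 + trips) system per individual; the global residual
scale is profiled analytically. What remains is a ≤ 4-dimensional
Nelder–Mead over relative variance ratios and atanh(φ), with three
deterministic starts. A dense multivariate-normal oracle in the test
suite confirms the structured likelihood to 1e-6. Fixed-effect SEs come
from the GLS information matrix; with a single stratum and no random
terms the fit reduces exactly to OLS.

Back-transformed stage means are inverse transforms of the fitted
linear predictor — under √ or arcsin √ transforms these are medians,
not means, of the response distribution.

Variance-component "shares" are reported as σ²_component / (σ²_ind +
σ²_trip + σ̄²_residual); the proportion of individual variance explained
by a covariate is (σ²_ind,without − σ²_ind,with)/σ²_ind,without,
floored at zero.

The two-group GLS comparisons (δ¹⁵N by stage; morphometrics by diet
class) are closed-form ML: group means, divisor-n variances, an
iteratively reweighted common-mean fit for the mean-equality LR under
heteroscedasticity, and a Bartlett-style LR for variance homogeneity.
Simulation shows both tests hold their nominal 5% size at n = 25 per
group within [0.03, 0.07].

Dive rates use a Poisson GLM of dives per trip with log(trip hours) as
offset (statsmodels); exponentiated coefficients are hourly rates.

## Diet (`isotopes`)

**Mixture classing.** One-dimensional Gaussian mixtures are fitted by
EM for K = 1..3 under equal- and unequal-variance modes, with seeded
k-means++-style initialisation, 10 restarts, a variance floor of 1e-4
(‰²) against degenerate spikes, and a monotone log-likelihood assertion
on every fit. Model selection minimises BIC = −2ℓ + k·ln n. Components
are canonically ordered by mean. At the study's configuration (n = 32
with a 6-sample minority class 3.6 SD away) BIC prefers two classes in
roughly two thirds of replicates — a genuine property of BIC at this
sample size, reproduced by the reference R implementation — so
class-level summaries should be read conditionally on a second class
being found.

**Mixing model.** The two-source model treats a consumer group's δ¹⁵N
as draws from a Normal whose mean is the p-weighted mix of the
TEF-shifted sources and whose variance propagates source SDs plus a
residual term: p ~ Uniform(0, 1), σ_res ~ half-Normal(1‰). TEF is fixed
at 2.7‰ by default (TEF uncertainty is config-exposed and defaults to
zero). One shared p is estimated per group, matching group-level
reporting. Two posterior routes are implemented: an emcee ensemble
sampler (16 walkers, 1000 burn + 3000 draws, split-R̂ checked) and a
deterministic quadrature over (p, σ_res) used for cross-checks and for
the 500-replicate credible-interval calibration, which shows 95%
intervals covering the generating p at ≈95%. The closed-form
mass-balance estimate p* = (μ_f + Δ − δ̄)/(μ_f − μ_c) serves as an
oracle: with the residual term and priors disabled the posterior mean
matches p* to within 0.01 for interior consumer means. Near the p = 1
boundary the truncated prior shrinks the posterior mean below p*
(e.g. an incubation-type group with p* ≈ 0.96 posts ≈ 0.95) — expected
behaviour of a bounded parameter, not a defect. Fish sources are pooled
with n-weighted means and combined within-plus-between sums of squares.
δ¹³C is carried through I/O but never modelled.

## Energetics (`energetics`)

DEE(P) = (1 − P)·e_land + P·e_sea. The two activity rates are not free
parameters: they are calibrated exactly through two known (P, DEE)
pairs (0.162 → 405, 0.360 → 483 kJ kg⁻¹ day⁻¹), giving e_land = 341.2
and e_sea = 735.1. This affine activity budget is the minimal model
consistent with those two points; any stage-specific mass or dive-cost
structure in the original calibration equations is absorbed into the
two rates. Colony consumption is (pairs × 2 × 1.1 kg day⁻¹ × 137 d +
chicks × 60 kg)/1000 tonnes, linear in every argument.

## Synthetic data (`synthetic`)

The generator emulates exactly the statistical structure the analyses
assume, with defaults set to the study conditions:

| parameter | incubation | chick-rearing | basis |
|---|---|---|---|
| dive depth mean (m) | 36.4 | 54.1 | reported stage means |
| dive depth SD (m) | 12.0 | 12·√1.8 ≈ 16.1 | ratio reported; base SD chosen (see below) |
| depth AR(1) φ | 0.47 | 0.47 | reported |
| trip duration (min) | 291 ± 60 | 316 ± 60 | means reported; SD chosen |
| P(at sea) | 0.162 | 0.360 | reported |
| dive rate (h⁻¹) | 15.39 | 13.62 | reported |
| diet classes (‰) | — | 9.54 ± 0.49 (26), 11.31 ± 0.49 (6) | reported |
| prey sources (‰) | — | krill 6.55 ± 0.625 (20), icefish 11.03 ± 1.16 (9), notie 11.06 ± 1.05 (5) | reported |

Choices where no value is reported, made once: base depth SD 12 m (keeps
the 2 m-threshold truncation bias on the mean far below the recovery
tolerance while spanning a realistic depth range); trip-duration SD
60 min (the reported SE of 0.91 min implies a between-trip SD far too
small to be a trip-level dispersion; 60 min is realistic for this
forager); individual and trip random intercepts on depth of 4 and 5 m
(these give individual/trip variance shares of ≈9% and ≈14%, close to
the reported 10%/17.6%); the fish diet class dives 10.68 m deeper;
CTCRW β = 1/300 s⁻¹ and σ = 0.065 (stationary speed ≈ 0.8 m s⁻¹,
per-trip maximum displacement of order 5–6 km); GPS error SD 25 m with
fixes every 180 s; surface offset piecewise-constant in ±1.5 m changing
every 3 h; depth sensor noise SD 0.05 m.

Structure: deployments of 4–11 days alternate exponential shore bouts
with truncated-normal trips, the shore mean set so the long-run at-sea
fraction equals P. Dives occur at the stage rate within trips (Poisson
count, slotted placement so trapezoidal descent–bottom–ascent profiles
never overlap); maximum depths follow a stationary AR(1) floored at
2.5 m. GPS tracks are CTCRW paths bridged (by endpoint detrending) to
start and end at the colony. The temperature channel is a wet/dry proxy
(2 °C at sea, 20 °C ashore, noise 0.5 °C). All randomness flows through
per-bird child streams of one master seed (`SeedSequence`-based), so a
given seed yields a byte-identical study on any platform.

What the generator does **not** emulate: bathymetry or land avoidance,
behavioural states within trips, diel rhythms, tidal or seasonal
trends, device effects on behaviour, prey patchiness, or any coupling
between dive depth and horizontal position. Passing recovery tests
therefore demonstrates that the estimators recover the parameters of
this statistical structure at the study's sample sizes — not that the
pipeline is robust to every failure mode of field data.

Edge-effect note: starting each deployment ashore (loggers start before
dawn departure) and clipping the final bout at recapture biases the
realised at-sea fraction slightly below its long-run value (≈0.005 at
these settings); this is a property of finite deployments, shared by
the real sampling design.

## Problem sizes

The test and acceptance runs use the study's own design sizes: 25 birds
per stage for cohort recoveries (~35k dives across ~480 trips for the
depth model), 16 + 16 plasma samples, 100 mixture replicates, and
500 quadrature replicates for mixing-model calibration. Unit tests use
smaller cohorts (8–12 birds) where only correctness, not precision, is
at stake.

## Known limitations

- The AR(1) moment structure is estimated within trips; trips with very
  few dives contribute little information and the per-trip-centred
  moment estimator is biased low by O(1/n) (the mixed model, which
  estimates φ jointly with the random effects, is not).
- The mixing model is strictly two-source and single-isotope; with
  consumer means outside the enriched source interval the posterior
  piles against a boundary and the mass-balance oracle is clipped.
- `compare_groups_gls` mean-difference sign follows first appearance
  order of the group labels in the input.
- The CTCRW bridge used for simulating trips is an endpoint detrend,
  not the exact conditioned integrated-OU bridge; fitted parameters on
  bridged tracks are therefore mildly attenuated, and parameter-recovery
  tests use free (unbridged) tracks.
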
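# Methods

This note documents the models behind `fmrcal`, the parameters that
matter, what the synthetic-data generator does and does not emulate, and
the numerical and design choices that were genuinely open.

## Acceleration processing

Raw tri-axial acceleration (surge *x*, sway *y*, heave *z*, in *g*, 25 Hz)
is split into a static component — a centred running mean per axis — and a
dynamic residual. VeDBA is the per-sample Euclidean norm of the dynamic
components; the absolute-sum variant (ODBA) is provided only as a
cross-check because the vectorial form is invariant to device orientation,
which matters for tail-mounted loggers that cannot sit on the body's
centre line.

* **Smoothing window: 2 s (configurable).** Conventional dynamic-body-
  acceleration practice uses 1.5–3 s; 2 s comfortably exceeds one wingbeat
  period (~0.3 s at 3.5 Hz) while tracking posture changes.
* **Edge policy: truncated window, no padding.** This keeps the identity
  `static + dynamic = input` exact at every sample, which the tests rely
  on.
* **Gaps** larger than two sample intervals split a record into segments;
  summary statistics combine segments duration-weighted. Gaps are flagged,
  never interpolated.

## Behaviour classification

One spectral frame per second: a Morlet continuous wavelet transform of
the dynamic heave signal over 12 log-spaced bands between 0.5 and 12 Hz,
amplitudes averaged within the second, plus the second's RMS. The CWT is
evaluated in 600-s chunks padded by the support of the largest wavelet
(16 s at 0.5 Hz), so chunking is numerically invisible.

Frames are standardized and over-clustered with k-means (k = 12), then
clusters map onto provisional classes by ordered heuristics: mean RMS ≥
1.8 g → dive; spectral peak in the 2.5–5 Hz wingbeat band with RMS ≥
0.5 g → flapping; everything else → "low". GPS rules resolve the low
seconds: speed ≥ 10 km h⁻¹ → gliding, slower seconds → resting, split into
land vs sea by a 500-m colony radius. Dive bouts (gap-merged at 2 s) are
typed by the behaviour found in a 5-s lookback: flight → plunge dive,
surface rest → duck dive. A dive at the very start of a record cannot be
typed and defaults to plunge — the dominant dive mode of plunge-diving
sulids — with a warning.

k, the mapping thresholds, the speed threshold and the colony radius are
declared configuration, not estimates: over-clustering followed by
many-to-one mapping is the standard unsupervised-ethogram workflow, and
all values are logged with the run.

## GPS trips and day/night

An iterative speed filter removes fixes implying point-to-point speeds
above 85 km h⁻¹ (above sustained gannet flight speed), never dropping the
first or last fix. A foraging trip is a maximal run of fixes beyond the
colony radius; trip distance sums great-circle legs (sphere radius
6371 km) *including* the two commute legs that cross the radius, so a
50-km-out-and-back track measures ~100 km. Trip accounting clips to the
DLW sampling window (equilibration sample → final sample).

Day/night apportionment uses the NOAA solar-position equations at the
standard 90.833° sunrise/sunset zenith; every interval is cut at the
solar events it spans and each piece classified by the solar elevation at
its midpoint, so day + night always equals the interval length. An
independent low-precision solar ephemeris in the test suite agrees to
well under two minutes at the colony's latitude. Polar day/night raises an
error; the method is not applicable there.

## DLW energetics

Enrichments are handled in ppm. The chain: injectate enrichment
back-calculated from diluted subsamples; initial body-water pool N from
the ¹⁸O dilution space by the plateau method,
`N = dose·(E_inj − E_eq)/(E_eq − E_bg)`; final pool proportional to final
body mass; fractional turnovers `k = ln(excess_eq/excess_fin)/Δt`; CO₂
production from the single-pool model with 25% evaporative water loss,

    rCO₂ [mol day⁻¹] = (N/2.078)(k_o − k_d) − 0.0062·k_d·N,

converted at 22.4 L mol⁻¹ and an energy equivalent of **27.97 kJ L⁻¹ CO₂**
(RQ ≈ 0.8, mixed fish diet; configurable — published seabird work uses
26.4–28.5 depending on assumed diet). The pool entering the CO₂ equation
is the mean of the initial and final ¹⁸O spaces. Elapsed time runs from
the **equilibration** sample to the final sample — the first
isotope-bearing sample is the natural zero point of the washout clock, and
the same convention divides EE into a daily rate.

Error behaviour worth knowing: with measurement noise at 1% of the initial
excess on all four measured enrichments, and study-typical turnover
(k_o·Δt ≈ 1.3, (k_o − k_d)/k_o ≈ 0.3), straight propagation gives a
per-bird 1σ EE error around 10%; the cohort mean is correspondingly
tighter (~2–3% at n = 15–40). The tests therefore pin the noise-free round
trip per bird (0.1%) and the noisy recovery at cohort level (5%).

## Activity coefficients and at-sea partitioning

The additive model `EE = Σᵢ Cᵢ·Tᵢ` over the six behaviours is fitted by
**no-intercept** least squares: a bird spending zero time in every
behaviour must expend zero energy, and the additive form has no constant
term. An intercept variant exists behind a flag for sensitivity analysis.
Two predictor bases are implemented — time in hours (default; the model's
units `kJ h⁻¹ × h` close only then) and activity-specific VeDBA sums — and
can be compared on the same cohort.

At-sea energy: **S1** subtracts the fitted land cost `C_land·T_land` from
the DLW total (conservation holds by construction); **S2** subtracts
`c_day·T_land,day + c_night·T_land,night` using externally published
on-land rates. The package ships **no default** day/night constants:
published values are colony- and year-specific, and S2 refuses to run
without explicit numbers. Birds whose published-constant land estimate
reaches their DLW total are flagged and excluded listwise from S2
regressions only. In the analysis scripts the supplied constants
(80/45 kJ h⁻¹) are deliberately offset from the generator's flat 55 kJ h⁻¹
truth, mimicking the borrowed-constants situation.

Identifiability: dive behaviours occupy ~2% of a deployment, so their
coefficients carry standard errors in the thousands of kJ h⁻¹ at realistic
noise — the fit reports this honestly rather than regularizing it away.
The per-behaviour fit table (estimated activity energy vs activity VeDBA
sum) returns R² ≈ 1 on synthetic cohorts because the generator gives each
behaviour a fixed expected VeDBA rate; on real data, within-behaviour
intensity variation would lower these, most for dives.

## Calibration models

OLS with intercept via statsmodels, reporting R², F with (k, n−k−1)
degrees of freedom, and p. Stepwise selection is bidirectional on AIC from
the VeDBA-only base model; the VeDBA term is protected (every model of
interest contains it; a flag releases it). Candidates: total distance,
dive rate, body mass, proportion of the period at sea, tarsus; at-sea
models use the night-at-sea proportion instead of the at-sea proportion.

## The synthetic-data generator

The generator is the study's ground-truth mirror, not a physical
simulation. It emulates:

* a semi-Markov ethogram with exponential dwell times and central-place
  structure — colony blocks (mean 12 h) alternating with trips (mean 13 h)
  that interleave flight phases (mean 700 s; flapping/gliding sub-bouts of
  60/24 s) with surface-rest phases (mean 1550 s), trips closing with a
  homeward flight; plunge dives enter from flight, duck dives from
  surface rest (~2 of each per at-sea hour);
* behaviour-specific accelerometry: per-bout phase-continuous heave
  sinusoids (flapping 3.5 Hz at 2.2 g; dives 2-s bursts at 3 g; rest/glide
  low-amplitude) on gravity-consistent static orientations, plus white
  noise (0.05 g per axis);
* GPS at 2-min intervals along a random radial bearing at 45 km h⁻¹ while
  flying, drifting while resting, with 10-m fix noise;
* isotope records by exact inversion of the single-pool model: water
  turnover k_d fixed at 0.30 day⁻¹, k_o solved from the true energy
  budget, pool from a 60% total-body-water fraction, enrichments following
  exponential washout with Gaussian measurement noise (2 ppm default,
  ~0.3–0.5% of the initial excesses — ~2% median EE error per bird).

True energy rates default to flapping 360, gliding 240, rest-at-sea 140,
rest-on-land 55, plunge 580, duck 480 kJ h⁻¹ — ordered and scaled to give
a cohort daily expenditure around 3,200–3,500 kJ day⁻¹ at the default
activity mix, the realistic range for a ~2.6-kg breeding sulid. Between-
bird heterogeneity (lognormal multipliers, CV 0.35, on dwell means and
trip length) reproduces the individual variation in activity mix that
makes the activity coefficients identifiable in real cohorts; without it
flapping and gliding times are nearly proportional across birds and the
design is effectively rank-deficient.

Not emulated: aerodynamics/hydrodynamics, depth, weather, prey capture,
preening and other sub-second behaviours, within-behaviour intensity
variation, and any systematic DLW biases (isotope fractionation, pool-size
model error). Passing tests therefore demonstrate internal consistency of
the chain and statistical calibration of the estimators under the stated
noise model — not field accuracy for any particular species.

## Problem sizes in tests and the acceptance script

Unit and property tests run on deployments of 6–12 h with colony/trip
blocks shortened proportionally (per-second classification accuracy does
not depend on record length). The acceptance script runs the energetics
chain on the full study conditions — 15 birds × 74 h at 25 Hz — with
activity budgets taken from the generator's labels (the classifier's
accuracy is measured separately on full wavelet + k-means runs of two 8-h
birds), the DLW round trip on 10 noise-free and 40 noisy records, and the
coefficient-coverage Monte Carlo on 500 cohorts of 15 birds.

## Known limitations

* The glide-vs-rest speed rule inherits the 2-min GPS resolution; seconds
  near trip phase changes are the classifier's dominant error mode.
* Dive-type assignment needs an intact pre-dive context; dives at record
  boundaries default to plunge with a warning.
* Coefficient coverage in the Monte Carlo sits at the nominal ~92% of the
  2-SE t-interval (df = 9); individual behaviours can dip to ~89% by
  binomial fluctuation over 500 replicates.
* The stepwise search inherits AIC's ~16% single-candidate type-I rate;
  selected covariates on noisy cohorts should be read accordingly.
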
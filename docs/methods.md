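# Methods

## Exposure model

The dosimetry layer is a free-space far-field model. The antenna (0.0891 W
at the input, gain taken as exactly 7 dB, 2.4 GHz carrier) is treated as a
point source with linearised gain, so the incident power density is
`S(r) = P_A·10^(G/10)/(4πr²)` and the cage average over the occupiable
interval `[r₀, r₁]` along the beam axis is the one-dimensional line average
`P_A·10^(G/10)/(4π r₀ r₁)`. Reflections and multiple scattering off the
room and cage hardware are deliberately ignored; the model is an estimate
of the direct illumination only, and is validated in the tests against
adaptive quadrature of the pointwise density (relative error < 1e-9).

Whole-body averaged SAR uses the empirical scaling
`SAR = (k/f_GHz)·⟨S⟩·⟨L⟩/⟨m⟩`. The coefficient is stored as
`k = 5.954e-2` in `DosimetryConstants` and is overridable: at this scale
the model reproduces the study setup's reported cage-average SARs
(0.0076 W/kg for the presenile placement, 0.0059 W/kg for the
juvenile/adult placement) from its reported densities and plausible rat
masses and lengths, whereas a coefficient two orders larger would place
those same configurations a hundredfold higher, inconsistent with any of
the summaries. Users fitting other phantoms or frequencies should supply
their own coefficient.

Geometry defaults: the cage-occupiable depth along the beam is 0.375 m
(the long dimension of the 480 × 210 × 375 mm cages), which reproduces the
two reported cage averages within 2% (computed 0.598 vs reported
0.605 W/m²; computed 0.309 vs 0.31 W/m²). Cohort mean masses come from the
baseline body-weight means (0.49155 kg presenile; 0.2484 kg pooled
juvenile+adult). Mean animal lengths are **not** published; the defaults
0.25 m (presenile) and 0.19 m (juvenile/adult) are working assumptions,
carried in the configuration and flagged `mean_length_is_assumed` in every
dosimetry report.

Known small discrepancies, left unresolved on purpose: the reported
worst-case density for the 20 cm placement (0.91 W/m²) computes to
0.89 W/m² with a gain of exactly 7 dB (the gain was quoted as "~7 dB"),
and the reported minimum density 0.13 W/m² corresponds to no stated cage
boundary under this geometry. Neither quantity affects the cage averages.

The far-field criterion (one free-space wavelength, c/f ≈ 12.5 cm at
2.4 GHz) is advisory: the presenile cage near edge sits at 12 cm, right at
the boundary, so `sar_range` emits a `FarFieldWarning` rather than
refusing — the setup itself operated there.

ICNIRP checking is inclusive at the boundary (SAR or density exactly at
the limit is compliant). The verdict uses the cage-averaged SAR and
density, which is what the whole-body limits are written for; the quoted
density margin uses the worst-case near-edge density, the conservative
figure (≈ 4× for this setup).

## Synthetic cohorts

The generator emulates the *statistical* structure of the published group
summaries; dispersions printed in those summaries are treated as
per-animal standard deviations, not standard errors — at n = 10 a cell
like 28.9 ± 15.4 s is only interpretable as an SD (an SE of 15.4 would
imply a per-animal SD near 49 s on a 60 s-capped variable). This reading
governs every draw below.

* **Body weight.** Baseline ~ Normal(mean, sd) truncated to positive;
  week t adds an independent Normal increment with mean equal to the
  printed consecutive-mean difference. Trajectories are therefore
  autocorrelated, and increments can be negative (the presenile exposed
  group declines in its final week). The increment SD is
  `sqrt(sd_t² − sd_{t−1}²)` when the printed cross-sectional variance
  grows, so the weekly spread tracks the tables; when the printed variance
  shrinks (independent increments cannot remove variance) a floor of
  0.1·sd_t keeps trajectories noisy without biasing means.
* **Temperatures.** Independent Normals truncated to the physiological
  band [30, 42] °C; at the published means and SDs the truncation is
  ≥ 3σ away, so means are recovered essentially unbiased.
* **Organs.** A weight-coefficient draw (% of body weight, truncated
  positive) multiplied by the terminal body weight, so regenerating the
  coefficient from stored masses returns the draw exactly.
* **Water maze.** Days {1, 2, 3, 4, 7}, four 60 s trials per day (the
  habituation day produces no records). Per trial, success is Bernoulli
  with the published per-day success percentage / 100, i.i.d.; successful
  latencies come from a Normal truncated to (0, 60) s whose
  *post-truncation* first two moments are root-found to equal the
  published cell (see below); failures are stored censored at exactly
  60 s. A failed trial is additionally flagged as passive swimming
  (drifting until rescue) with probability 0.50 / 0.35 / 0.25 / 0.15 /
  0.10 on days 1/2/3/4/7 — a stylized decaying pattern matching the
  qualitative account (passivity concentrated on day 1 and fading), not a
  reconstruction of the individual-animal roster, which is not machine
  readable in the source tables.

Moment matching solves for (location, scale) by nested bisection: for each
scale the location matching the target mean is bracketed and solved by
Brent's method (the truncated mean is strictly increasing in location),
and the post-truncation SD of that mean-matched family increases with
scale towards the uniform limit, so a second Brent solve pins the scale.
Solutions are verified to 1e-6 in both moments and cached per cell;
unattainable cells (e.g. an SD at or beyond half the interval width) raise
`MomentMatchError` naming the offending values. Sampling uses vectorised
rejection from the parent Normal, which is exact for the truncated law and
deterministic given the generator state.

Animal identifiers follow the study's ear-tag scheme "cage–number";
presenile cohorts split 5 + 5 across their two cages, exposed arms in
odd-numbered cages.

What the generator does **not** emulate — and hence what passing tests do
not establish about real animals: within-animal correlation across
endpoint families (weight, temperature and maze performance are drawn
independently), day-to-day latency correlation within an animal beyond the
day calibration, feed/water intake and energy balance, circadian
temperature structure, swim paths (latency-level simulation only), and the
source tables' irregular success-percentage denominators (55.5%, 63.6%,
97.7% imply 36- or 44-trial denominators rather than 10 × 4; the
percentages are used as per-trial probabilities as printed). Calibration
recovery results certify the generator against its own targets, not the
biology.

## Endpoints

Weekly gain is the difference of consecutive group means (identically the
mean of per-animal gains, which supply the dispersion); gains telescope to
final − baseline. Organ coefficients are `100·organ/body` on terminal
weight. The core–surface differential subtracts skin from rectal group
means per timepoint. MWM daily summaries average *successful* latencies
only, per the study's definition of "average time of successful swims";
the success percentage uses exact integer counts before the one division.
Days with zero successes carry an explicit `latency_defined = False` flag
rather than a silent NaN convention. An all-trials latency average
(counting censored 60 s failures) is deliberately not the default
anywhere.

## Statistics

The Mann–Whitney U statistic is computed from mid-ranks; the reported U is
that of the first sample, so U(x, y) + U(y, x) = n₁n₂. Exact two-sided
p-values enumerate the null distribution of U by a dynamic programme over
rank subsets (counts of subsets of {1..n₁+n₂} of size n₁ by rank sum,
exact integer arithmetic) and use the convention

    p = min(1, 2·min(P(U ≤ u), P(U ≥ u)))

stated explicitly because two-sided conventions differ between packages.
`auto` uses the exact path for tie-free samples with n₁, n₂ ≤ 12 and
otherwise a normal approximation with tie-corrected variance and an
optional continuity correction (on by default; which variant the study's
software used is not stated, so it is a flag). With ties present the exact
path falls back to the approximation — exact conditional tie handling is a
different test and is not claimed. The exact distribution is cached per
(n₁, n₂), which is what makes the 10,000-replicate null simulation in the
test suite cheap.

Comparisons are run per endpoint × age group × timepoint at raw α = 0.05
with no multiple-testing correction, mirroring the study's reporting; a
Holm adjustment is available but off by default. MWM comparisons use each
animal's mean successful latency per day; animals with no success that day
drop out of that day's sample (so n may fall below 10). Significance is
strict: p < α.

## Determinism and problem sizes

Every stochastic step flows from `numpy.random.Generator`. The pipeline
spawns one child seed per cohort from
`SeedSequence([master_seed, age_index, arm_index])`, so a cohort's data
never depend on which other cohorts are in the run; manifests record the
config hash, child seeds and sha256 of every output, and reruns are
byte-identical. Validation problem sizes, chosen to give comfortable
Monte-Carlo resolution: calibration recovery uses 200 cohorts per arm with
a 3-standard-error per-cell criterion; the day-1 latency recovery uses 500
cohorts; the null rejection-rate checks use 10,000 two-sample draws (test
level) and 200 paired-cohort replicates (pipeline level); the
exact-vs-enumeration equivalence is exhaustive for all n₁, n₂ ≤ 7.

## Limitations

The dosimetry is a planning model, not a field solver: no anatomical
phantom, tissue dielectrics, near-field correction or scattering. The SAR
coefficient is adopted, not derived here. The synthetic cohorts cannot
reproduce the study's per-comparison p-values (those depend on the
unavailable raw data); with each arm simulated from its own published
means, some synthetic contrasts are significant by construction wherever
the printed means differ — the type-I behaviour of the machinery is
instead certified under same-calibration null simulations.
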
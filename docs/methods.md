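# Methods

This note records the models behind each stage, the defaults and why,
the numerical choices, and what the synthetic tests do and do not
demonstrate about field data.

## Data model

Two streams per deployment, on one clock (seconds since deployment
start): GNSS at a nominal 5 Hz (position in decimal degrees, Doppler
velocity as east/north components in m/s, vertical displacement in m)
and triaxial body-frame acceleration at a nominal 100 Hz (lateral,
longitudinal, dorsoventral, m/s²). Internally everything is SI; degrees
and g exist only at the file boundary. Headings are azimuths in radians,
clockwise from north in [0, 2π); wind directions use the meteorological
coming-from convention in every public output. A GNSS gap larger than
3× the nominal interval splits the record into segments and no event
may span a segment boundary; the same rule truncates a floating window
used for wave estimation.

The vertical-displacement datum is irrelevant: only the high-passed
signal is used, so absolute altitudes are unsupported outputs.

## Take-off detection

Horizontal speed is smoothed by a centred moving average over a window
specified in **seconds** (default 0.4 s) and converted to samples at the
native rate. A take-off is an upward crossing of `speed_threshold`
(default 4 m/s) preceded by at least `min_floating` (30 s) below the
threshold and followed by at least `min_flight` (30 s) at or above it;
crossings failing either rule are the "very short flights" and are
dropped. Because soaring flight occasionally dips under the line, a
below-threshold dip shorter than 5 s does not split a flight
(hysteresis); a sustained 30 s below the line is a landing and opens the
floating window of the next event. Floating in the source data is
typically below 2.5 m/s; that figure is diagnostic only — the operative
rule uses the 4 m/s line plus the context rules. Eligibility flags:
wind estimation needs ≥ 5 min of flight, wave estimation ≥ 15 min of
floating.

## Wind from the flight track

For a bird flying at roughly constant air speed Va in a horizontally
uniform wind (Vw, blowing toward φ_t), ground speed over flight
direction θ is V(θ) = Va + Vw·cos(θ − φ_t): maximal in tailwind,
minimal in headwind. Writing V = a + b·cosθ + c·sinθ makes the fit
exact linear least squares — no initialisation or convergence issues —
with Vw = √(b² + c²) ≥ 0 by construction, φ_t = atan2(c, b), and the
reported coming-from direction φ_w = φ_t + π. Samples: [t_takeoff + 10 s,
t_takeoff + 5 min), direction atan2(v_east, v_north), samples slower
than 0.5 m/s dropped (undefined direction).

Reliability: Gaussian least-squares AIC, AIC = n·ln(RSS/n) + 2k with
k = 4 for the sinusoid (Va, Vw, φ, σ) and k = 2 for the best constant
fit; the estimate is kept when AIC_const − AIC_sin ≥ 2 and the headings
span at least 90° of azimuth (below that the sinusoid is barely
identifiable and the estimate is flagged). The 5 Hz samples are serially
correlated and are deliberately not decimated or down-weighted; the
ΔAIC ≥ 2 margin absorbs the resulting optimism, and `decimate` knobs
were judged not worth the configuration surface. Assumptions worth
remembering: constant wind and air speed over the 5 min window, and
enough heading diversity — both hold for dynamic-soaring tracks but can
fail for straight commuting flight (flagged by the coverage check).

## Waves from floating motion

While floating, the bird rides the surface, so its vertical GNSS
displacement tracks the surface elevation plus low-frequency GNSS
drift. The estimator resamples the floating window (floating start to
10 s before take-off; optionally only the last N seconds) to a uniform
grid, applies a 4th-order recursive high-pass at 0.07 Hz forward and
backward (zero phase, so crossing times are not biased; the stated
−3 dB point applies per pass), splits the record at upward zero
crossings (a sample exactly at zero counts as non-negative; crossing
times refined by linear interpolation to reduce 5 Hz discretisation
bias in periods), and reports Hs as the mean crest-to-trough height of
the highest ⌈n/3⌉ waves. At least 30 individual waves are required — a
floor corresponding to ~15 min of 30 s swell — otherwise the estimate
is refused with the count.

Height-domain Hs and the variance-domain 4·σ definition agree only for
a narrow-band Rayleigh sea; on the generator's moderately broad spectra
the zero-crossing estimate runs ~4–7% below 4·σ, which is physics, not
a bug, and is covered by the cross-check test tolerance.

## Running and flapping from acceleration

Sea-surface running drives the legs asymmetrically and appears as a
sub-0.2 s-period burst in lateral acceleration; wing flapping lives at
0.25–0.4 s and can leak into the lateral channel on a tilted mount, so
the running detector uses only the high-frequency band: zero-phase
band-pass 5–20 Hz (band edges are configurable — the upper edge stays
under Nyquist margin, the lower edge above the flap band), centred
sliding variance over 0.6 s, threshold at 2% of the peak variance
within ±20 s of the take-off moment (a window bracketing the longest
plausible run with margin). The contiguous above-threshold stretch
containing the take-off is the running phase; an interior quiet gap
ends it. Two refinements:

* a centred sliding variance of a sharp-edged burst crosses a
  2%-of-peak level about (0.5 − 0.02)·0.6 s ≈ 0.29 s *outside* each
  true edge; the reported bounds are pulled inward by that amount,
  removing a systematic +0.58 s duration bias;
* a purely relative threshold cannot express "no burst" (on flat noise
  2% of the peak is below every sample), so the peak must also exceed
  5× the window's median variance or the no-running flag is returned.

Lift-off speed Vr is the GNSS speed at the sample nearest the running
end; take-off direction θ_t is the azimuth of the vector-mean velocity
over the phase (not the mean of angles); cruising direction is the
great-circle bearing from the take-off position to the position 5 min
later.

Flaps are counted in the dorsoventral channel band-passed to
1.8–4.0 Hz. A flap is a peak with prominence ≥ 6× the median absolute
deviation of the band-passed signal during floating (self-scaling to
each deployment's noise floor; the factor was fixed once on synthetic
data) and height ≥ 10× that MAD (so a lone noise excursion cannot
register as a single flap). Counting starts 0.2 s before the detected
running end (absorbing segmentation jitter — nothing but noise precedes
the train in the dorsoventral channel) and stops at the first
inter-flap interval over 0.5 s. Filter ringing at the train edges
produces spurious peaks at 30–40% of the flap amplitude; candidates are
gated at 45% of the median strong-peak height before chaining. Both
signal polarities are searched and the longer chain kept, making the
count invariant to an upside-down mount. Flapping *during* the run is
not counted — the dorsoventral signal there mixes leg and wing motion.

Flap frequency is the peak of time-averaged Morlet continuous-wavelet
power over 1–5 Hz across the bout; bouts under 3 flaps get no
frequency, and frequencies outside 1.8–4.0 Hz are flagged out-of-range
and excluded from downstream statistics.

**Resolution limit:** the 1.8–4.0 Hz band-pass smears a 1–2 cycle train
into a packet whose edge lobes are not separable from genuine flaps by
amplitude, so counts of 1–2 carry ±1 uncertainty; counts of 0 and ≥ 3
are exact on clean signals.

## Joined statistics

Lift-off air speed: Va = Vr + Vw·cos(θ_t − φ_w) — headwind adds the
full wind speed, tailwind subtracts it. Headwind bias of take-off
directions is tested with the v-test (modified Rayleigh):
V = mean cos(θ − μ₀), u = V√(2n), p from the standard normal upper
tail. Environmental effects on each effort metric are fitted as linear
mixed models with a per-bird random intercept, estimated by maximum
likelihood (not REML — fixed-effect sets differ between compared
models) with AIC = −2·llf + 2(k_fixed + 2); p-values are
likelihood-ratio chi-square against the null. Condition categories use
the density modes of a Weibull fitted to wind speed (λ((k−1)/k)^{1/k};
a shape k ≤ 1 has no interior mode and demands explicit thresholds) and
a lognormal fitted to wave height (exp(μ − σ²)). VIF is 1/(1 − R²) per
predictor; it is reported both for the plain wind+wave design and with
the uncentred interaction column appended, since the interaction
inflates it by an order of magnitude. Group comparisons use
Mann–Whitney (exact for small tie-free samples), Kruskal–Wallis (its
chi-square approximation is the standard form; it is not enumerated),
Pearson correlation, and the through-origin regression slope that
estimates the mean running acceleration from (duration, end-speed)
pairs. Each analysis uses its maximal complete-case subset, so sample
sizes legitimately differ between tables. No multiple-testing
correction is applied; p-values are raw.

## Synthetic data: what it emulates and what it does not

One simulated trip is floating → running → flight on a common clock:

* floating: slow drift (0.3 m/s) with GNSS speed noise; vertical
  displacement as a random-phase sum of sinusoids whose amplitudes
  follow a Gaussian bell centred at 1/Tp (width 0.2/Tp), scaled so
  4·√variance = Hs exactly. The bell is *not* a named ocean spectrum —
  the estimator under test uses only wave heights, not spectral shape.
* running: speed ramping at `run_accel` (default 1.23 m/s²) for
  `run_duration` (default 5.1 s) along the headwind azimuth; lateral
  acceleration carries a sharp-edged band-limited 6–15 Hz burst at 10×
  the noise sd plus a 3.2 Hz tone (the flap-band confound the detector
  must ignore).
* flapping: exactly `flap_count` cycles of a `flap_freq` sinusoid
  (default 2.55 Hz) on the dorsoventral channel from the running end.
* flight: heading as a slow deterministic sweep plus a low-passed
  random walk (guaranteeing the azimuthal coverage the sinusoid fit
  needs), ground speed following the wind law with Gaussian noise,
  blended from the lift-off speed over the first 10 s for continuity.

Batch scenarios draw wind from Weibull(k=2.6, λ=7.3) (mean ≈ 6.5,
mode ≈ 6.0 m/s), wave height from a lognormal (mean ≈ 3.0, mode ≈
2.7 m), directions von Mises about west, and couple effort to the
environment: running duration decreasing in wind and wave, flapping
zero-inflated (a bird either lifts straight into soaring — likelier in
strong wind and high waves — or flaps a burst of ≥ 3 strokes). Airspeed
rises with wind (Va = max(15, Vw + 5.5) m/s), as soaring birds do in
headwinds; without this a strong-wind headwind leg would implausibly
stall the simulated ground track below flying speed.

Not emulated: GNSS multipath and outliers (all noise is Gaussian),
hydrodynamic floating dynamics, wave directionality, altitude-dependent
wind shear, within-run flapping, and behavioural heading preferences.
Passing recovery tests therefore demonstrates correctness of the
estimators under the stated signal model, not robustness to every field
artefact; the deployment-level gates (ΔAIC, coverage, wave count,
no-running flag) are the run-time defences.

## Numerical choices and problem sizes

All filters are 4th-order recursive sections applied forward–backward
(zero phase). Ties: a zero sample completes an upward crossing;
relative angles wrap to (−π, π] with the boundary mapped to +π; the
circular mean uses vector summation. The MixedLM fit falls back to
Powell when the default optimizer hits a singular Hessian (common when
the random-effect variance estimate touches zero); non-converged models
are flagged and excluded from best-model selection.

Test and acceptance problem sizes — 100 flights for wind recovery, 50
seeds per wave height, 20 seeds per running duration, a 20-trip
end-to-end batch, 25–50 seeds of mixed-model selection at ~10 birds ×
18 events — were chosen as the smallest sizes at which the Monte-Carlo
tolerances above are meaningful; the whole suite runs in well under a
minute per study on one CPU.

## Known limitations

* Wind estimates assume constant Va and Vw over 5 min; mesoscale
  variability biases both, and the near-surface wind is weaker than the
  estimate taken at flight height.
* Hs from a floating bird underestimates 4·σ slightly on broad seas and
  says nothing about wave direction or swell/wind-sea partitioning.
* Running bounds inherit ~±0.3 s sensitivity to the variance window and
  threshold configuration even after edge correction.
* Flap counts of 1–2 are ±1 (see above); flap frequency within the run
  is not measured at all.
* The colony mask assumes a single circular colony.
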
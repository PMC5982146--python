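# Methods

This note documents the models, conventions and numerical choices behind
`gaitkit`, what the synthetic generator does and does not emulate, and the
design decisions taken where the problem was genuinely open.

## Signals and frames

Two 3-axis accelerometers sit above the lateral malleoli, sampled at 200 Hz
(g-units; `G_CONST = 9.80665 m/s²` wherever SI units are needed).  The
sensor X-axis points up the shank on both legs, while the Y/Z axes are
mirrored between sides.  `harmonize_axes` maps both sensors into one
anatomical frame — vertical (up the shank), anterior (walking direction),
lateral (away from the midline) — by sign-flipping the lateral channel on
one configured side (`MIRROR_SIDE = "left"`).  The exact per-side sign
convention of real hardware varies by mounting; the configured mirroring is
an assumption, recorded here and in the configuration, and is exercised by
the simulator, which emits sensor-frame traces.  Harmonisation is a signed
permutation, so per-sample vector magnitude is preserved exactly.

Biomechanical traces (vGRF, aGRF in N; knee flexion and adduction moments in
N·m) share the accelerometer time base, emulating hardware-triggered
synchronisation.  The package consumes these as exported time series; it
does not perform inverse dynamics.

Normalisation follows the anthropometric convention: forces and moments are
divided by body mass (N/kg, N·m/kg), acceleration-derived features by body
height (g/m).  Stride time and angle features are not height-dependent and
pass through unchanged.  Normalising twice is a state error; the
`normalized` flag rides on every feature object.

## Event detection

* **Heel strikes** are local maxima of the anterior acceleration with
  prominence ≥ 0.5 g and spacing ≥ 0.4 s (a cadence ceiling near 150
  strides/min).  No peak-picking parameters exist in the source protocol;
  these defaults are exposed in the configuration.  Detection count is
  invariant under uniform amplitude scaling provided the prominence
  threshold is scaled with the same normalisation.
* **Step starts from force** are upward crossings of 20% of the vGRF trace
  maximum, at sample resolution, debounced at 0.4 s.  Whether the original
  procedure interpolated crossing times is unknowable; sample resolution is
  used.
* **Cross-validation** of the two detectors uses greedy nearest-neighbour
  matching within a tolerance (default 50 ms), each event used at most once.

A *stride* is heel-strike to next heel-strike of one limb (what per-sensor
analyses sometimes call a "step"); windows are half-open `[hs, next_hs)`
with 0-based sample indices.  Stance is approximated as a fixed fraction of
the stride (default 0.60) because toe-off is not detected from
accelerometry alone; the fraction is configurable.

## Per-stride features

Biomechanical: KFM and KAM maxima are searched over the stance window (their
loading-response peaks occur in early stance; searching the full stride is a
configuration switch), aGRF over the whole stride (the propulsive peak is
late).  The vGRF value is the *first* strict local maximum within stance at
or above the step-detection threshold — the weight-acceptance peak of the
M-shaped profile — falling back to the stance maximum for unimodal
profiles.  A strict local maximum means a sample greater than both
neighbours.

Inertial: "residual acceleration" is defined as the per-sample deviation of
the acceleration vector magnitude from 1 g, summarised by RMS — this keeps
VM in acceleration units and window-length invariant, and vanishes for a
stationary or purely rotating sensor.  The "initial 10%" windows are the
first `round(0.10 · n_stride)` samples of the stride (a switch selects 10%
of stance instead); windows shorter than 2 samples are a feature error.
MAG-* search `|acceleration|` in a 100 ms window after the heel strike
(the protocol says only "at HS").  IMP-* are standard deviations over the
initial-10% window — the field calls them impulses and the name is kept.
Tilt angles come from 2nd-order zero-phase Butterworth low-passed channels
(3 Hz cutoff): lateral tilt = atan2(lat_lp, vert_lp), anterior tilt =
atan2(ant_lp, vert_lp), in degrees; ANG-* are their SDs over stance.  The
ANG-A definition uses the anterior tilt (the duplicated "lateral" wording in
the source's variable table is treated as a typo).  Free fall (near-zero
filtered magnitude) is rejected.

## Trial summaries

Averages pool all retained strides of both limbs.  The Symmetry Index uses
Robinson's form with the surgical/non-surgical convention (positive SI =
smaller values on the surgical limb); it is undefined (reported missing)
when the paired values sum to zero.  SI is computed per stride pair and
averaged (a trial-mean variant is a switch).  Pairs are matched by ordinal
position — the i-th stride of each limb belongs to the i-th gait cycle.
Matching by heel-strike enclosure was considered and rejected: with limbs in
antiphase a heel strike falls near the midpoint of the contralateral
stride, so enclosure pairs stride i with i−1 on one side and breaks the
symmetry null (a perfectly symmetric trial must yield SI = 0 for every
feature, which ordinal pairing guarantees by construction).

Outlier subjects are flagged when any of the four biomechanical trial
averages deviates from the cohort median by more than 3 scaled MADs
(scale 1.4826).  The multiplier and the restriction to biomechanical
averages (the clinically meaningful exclusion signal) are choices; both are
exposed.  Note that under unbounded cohort variation a 3-MAD rule will
occasionally flag legitimate borderline subjects — demonstrations of
"exactly one flagged" therefore use constructed cohorts with bounded
within-cohort variation.

## Estimation models

The eleven inertial variables partition into directional categories:
lateral {MAG-L, IMP-L, ANG-L}, vertical {MAG-V, IMP-V}, anterior {MAG-A,
IMP-A, ANG-A}, inclusive {VM, VM10, ST}.

**Stepwise selection.** Forward selection over all eleven candidates (the
results are grouped by category afterwards).  Candidates are ranked by the
cross-validated criterion — the mean across k folds (default k = 10,
subjects partitioned, deterministic given the seed; with n < 2k some folds
hold one subject) of the training-fit adjusted R².  The ranked candidate is
accepted only if (a) that criterion increases, (b) the full-sample adjusted
R² increases (the classic inclusion criterion), (c) its partial t-test has
p < 0.05, and (d) the pooled out-of-fold prediction R² increases.  Ties
break toward the lower column index, which also resolves duplicated
columns.  The out-of-fold gate is what makes the procedure honest at these
sample sizes: with the training-side criterion alone, a pure-noise candidate
improves the adjusted R² about half the time, whereas the combined rule
selects anything at all in well under 20% of null replicates (measured:
16% over 50 replicates at n = 100, 5 candidates).  `cv=False` drops
gates (a) and (d) for the plain adjusted-R²/p-to-enter variant.

**Hierarchical regression.** OLS models grown category-block by
category-block in the target's direction order — KFM and aGRF: anterior,
vertical, lateral, inclusive; KAM: lateral, anterior, vertical, inclusive;
vGRF: vertical, lateral, anterior, inclusive (primary axis first, then the
anterior→vertical→lateral cycle, inclusive always last).  Each step reports
multiple R, adjusted R² = 1 − (1 − R²)(n − 1)/(n − p − 1), and ΔR²
computed on *adjusted* R² (so it can be negative, unlike nested raw-R²
increments).  An empty category contributes ΔR² = 0 with carried-forward
statistics; an empty *leading* category reports R = 0 — the convention that
reproduces the published table shape where a primary axis enters first even
when no variable of that axis survived selection.  A rank-deficient design
raises an error naming the offending block.  The final step's adjusted R²
equals a one-shot OLS on all selected variables regardless of entry order;
only the ΔR² decomposition depends on the order.

**Pearson screening** reports r with p from the exact t transform (n − 2
df), two-tailed, with α ∈ {0.05, 0.01} stars and sub-threshold entries
suppressed in the formatted table only (no multiple-testing correction, by
design); the raw r/p matrices remain available.

The model suite fits all four targets, both on the full cohort and with
MAD-flagged subjects removed, and requires at least 8 subjects per branch.

## The synthetic generator

The generator is the package's study-conditions stand-in: no raw cohort
data exist, so every quantitative claim in the tests is made against
simulated gait with known truth.

Per trial: stride durations are i.i.d. normal (default mean 1.15 s, SD
0.05 s — self-selected treadmill pace near 1.1 m/s), snapped to the 200 Hz
grid and **shared by both limbs**, with the right limb offset by a constant
half mean stride.  The shared sequence plus shared per-stride amplitude
factors (CV 3%) make the symmetry null exact: with asymmetry 1 and no
noise, the limbs' per-stride features are identical by construction.  An
`asymmetry` ratio multiplies every surgical-limb amplitude, so the
generating SI of a scaled variable is 200(1 − a)/(1 + a).

Waveforms are minimal shapes carrying the landmarks the analysis detects:

* anterior acceleration — a damped oscillation at each heel strike
  (default 2.0 g, 18 Hz, 25 ms decay; apex exactly on the heel-strike
  sample) over a per-stride tilt program and a small swing harmonic;
* vertical acceleration — 1 g gravity, a transient at 0.8× the anterior
  amplitude, and a 0.08 g double-frequency bounce;
* lateral acceleration — sine of the lateral tilt program (default 4°
  amplitude, one cycle per stride, zero at heel strike) plus a 0.4×
  transient;
* vGRF — per stance (60% of the stride): a linear rise to the first peak in
  20 ms (so the 20%-threshold crossing lands within one sample of the heel
  strike), cosine fall to a 0.72 valley, second hump at 0.95 of the first,
  cosine decay to zero — an M shape whose first-peak amplitude is the
  controlled truth value;
* aGRF — braking (−0.3×) then propulsive humps; knee moments — single
  early-stance cosine bumps.  Every apex is snapped to the sampling grid,
  so noiseless extraction recovers the generating amplitudes to machine
  precision.

The transient's frequency/decay defaults keep it spectrally separated from
the sub-3 Hz tilt program, so the tilt low-pass recovers the generating
angle SD within 10% (measured ≈ 6% on defaults); the amplitudes have no
empirical anchor in the source (chosen for detectability and plausibility,
not fidelity).  Additive Gaussian noise (default 0.02 g) applies to the
accelerometer channels only.

What the generator does **not** emulate: soft-tissue artefact, sensor drift
and bias, turning or non-steady gait, double-support force transfer between
belts, within-stride waveform variability beyond amplitude scaling, and any
nonlinear feature→target physiology.  Passing tests therefore demonstrate
that the pipeline is correct and well-calibrated under its stated
assumptions, not that real-world accuracy matches.

`simulate_cohort` layers known linear effects on top: each subject draws an
independent gait profile (transient amplitudes and decay, tilt amplitudes,
stride time, anthropometrics from a realistic TKA cohort distribution:
height 1.71 ± 0.08 m, mass 87 ± 18 kg, age 67 ± 8 y, default n = 18), and
each trial-average biomechanical target is generated as `intercept +
coefficients · inertial features + Gaussian noise`.  Per-stride biomechanical
amplitude jitter is disabled in cohort mode so the generating linear model
holds exactly at zero noise.  With `include_traces=False` the generator
stops at the truth tables (the accelerometer signal is still synthesised to
compute the features), which is what makes 100-replicate × 200-subject
recovery studies affordable; the test suite and acceptance script use 6–10
strides per trial in those studies and 20–60 strides elsewhere.

## Numerical conventions

* Index-based windows throughout feature extraction (`[hs_index,
  next_hs_index)`), so generator truth and extractor agree exactly on
  noiseless data; sampling-uniformity tolerance 1e-6 s.
* Adjusted R² requires n > p + 1; the empty model has R = 0, adjusted
  R² = 0.
* All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; identical seeds give bit-identical traces,
  truth tables and model reports.
* CSV is the interchange format (no standard biomechanics container fits
  exported per-limb traces); `#`-prefixed header lines carry the
  configuration hash and are ignored on read.  Round trips are lossless to
  better than 1e-9.

## Known limitations

* Stance is a fixed stride fraction, not a detected toe-off; ANG-* windows
  inherit that approximation.
* Tilt from accelerometer low-passing conflates linear acceleration with
  orientation below the cutoff; only slow orientation content is trusted.
* The estimation models are strictly linear OLS on one row per subject —
  no mixed effects across strides, no regularisation, by scope.
* Published cohort-specific correlation and R² values cannot be reproduced
  without the original recordings; the package instead verifies the
  *procedures* against closed-form oracles and the *structure* of the
  results against constructed cohorts.
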
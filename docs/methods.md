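# Methods

## Signal model and normalization

Two-channel fibre photometry is modelled as a calcium-dependent signal
channel and a calcium-independent isosbestic reference that share a common
motion/bleaching component linearly. Normalization fits ordinary least
squares of signal on reference over a quiet baseline window and predicts
`F_normalized` for the whole session. Two z-scoring conventions exist for
the printed formula z = (F_normalized − μ)/σ: z-scoring the prediction
itself discards the activity residual, so the default mode here z-scores
the motion-corrected carrier `signal − F_normalized` (equivalently, the
signal after removing the reference-explained component); the literal
reading is available as `mode="predicted"`. Both modes self-normalize
exactly over the baseline window (mean 0, sample SD 1 with ddof = 1, to
better than 1e-9), which the test suite asserts.

The default baseline is the 10 minutes immediately preceding the first
stimulus, matching the acclimation structure of the sessions the package
targets. Bout-local analyses instead re-standardize against the 15 s
before each bout's first lick.

Downsampling is the mean over non-overlapping blocks (nearest-integer
block size, trailing remainder dropped): deterministic and anti-aliasing.
The centered moving-average smoother (spans 20 and 5 samples, shrinking at
the edges) is presentation-only; no statistic in the package is computed
on smoothed data.

## Bout segmentation

Photometry rules: licks are grouped greedily wherever consecutive licks
are < 20 s apart, then groups lasting < 4 s (last minus first lick) are
discarded. Grouping precedes the duration filter, so a discarded short
cluster still separates its neighbours; whether a sub-4-s cluster should
instead reset the 20-s clock is not decidable from the rule statement, and
the chosen reading keeps bouts maximal. Single-lick groups have duration 0
and are always discarded. Opto rules: maximal runs with every interlick
interval ≤ 5 s, keeping runs of ≥ 3 licks. Both implementations are
checked against an O(n²) brute-force scan on a thousand random trains,
including gaps placed exactly at the 5-s and 20-s boundaries.

The interlick-interval mixture truncates intervals to (0, 1] s and fits a
two-component Gaussian mixture by EM (scikit-learn, seeded, three
restarts, variance floor 1e-6 s²). Components are reported in ascending
mean order; degenerate interval sets collapse to coincident means rather
than a singular fit.

## Event-locked statistics

Per-bout responses use a −15 s local baseline and a 10-s response window
clipped to the bout's last lick when the bout is shorter (the clipped
window is closed at the last lick so the bout's final lick counts). The
identity z_per_lick × licks-in-window = z_per_bout is asserted per bout.

Rise and decay constants use the literal 63.8% / 37% crossing criteria on
the bout-averaged peri-event trace (PSTH), not the 1 − 1/e and 1/e
conventions; both constants are exposed as arguments. The PSTH is built on
the trace's own grid by per-bout interpolation and averaged across bouts
before the criterion search. Because the criterion references the PSTH
*maximum within a bout*, the rise-side PSTH extent defaults to the
shortest bout's duration (clipped to 5–30 s): beyond that point some bouts
have ended and the average is no longer a rising front. The decay-side
PSTH is aligned to last licks but standardized against each bout's
*pre-bout* baseline, so the last-lick value reflects the activation being
decayed from. Crossing estimators return the earliest grid point at or
past the criterion, an upward bias of at most one grid step (0.25 s at
4 Hz).

## Synthetic sessions

The generator emulates, with known ground truth: bout-structured lick
trains with bimodal sub-second interlick intervals (two-component
lognormal, default medians 0.13 s and 0.35 s with weights 0.8/0.2 —
typical ~7–8 Hz rodent licking); fast lick-locked calcium transients; slow
post-ingestive ramps; and a shared bleaching + band-limited motion
artifact in both channels (reference gain 0.7).

The lick-locked response is an asymmetric exponential bout envelope:
activity relaxes toward the bout amplitude with time constant `tau_rise`
(default 3.7 s) while licking and decays with `lambda_decay` (default
7.5 s) after the last lick. A superposition of per-lick kernels was
considered and rejected: convolving a lick train with any per-lick kernel
makes the bout envelope's rise time a function of the kernel's *decay*
constant (the envelope is the running integral of the kernel), so the
crossing estimators could not recover the nominal constants and the
generator would not be self-consistent. With the envelope form, the
63.8% and 37% crossings sit at 1.016 τ and 0.994 λ analytically, which is
what makes the recovery tests meaningful.

The default amplitude is 3.5 z — the magnitude of lick-locked activation
the package is designed around. The post-ingestive ramp is a saturating
function of cumulative intake volume (licks × 2 µl plus any infusion
epochs), delayed by `ramp_latency` (3.5 min) and low-pass filtered so a
step drive reaches half its plateau `ramp_t50` (16 min) later; it
reproduces ramping activation that keeps building after intake stops.

Channel noise is white at the acquisition rate (default 1017.3 Hz, the
demodulated rate of the emulated rig). This matters: the 4-Hz analysis
grid is produced by block-averaging ~254 raw samples, which is what gives
the z-trace its low noise floor and lets ten-bout sessions recover τ and λ
within the tested tolerances. The reference channel carries a smaller
independent noise floor (0.2 × `noise_sd`) so the z-scale of the regressed
residual stays within a few percent of the ground-truth amplitude. Noise,
artifact and bleach magnitudes are modelling choices — no measured values
exist for them — picked once for estimator testability.

What the generator does *not* model: spontaneous physiological baseline
fluctuations (so local baseline SDs at 4 Hz are much smaller than in real
recordings, and locally re-standardized z values are correspondingly
larger), hemodynamic or wavelength-dependent artifacts, indicator
nonlinearity and saturation, photobleaching of the response itself, and
any effect of stimulation on behaviour. Passing recovery tests therefore
show estimator correctness under the stated signal model, not robustness
to every failure mode of real photometry.

## Intake dynamics and encoding model

Trailing-window lick counts use half-open windows (t − w, t] on the 4-Hz
grid and are verified against a brute-force recount. The shuffled-control
correlation scrambles the intake predictor by full random permutation
(seeded; 100 permutations by default, mean reported); a circular-shift
null is deliberately not the default since the procedure being mirrored is
a scramble.

The encoding model is a Gaussian-identity linear model (the response is a
continuous z-score) over per-second rows: caloric density (kcal/ml,
constant within session: Intralipid 2, Ensure 0.923, glucose 0.96, zero
for saline/water/dry), licks in the past 10 s, and the instantaneous lick
rate taken as the licks in the trailing 1-s bin. z at each second is the
mean of the 4-Hz samples in that second. ΔR² for a variable is R²(full) −
R²(without it); exactly collinear designs are rejected with the offending
columns named, and near-duplicated predictors legitimately each get ΔR² ≈
0 despite joint explanatory power. Cross-validation uses sample-wise
random 80/20 splits for 100 seeded iterations; rows are temporally
autocorrelated, so this estimates interpolation error rather than
extrapolation error — a caveat inherent to the mirrored procedure.

## Single-cell classification

Per-cell z uses the 10-min baseline; zero-variance cells are flagged and
excluded rather than aborting. Activation is mean local z ≥ 1 over the
15-s response window — the threshold is applied inclusively everywhere
(the source procedures mix "≥1" and ">1"), and is a parameter. The
population-weighted score multiplies the fraction of cells activated in
*all* bouts by the mean response of those activated cells; averaging over
all cells instead would dilute by non-responders twice, but the
alternative is one flag away. Overlap significance uses the two-sided
Fisher exact test, verified against hypergeometric enumeration for every
2×2 table with n ≤ 30.

## Optogenetics accounting

Pulse timestamps are rising edges; `frequency × pulse_width ≥ 1` is
rejected. Lick-on retriggering restarts the 2-s window and the pulse phase
at each lick (a retrigger cannot interrupt a pulse in flight); lick-off
suppression deletes free-running cycle pulses within 2 s after any lick
without resetting the cycle phase — the phase-reset alternative is
plausible but not chosen, and the suppressed pulses are returned so the
partition against the open-loop schedule is checkable. The ×20 and ×8
summary formulas credit each lick with its full 2-s window; merged windows
make the simulated count at most the formula count, and for isolated licks
(gaps > 2 s) the two agree exactly.

Infusion profiles integrate piecewise-constant rates exactly on a 1-s
grid; a constant-rate infusion has T50 = duration/2 by construction.

## Problem sizes

The test suite and the acceptance script use sessions of roughly 10 bouts
of 150–320 licks over ~25–40 min equivalents, cell ensembles of 40–100
neurons, 200-run calibration loops for the Fisher type-I rate, and the
full τ/λ grid (τ ∈ {1, 3.7, 8} s × λ ∈ {3, 7.5, 15} s × noise ∈
{0.1, 0.5}); these sizes give stable estimates while keeping the whole
suite in the minutes range on one CPU.

## Known limitations

- The package starts at extracted traces and event logs; acquisition-file
  readers, video processing and cell extraction are out of scope.
- Statistics are per session/animal; no across-animal mixed models.
- The crossing estimators are grid-quantized and upward-biased by up to
  one grid step; fitting parametric kinetics would remove this but would
  no longer mirror the printed procedure.
- The GLM's caloric-density column is session-constant, so its ΔR²
  reflects between-session variance only.
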
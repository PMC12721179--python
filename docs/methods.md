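# Methods

This note records the models, parameter choices, and numerical
conventions behind `gaitcode`, and what the synthetic-data tests do and
do not establish.

## Kinematics chain

Input is a gapless 80 Hz table of 2-D coordinates (mm) for nose, tail
base, and the four limbs. The processing order is fixed:

1. **Smoothing.** Savitzky–Golay, polynomial order 3, window 7 frames
   (87.5 ms). The window length is a free choice: 7 frames is the
   shortest window that still attenuates tracking noise without
   distorting gait content up to 8 Hz. scipy's `interp` edge mode fits
   the boundary polynomial over the last full window, so polynomial
   trajectories pass through unchanged. Note the 7-frame cubic window
   reduces white-noise sd only by ≈ 1.7× (variance factor 1/3); a
   15-frame window achieves > 2× at the cost of 8 Hz fidelity.
2. **Speed.** Per-limb speed is the frame-difference displacement times
   the frame rate; body speed is the RMS over the four limbs. RMS
   (rather than the mean) weights moving limbs more and is what the
   speed-binned analyses consume. Acceleration is the centered
   difference of body speed.
3. **Bout detection.** Candidates are runs of body speed ≥ 50 mm/s
   sustained ≥ 0.5 s (dips shorter than 0.5 s are bridged). The onset is
   refined to the highest-prominence peak of positive acceleration in a
   50-frame window centered on the threshold crossing; candidates whose
   peak prominence is ≤ 1000 mm/s² are discarded. A bout ends when speed
   stays below 50 mm/s for ≥ 0.25 s. Bouts shorter than 1 s are dropped;
   when two bouts are separated by less than 1 s (previous offset to
   next onset) the later one is dropped. The 50 mm/s threshold matches
   the lowest analysed speed bin; the offset rule exists only to bound
   stride search and is deliberately loose.
4. **Gait signal.** Limb position is projected onto the nose–tail axis,
   measured back from the nose, and band-passed 0.5–8 Hz with a
   2nd-order Butterworth applied forward and backward (zero phase).
   Signals shorter than three filter lengths are rejected rather than
   padded.
5. **Strides and phase.** Stance onsets are local minima of the filtered
   signal (limb closest to the nose), swing onsets local maxima, with a
   minimum peak distance of half the 8 Hz period and a small prominence
   floor (0.1 signal sd) against tracker noise. A stride requires
   exactly one maximum between consecutive minima; partial edge cycles
   are dropped. Phase is the analytic-signal (Hilbert) angle of the
   full-session filtered signal, shifted +180° so stance onset ≈ 0°,
   wrapped to [0°, 360°), and masked to bout frames.

## Single-unit statistics

- **Peri-event rates.** Spikes are counted in 25 ms bins on a window
  padded by 4 kernel widths, convolved with a unit-mass Gaussian
  (σ = 0.1 s), converted to Hz, then block-averaged to the output bin
  (0.1 s for modulation, 0.2 s for decoding). Padding keeps kernel mass
  conservation at the analysis-window edges to < 1%.
- **Onset modulation.** Two-sided paired t-test per 0.1 s bin against
  the −1.0 to −0.9 s baseline bin, α = 0.05, no multiple-testing
  correction (the per-bin fraction is a descriptive curve, and
  correcting would change its meaning). Zero-variance differences —
  including the baseline tested against itself — count as not
  modulated.
- **Speed tuning.** Mean rate per 20 mm/s bin from 50 to 310 mm/s
  (13 bins) over walking frames, occupancy-weighted; empty bins are
  dropped; units with < 3 occupied bins are flagged invalid. R² is the
  squared Pearson correlation of bin rate against bin-centre speed.
- **Phase locking.** Each spike takes the phase of its containing video
  frame (12.5 ms; no sub-frame interpolation — at 2.5 Hz strides one
  frame spans 11°, well inside the 15° bins). Rates in 24 bins are
  divided by per-bin occupancy time, which removes artefacts from
  nonuniform phase sampling at varying speeds; the vector length is the
  magnitude of the rate-weighted resultant of the bin centres. With 24
  bins the binning attenuates a true resultant by sin(π/24)/(π/24)
  ≈ 0.9971, far inside the 0.02 oracle tolerance used in tests.
- **Jitter null.** Each surrogate displaces every spike independently by
  U(−0.15, +0.15) s — the stricter reading of "shifting spike times",
  destroying fast phase structure while preserving slow rate — and
  recomputes r along the identical arithmetic path (so a zero-width
  jitter reproduces r bit for bit). Spikes jittered off walking frames
  drop out of that surrogate. A unit is locked to a limb if its r
  exceeds the 95th percentile of 1000 surrogates, and locked overall if
  locked for at least one limb.

## Decoding

Trials × units × classes tensors are built per task: time — one trial
per bout, 15 population vectors in 0.2 s bins tiling ±1.5 s around
onset; speed — one trial per 0.2 s walking bin, labelled by mean body
speed in four 50 mm/s classes from 50 to 250; phase — one trial per
stride, smoothed 25 ms rates averaged over the frames of each 30° bin
(strides not covering all 12 bins are dropped). Sessions are sampled to
a fixed per-session quota and pooled by unit concatenation into a
pseudo-population, trials aligned by index; sessions missing the quota
are excluded with a warning rather than resampled, to avoid duplicated
trials.

The classifier is one binary RBF-SVM per unordered class pair, with
per-unit standardisation and a median-heuristic kernel bandwidth learned
on training data only. Prediction tallies one vote per pair classifier;
ties break by the summed signed decision-function margin, then by lowest
class index — fully deterministic. Regularisation C ∈ {0.1, 1, 10, 100}
and bandwidth multiplier ∈ {0.1, 0.3, 1, 3, 10} are searched in fixed
order, capped at 20 evaluations, with 5-fold stratified CV; the search
runs once per evaluation call on the first unit draw and is reused,
since re-tuning per draw/iteration would dominate runtime without
changing the regional contrasts the pipeline reports.

Evaluation nests random unit draws (outer) over leave-trials-out
iterations (inner; 1 trial for time, 2 for speed, 4 for phase). Chance
bands come from re-evaluating tensors whose class labels are permuted
independently within each trial (2.5/97.5 percentiles over surrogates,
one unit draw each). Errors: RMSE over physical bin centres (seconds,
mm/s) plus a bin-index RMSE; phase error is the circular absolute
difference wrapped to [0°, 180°]. The pre-start window is −0.9 to
−0.3 s, post-start 0.3 to 0.9 s — three 0.2 s bins each.

## Synthetic world

The generator emulates the statistical structure the analysis assumes,
not biomechanics. Defaults: 80 Hz frames, stride frequency 2.5 Hz, trot
offsets (left-rear/right-fore at 0°, left-fore/right-rear at 180°),
walking bouts averaging 4 s separated by gaps averaging 4 s (both ≥ 1 s),
body speed an Ornstein–Uhlenbeck walk inside 50–310 mm/s with a
raised-cosine onset rise sized to clear the 1000 mm/s² prominence
filter, limb oscillation an asymmetric sinusoid (stance fraction 0.55,
faster swing), additive Gaussian tracking noise of 0.5 mm (≈ the pixel
scale of the emulated video), and per-limb slow phase jitter of 8°.

Two conventions matter:

- **Speed scale.** The analysis measures body speed as RMS limb speed,
  which limb oscillation inflates above the translation speed. The
  configured speed range refers to the *measured* scale; the body
  translates at speed/F with F = √(1 + a²·E[w′²]) computed from the limb
  waveform. Without this, the lowest speed class would be unoccupied.
- **Spike intensity.** log λ(t) = log(baseline) + a·shape(t) +
  g·speed(t) + κ·cos(φ(t) − φ₀), sampled on a 1 ms grid and realised by
  thinning (exact for piecewise-constant intensity). The ramp shape
  rises linearly from `ramp_lead` before onset to 1 at onset + 0.1 s and
  decays exponentially. Ramp amplitude and speed gain act on the log
  rate, which guarantees positivity; the phase term is exactly von
  Mises, so κ = 1 yields a true resultant of I₁(1)/I₀(1) ≈ 0.4464.

Region presets encode the qualitative contrast the pipeline is meant to
recover: "M1-like" (weak ramp a ≈ 0.2, strong phase tuning κ ≈ 2) and
"DMS-like" (strong early ramp a ≈ 1.2, lead 0.6–1.2 s, weak κ ≈ 0.3).
The real tuning-strength distributions are unpublished; these presets
are calibration knobs, not estimates, so a green contrast test
establishes that the pipeline *orders* such populations correctly, not
that real regions carry these effect sizes. The generator also omits
non-Poisson history effects, behavioural states other than rest/walk
(no grooming or rearing), tracking dropouts, and speed-dependent stride
frequency.

## Reduced-scale testing

The published analysis uses 50 draws × 50 iterations × 200 units on
hundreds of real trials; the test suite shrinks these (typically 10
draws, 10–15 iterations, 50 units, 20–60 trials, smaller tuning grids,
200–300 jitter surrogates) so the whole suite runs in minutes on one
CPU. Counts were reduced, thresholds and acceptance bands were not. All
randomness flows from one master seed through a per-stage SHA-256
derivation, so partial re-runs reproduce the full pipeline bit for bit;
the end-to-end report is byte-identical across re-runs at a fixed seed.

## Known limitations

- Bout acceptance is fully automatic; the original workflow also
  included manual review of rhythmicity, so the automated chain may
  admit bouts a human would reject.
- Pseudo-population pooling treats trials from different sessions as
  matched and draws as independent samples for group tests; the report
  logs this caveat verbatim.
- The phase decoder averages smoothed rates within per-stride 30° bins;
  at high stride rates the 0.1 s kernel blurs adjacent bins, putting a
  ceiling on phase-decoding accuracy that is visible even for strongly
  tuned synthetic units.
- `speed_tuning` and the speed decoder use measured (RMS-limb) speed;
  comparisons against generator ground truth are monotone but not
  identical in scale.
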